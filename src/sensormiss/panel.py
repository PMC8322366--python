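"""Participant-day panel of missing vs expected measurement groupings.

The model's unit of observation is the participant-day: on each calendar
day a participant is enrolled, the schedule implies ``E`` expected
measurement groupings; the response is the count of those that never
arrived, ``y = max(0, E - observed)``.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .events import MeasurementGrouping
from .schedule import SensorSchedule, expected_groupings_per_day

logger = logging.getLogger(__name__)

RACE_LEVELS = [
    "non-Hispanic White",
    "non-Hispanic Black",
    "Asian",
    "American Indian/Alaska Native",
    "Other/Hispanic",
]
#: race dummies in the model; reference level is non-Hispanic White
RACE_DUMMY_LEVELS = RACE_LEVELS[1:]

EDUCATION_4YR_PLUS = {"Bachelors", "Graduate degree"}

COVARIATE_COLUMNS = [
    "participant_id",
    "study_id",
    "os",
    "gender",
    "education",
    "race_ethnicity",
    "age_years",
]

PANEL_COLUMNS = [
    "participant_id",
    "study_id",
    "sensor",
    "day_index",
    "week",
    "y_missing",
    "e_expected",
    "os_ios",
    "male",
    "degree_4yr_plus",
    "race",
    "age_decades",
]

#: covariates entering the regression; participants missing any are
#: excluded by the complete-case filter
MODELED_COVARIATES = ["os", "gender", "education", "race_ethnicity", "age_years"]


def validate_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Check a covariate table: required columns, unique ids, known levels."""
    missing_cols = [c for c in COVARIATE_COLUMNS if c not in covariates.columns]
    if missing_cols:
        raise ValueError(f"covariate table lacks columns {missing_cols}")
    if covariates["participant_id"].duplicated().any():
        dupes = covariates.loc[
            covariates["participant_id"].duplicated(), "participant_id"
        ].tolist()
        raise ValueError(f"duplicate participant ids in covariate table: {dupes}")
    levels = {
        "os": {"Android", "iOS"},
        "gender": {"Female", "Male"},
        "race_ethnicity": set(RACE_LEVELS),
    }
    for col, allowed in levels.items():
        vals = covariates[col].dropna()
        vals = vals[vals.astype(str).str.len() > 0]
        bad = set(vals) - allowed
        if bad:
            raise ValueError(f"unknown {col} levels {sorted(bad)}; allowed {sorted(allowed)}")
    return covariates


def _is_missing(s: pd.Series) -> pd.Series:
    return s.isna() | (s.astype(str).str.strip() == "")


def encode_covariates(covariates: pd.DataFrame) -> pd.DataFrame:
    """Add model dummy columns (os_ios, male, degree_4yr_plus, race, age_decades).

    Missing source values propagate as NaN dummies; they are resolved by
    :func:`complete_case_filter`, never silently imputed.
    """
    cov = covariates.copy()

    def dummy(col: str, true_values: set[str]) -> pd.Series:
        miss = _is_missing(cov[col])
        out = cov[col].isin(true_values).astype(float)
        out[miss] = np.nan
        return out

    cov["os_ios"] = dummy("os", {"iOS"})
    cov["male"] = dummy("gender", {"Male"})
    cov["degree_4yr_plus"] = dummy("education", EDUCATION_4YR_PLUS)
    race = cov["race_ethnicity"].where(~_is_missing(cov["race_ethnicity"]), np.nan)
    cov["race"] = race
    cov["age_decades"] = pd.to_numeric(cov["age_years"], errors="coerce") / 10.0
    return cov


def build_daily_panel(
    groupings_by_participant: Mapping[str, Sequence[MeasurementGrouping]],
    schedule: SensorSchedule,
    covariates: pd.DataFrame,
    timezone: str = "UTC",
    drop_partial_edge_days: bool = False,
    enrollment: Mapping[str, tuple[str, int]] | None = None,
) -> pd.DataFrame:
    """Build the participant-day panel from segmented measurement groupings.

    For each participant, days run from the calendar day (in ``timezone``)
    of their first event to that of their last event, inclusive.  Each
    grouping counts toward the day containing its start time, so no
    grouping is ever counted twice.  ``y_missing`` is clipped at zero
    when more groupings than expected are observed (clock drift, OS
    bursts); such days are logged.

    Parameters
    ----------
    groupings_by_participant : mapping
        ``participant_id -> list of MeasurementGrouping`` from
        :func:`~sensormiss.events.segment_events`.
    schedule : SensorSchedule
        The design whose expected count defines the offset ``E``.
    covariates : DataFrame
        One row per participant (see :data:`COVARIATE_COLUMNS`).
    timezone : str
        IANA timezone used to cut streams into calendar days.
    drop_partial_edge_days : bool
        If True, exclude each participant's first and last observed day
        (which may be only partially covered by enrollment).
    enrollment : mapping, optional
        ``participant_id -> (first_day_iso, n_days)`` enrollment windows
        from the study design.  When given for a participant, days span
        that window (in ``timezone``) instead of being inferred from the
        first/last event; days with zero groupings at either edge are
        then correctly counted as fully missing.
    """
    validate_covariates(covariates)
    cov = encode_covariates(covariates).set_index("participant_id")

    unknown = sorted(set(groupings_by_participant) - set(cov.index))
    if unknown:
        raise KeyError(f"participants absent from covariate table: {unknown}")

    e_expected = expected_groupings_per_day(schedule)
    rows = []
    for pid in sorted(groupings_by_participant):
        groupings = groupings_by_participant[pid]
        window = (enrollment or {}).get(pid)
        if len(groupings) == 0 and window is None:
            logger.warning("participant %s has no events; contributing zero rows", pid)
            continue
        if groupings:
            starts = pd.DatetimeIndex(
                pd.to_datetime([g.start_ms for g in groupings], unit="ms", utc=True)
            ).tz_convert(timezone)
            days = starts.normalize()
            observed = pd.Series(1, index=days).groupby(level=0).sum()
        else:
            observed = pd.Series(dtype=int)
        if window is not None:
            first_day = pd.Timestamp(window[0], tz=timezone)
            all_days = pd.date_range(first_day, periods=int(window[1]), freq="D")
        else:
            all_days = pd.date_range(days.min(), days.max(), freq="D", tz=days.tz)
        counts = observed.reindex(all_days, fill_value=0)
        if drop_partial_edge_days and len(counts) > 2:
            counts = counts.iloc[1:-1]
        elif drop_partial_edge_days:
            counts = counts.iloc[0:0]
        over = counts[counts > e_expected]
        if len(over):
            logger.warning(
                "participant %s: %d day(s) with more groupings than expected "
                "(max %d > E=%d); y clipped at 0",
                pid,
                len(over),
                int(over.max()),
                e_expected,
            )
        person = cov.loc[pid]
        day_index = np.arange(len(counts)) + (1 if drop_partial_edge_days else 0)
        for di, obs in zip(day_index, counts.to_numpy()):
            rows.append(
                {
                    "participant_id": pid,
                    "study_id": person["study_id"],
                    "sensor": schedule.sensor_name,
                    "day_index": int(di),
                    "week": di / 7.0,
                    "y_missing": int(max(0, e_expected - obs)),
                    "e_expected": int(e_expected),
                    "os_ios": person["os_ios"],
                    "male": person["male"],
                    "degree_4yr_plus": person["degree_4yr_plus"],
                    "race": person["race"],
                    "age_decades": person["age_decades"],
                }
            )
    return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def participant_missingness_summary(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-participant mean proportion of missing groupings.

    Returns one row per participant with the mean over days of
    ``y_missing / e_expected`` and the number of observed days, sorted
    ascending by the mean proportion.
    """
    if panel.empty:
        raise ValueError("panel is empty")
    prop = panel["y_missing"] / panel["e_expected"]
    out = (
        panel.assign(prop_missing=prop)
        .groupby(["participant_id", "study_id"], as_index=False)
        .agg(mean_prop_missing=("prop_missing", "mean"), days_observed=("prop_missing", "size"))
        .sort_values("mean_prop_missing", kind="mergesort", ignore_index=True)
    )
    return out


def complete_case_filter(
    panel: pd.DataFrame, modeled: Sequence[str] = ("os_ios", "male", "degree_4yr_plus", "race", "age_decades")
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop every row of any participant missing a modeled covariate.

    Returns the filtered panel and an exclusion report with one row per
    dropped participant listing the missing covariates.
    """
    per_participant = panel.groupby("participant_id", sort=True)
    dropped = []
    keep_ids = []
    for pid, grp in per_participant:
        first = grp.iloc[0]
        missing = [c for c in modeled if pd.isna(first[c])]
        if missing:
            dropped.append(
                {"participant_id": pid, "missing_covariates": ",".join(missing)}
            )
        else:
            keep_ids.append(pid)
    report = pd.DataFrame(dropped, columns=["participant_id", "missing_covariates"])
    filtered = panel[panel["participant_id"].isin(keep_ids)].reset_index(drop=True)
    if filtered.empty:
        raise ValueError("complete-case filter removed every participant")
    return filtered, report


def covariate_summary(covariates: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level marginal counts and percentages of each covariate level.

    Percentages are relative to the full cohort including participants
    with missing values, matching how demographic tables are usually
    printed.
    """
    validate_covariates(covariates)
    n = len(covariates)
    rows = [{"variable": "participants", "level": "N", "count": n, "percent": 100.0}]
    for col in ["os", "gender", "education", "race_ethnicity"]:
        vals = covariates[col].where(~_is_missing(covariates[col]), "Missing")
        for level, count in vals.value_counts().items():
            rows.append(
                {
                    "variable": col,
                    "level": level,
                    "count": int(count),
                    "percent": round(100.0 * count / n, 0) if n else np.nan,
                }
            )
    age = pd.to_numeric(covariates["age_years"], errors="coerce")
    rows.append(
        {
            "variable": "age_years",
            "level": "mean (SD)",
            "count": int(age.notna().sum()),
            "percent": np.nan,
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["age_mean"] = float(age.mean()) if age.notna().any() else np.nan
    out.attrs["age_sd"] = float(age.std()) if age.notna().sum() > 1 else np.nan
    return out
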