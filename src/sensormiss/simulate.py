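"""Synthetic cohorts, panels and event streams with full ground truth.

Real duty-cycled sensor logs from clinical digital-phenotyping studies
cannot be redistributed, so every downstream stage is validated against
data generated here: a cohort whose covariate marginals mirror the
six-study meta-analytic cohort that motivates the package, per-day
non-collection counts drawn from the hierarchical negative-binomial
model itself, and raw event streams whose segmentation reproduces those
counts exactly.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .events import EventStream
from .panel import (
    COVARIATE_COLUMNS,
    RACE_LEVELS,
    encode_covariates,
)
from .schedule import SensorSchedule, expected_groupings_per_day

#: design-matrix column for each non-reference race level
RACE_DUMMY_COLS = {
    "non-Hispanic Black": "race_black",
    "Asian": "race_asian",
    "American Indian/Alaska Native": "race_amindian",
    "Other/Hispanic": "race_other",
}

#: fixed-effect design columns, in report order
FIXED_EFFECT_COLS = [
    "week",
    "os_ios",
    "male",
    "degree_4yr_plus",
    "race_black",
    "race_asian",
    "race_amindian",
    "race_other",
    "age_decades",
]


class ConfigError(ValueError):
    """Invalid simulation configuration (e.g. probabilities outside [0, 1])."""


@dataclass(frozen=True)
class TrueParams:
    """Ground-truth parameters of the hierarchical NB model.

    ``alpha0`` is the grand-mean log rate (log of the conditional
    non-collection rate at week 0 for the reference covariate pattern);
    ``beta`` maps design columns to log rate ratios; ``sigma_gamma`` and
    ``sigma_delta`` are the participant- and study-level random-intercept
    SDs; ``omega`` is the NB inverse-overdispersion (shape), with
    Var(y) = mu + mu^2/omega.
    """

    alpha0: float
    beta: Mapping[str, float] = field(default_factory=dict)
    sigma_gamma: float = 0.0
    sigma_delta: float = 0.0
    omega: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_gamma < 0 or self.sigma_delta < 0:
            raise ConfigError("random-effect SDs must be >= 0")
        if self.omega <= 0:
            raise ConfigError("omega must be > 0")
        unknown = set(self.beta) - set(FIXED_EFFECT_COLS)
        if unknown:
            raise ConfigError(f"unknown fixed-effect names {sorted(unknown)}")

    def beta_vector(self, cols: list[str] | None = None) -> np.ndarray:
        cols = FIXED_EFFECT_COLS if cols is None else cols
        return np.array([self.beta.get(c, 0.0) for c in cols])


def _rate_ratio_params(intercept_rate, rr, sigma_gamma, sigma_delta, omega):
    return TrueParams(
        alpha0=math.log(intercept_rate),
        beta={k: math.log(v) for k, v in rr.items()},
        sigma_gamma=sigma_gamma,
        sigma_delta=sigma_delta,
        omega=omega,
    )


#: Published point estimates for GPS non-collection in the motivating
#: six-study cohort (rate ratios on the exp scale), used as simulation
#: ground truth in parameter-recovery studies.
GPS_TRUE_PARAMS = _rate_ratio_params(
    0.269,
    {
        "week": 1.009,
        "os_ios": 0.660,
        "male": 0.822,
        "degree_4yr_plus": 0.688,
        "race_black": 1.329,
        "race_asian": 0.898,
        "race_amindian": 1.241,
        "race_other": 0.926,
        "age_decades": 1.011,
    },
    sigma_gamma=0.888,
    sigma_delta=0.295,
    omega=0.64,
)

#: Published point estimates for accelerometer non-collection, same cohort.
ACCEL_TRUE_PARAMS = _rate_ratio_params(
    0.191,
    {
        "week": 1.005,
        "os_ios": 1.301,
        "male": 0.821,
        "degree_4yr_plus": 0.786,
        "race_black": 1.638,
        "race_asian": 0.724,
        "race_amindian": 1.137,
        "race_other": 0.978,
        "age_decades": 1.010,
    },
    sigma_gamma=1.012,
    sigma_delta=0.721,
    omega=0.53,
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level simulation settings.

    Default covariate marginals mirror the motivating cohort: 23% iOS,
    33% male, 25% with a 4-year degree or higher, race distribution
    dominated by non-Hispanic White, age 25.4 (SD 10.8) years.
    """

    n_studies: int = 6
    participants_per_study: int = 30
    days_per_participant: int = 90
    p_ios: float = 0.23
    p_male: float = 0.33
    p_degree_4yr_plus: float = 0.25
    race_probs: tuple[float, ...] = (0.579, 0.153, 0.183, 0.010, 0.075)
    age_mean: float = 25.4
    age_sd: float = 10.8
    schedule: SensorSchedule = field(
        default_factory=lambda: SensorSchedule("gps", 60, 540)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_ios", "p_male", "p_degree_4yr_plus"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        rp = np.asarray(self.race_probs, dtype=float)
        if rp.size != len(RACE_LEVELS) or np.any(rp < 0) or abs(rp.sum() - 1.0) > 1e-9:
            raise ConfigError(
                f"race_probs must be {len(RACE_LEVELS)} non-negative values summing to 1"
            )
        if min(self.n_studies, self.days_per_participant) < 1 or self.participants_per_study < 0:
            raise ConfigError("n_studies, days_per_participant must be >= 1")


def generate_cohort(config: SimConfig) -> pd.DataFrame:
    """Draw a synthetic cohort covariate table.

    The RNG is split hierarchically per study and participant, so
    enlarging one study leaves every other participant's draws intact.
    """
    root = np.random.SeedSequence(config.seed)
    study_seeds = root.spawn(config.n_studies)
    rows = []
    for j, study_seq in enumerate(study_seeds):
        study_id = f"study_{j:02d}"
        for i, pseq in enumerate(study_seq.spawn(config.participants_per_study)):
            rng = np.random.default_rng(pseq)
            rows.append(
                {
                    "participant_id": f"{study_id}_p{i:04d}",
                    "study_id": study_id,
                    "os": "iOS" if rng.random() < config.p_ios else "Android",
                    "gender": "Male" if rng.random() < config.p_male else "Female",
                    "education": (
                        "Bachelors"
                        if rng.random() < config.p_degree_4yr_plus
                        else "High school"
                    ),
                    "race_ethnicity": RACE_LEVELS[
                        rng.choice(len(RACE_LEVELS), p=np.asarray(config.race_probs))
                    ],
                    "age_years": round(float(rng.normal(config.age_mean, config.age_sd)), 1),
                }
            )
    return pd.DataFrame(rows, columns=COVARIATE_COLUMNS)


# Per-study demographic margins of the motivating six-study cohort
# (N, android, ios, male, female, gender_missing, highschool, associates,
#  bachelors, graduate, edu_missing, white, black, asian, amindian,
#  other_hispanic, race_missing, age_mean).
_REFERENCE_STUDY_MARGINS = {
    "study_A": (16, 0, 16, 4, 12, 0, 16, 0, 0, 0, 0, 7, 4, 5, 0, 0, 0, 19.4),
    "study_B": (11, 7, 4, 8, 3, 0, 11, 0, 0, 0, 0, 9, 1, 1, 0, 0, 0, 31.5),
    "study_C": (12, 12, 0, 5, 7, 0, 2, 6, 3, 1, 0, 9, 2, 1, 0, 0, 0, 20.4),
    "study_D": (59, 40, 19, 0, 57, 2, 0, 3, 36, 13, 7, 32, 12, 7, 0, 5, 3, 41.1),
    "study_E": (39, 35, 4, 16, 23, 0, 39, 0, 0, 0, 0, 14, 3, 14, 0, 5, 3, 18.4),
    "study_F": (74, 69, 5, 36, 38, 0, 74, 0, 0, 0, 0, 46, 9, 9, 2, 5, 3, 18.2),
}


def reference_cohort() -> pd.DataFrame:
    """Deterministic 211-participant cohort reproducing the published
    per-study demographic margins of the motivating six-study cohort.

    Within each study, categorical levels are assigned to participants in
    a fixed order (the joint distribution within study is synthetic; only
    the margins are faithful).  Ages are set to the study mean.
    """

    def fill(n, counts_levels):
        out = []
        for count, level in counts_levels:
            out.extend([level] * count)
        assert len(out) == n
        return out

    rows = []
    for sid, m in _REFERENCE_STUDY_MARGINS.items():
        (n, android, ios, male, female, g_miss, hs, assoc, bach, grad, e_miss,
         white, black, asian, amind, other, r_miss, age_mean) = m
        os_col = fill(n, [(android, "Android"), (ios, "iOS")])
        gender = fill(n, [(male, "Male"), (female, "Female"), (g_miss, None)])
        edu = fill(
            n,
            [(hs, "High school"), (assoc, "Associates"), (bach, "Bachelors"),
             (grad, "Graduate degree"), (e_miss, None)],
        )
        race = fill(
            n,
            [(white, RACE_LEVELS[0]), (black, RACE_LEVELS[1]), (asian, RACE_LEVELS[2]),
             (amind, RACE_LEVELS[3]), (other, RACE_LEVELS[4]), (r_miss, None)],
        )
        for i in range(n):
            rows.append(
                {
                    "participant_id": f"{sid}_p{i:04d}",
                    "study_id": sid,
                    "os": os_col[i],
                    "gender": gender[i],
                    "education": edu[i],
                    "race_ethnicity": race[i],
                    "age_years": age_mean,
                }
            )
    return pd.DataFrame(rows, columns=COVARIATE_COLUMNS)


@dataclass
class GroundTruth:
    """Everything the simulator knows that an analyst would not."""

    params: TrueParams
    gamma: pd.Series  # participant random intercepts, indexed by participant_id
    delta: pd.Series  # study random intercepts, indexed by study_id
    mu: np.ndarray  # per panel row
    y: np.ndarray  # per panel row, after clipping at E
    n_clipped: int = 0
    clip_rate: float = 0.0

    def to_json(self) -> str:
        return json.dumps(
            {
                "params": {
                    "alpha0": self.params.alpha0,
                    "beta": dict(self.params.beta),
                    "sigma_gamma": self.params.sigma_gamma,
                    "sigma_delta": self.params.sigma_delta,
                    "omega": self.params.omega,
                },
                "gamma": self.gamma.to_dict(),
                "delta": self.delta.to_dict(),
                "n_clipped": int(self.n_clipped),
                "clip_rate": float(self.clip_rate),
            },
            indent=2,
        )


def simulate_panel(
    cohort: pd.DataFrame, params: TrueParams, config: SimConfig
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate daily non-collection counts from the hierarchical NB model.

    For participant i in study j on day d (week w = d/7):

        log mu = log E + alpha0 + beta' X + gamma_ij + delta_j
        y ~ NegBin(mu, omega),  clipped at E

    NB draws exceeding the design ceiling E are clipped (the bounded
    reality the unbounded NB cannot express); the clip rate is recorded
    in the returned ground truth.
    """
    cov = encode_covariates(cohort)
    study_ids = sorted(cov["study_id"].unique())
    e_expected = expected_groupings_per_day(config.schedule)
    log_e = math.log(e_expected)

    root = np.random.SeedSequence(entropy=(config.seed, 0x5E50A))
    study_seqs = {sid: seq for sid, seq in zip(study_ids, root.spawn(len(study_ids)))}
    delta = pd.Series(
        {
            sid: params.sigma_delta * np.random.default_rng(seq).standard_normal()
            for sid, seq in study_seqs.items()
        }
    )

    race_dummies = {
        col: (cov["race"] == level).astype(float)
        for level, col in RACE_DUMMY_COLS.items()
    }
    days = np.arange(config.days_per_participant)
    weeks = days / 7.0

    rows = []
    mu_all, y_all = [], []
    gamma = {}
    n_clipped = 0
    for sid in study_ids:
        members = cov[cov["study_id"] == sid]
        p_seqs = study_seqs[sid].spawn(len(members) + 1)[1:]
        for (idx, person), pseq in zip(members.iterrows(), p_seqs):
            rng = np.random.default_rng(pseq)
            g = params.sigma_gamma * rng.standard_normal()
            gamma[person["participant_id"]] = g
            x = {
                "week": weeks,
                "os_ios": person["os_ios"],
                "male": person["male"],
                "degree_4yr_plus": person["degree_4yr_plus"],
                "race_black": race_dummies["race_black"].loc[idx],
                "race_asian": race_dummies["race_asian"].loc[idx],
                "race_amindian": race_dummies["race_amindian"].loc[idx],
                "race_other": race_dummies["race_other"].loc[idx],
                "age_decades": person["age_decades"],
            }
            eta = log_e + params.alpha0 + delta[sid] + g
            eta = eta + sum(params.beta.get(k, 0.0) * np.asarray(v) for k, v in x.items())
            mu = np.exp(eta)
            if not np.all(np.isfinite(mu)):
                bad = int(np.flatnonzero(~np.isfinite(mu))[0])
                raise ConfigError(
                    f"non-finite mean for participant {person['participant_id']} "
                    f"day {bad}: check TrueParams magnitudes"
                )
            y_raw = rng.negative_binomial(
                params.omega, params.omega / (params.omega + mu)
            )
            n_clipped += int(np.sum(y_raw > e_expected))
            y = np.minimum(y_raw, e_expected)
            mu_all.append(mu)
            y_all.append(y)
            for d, w, yy in zip(days, weeks, y):
                rows.append(
                    {
                        "participant_id": person["participant_id"],
                        "study_id": sid,
                        "sensor": config.schedule.sensor_name,
                        "day_index": int(d),
                        "week": w,
                        "y_missing": int(yy),
                        "e_expected": e_expected,
                        "os_ios": person["os_ios"],
                        "male": person["male"],
                        "degree_4yr_plus": person["degree_4yr_plus"],
                        "race": person["race"],
                        "age_decades": person["age_decades"],
                    }
                )
    panel = pd.DataFrame(rows)
    mu_arr = np.concatenate(mu_all) if mu_all else np.empty(0)
    y_arr = np.concatenate(y_all).astype(np.int64) if y_all else np.empty(0, dtype=np.int64)
    truth = GroundTruth(
        params=params,
        gamma=pd.Series(gamma),
        delta=delta,
        mu=mu_arr,
        y=y_arr,
        n_clipped=n_clipped,
        clip_rate=n_clipped / len(panel) if len(panel) else 0.0,
    )
    return panel, truth


BASE_EPOCH_MS = 1_451_606_400_000  # 2016-01-01T00:00:00Z


def simulate_streams(
    panel: pd.DataFrame,
    schedule: SensorSchedule,
    seed: int = 0,
    within_cycle_hz: float = 1.0,
) -> tuple[list[EventStream], dict[str, tuple[str, int]]]:
    """Emit raw duty-cycled event streams realizing a simulated panel.

    For each participant-day, ``y_missing`` of the ``E`` design cycles
    are dropped uniformly at random; each retained on-cycle carries
    events at ``within_cycle_hz`` from the cycle start.  Also returns
    the enrollment window per participant (first day ISO date, number of
    days) so the panel can be rebuilt exactly even when edge days are
    entirely missing.

    Exact round-trip through segmentation requires the within-cycle
    event spacing (1/hz) to be below half the off-cycle.
    """
    e_expected = expected_groupings_per_day(schedule)
    cycle_ms = schedule.cycle_length_s * 1000
    n_events_per_cycle = max(1, int(schedule.on_cycle_s * within_cycle_hz))
    within_offsets = (
        np.arange(n_events_per_cycle) * (1000.0 / within_cycle_hz)
    ).astype(np.int64)

    root = np.random.SeedSequence(entropy=(seed, 0x57BEA))
    streams = []
    enrollment: dict[str, tuple[str, int]] = {}
    pids = sorted(panel["participant_id"].unique())
    for pid, pseq in zip(pids, root.spawn(len(pids))):
        rng = np.random.default_rng(pseq)
        sub = panel[panel["participant_id"] == pid].sort_values("day_index")
        study_id = sub["study_id"].iloc[0]
        ts_parts = []
        for _, row in sub.iterrows():
            day_start = BASE_EPOCH_MS + int(row["day_index"]) * 86_400_000
            kept = np.sort(
                rng.choice(
                    e_expected, size=e_expected - int(row["y_missing"]), replace=False
                )
            )
            if kept.size:
                cycle_starts = day_start + kept.astype(np.int64) * cycle_ms
                ts_parts.append(
                    (cycle_starts[:, None] + within_offsets[None, :]).ravel()
                )
        ts = np.concatenate(ts_parts) if ts_parts else np.empty(0, dtype=np.int64)
        streams.append(EventStream(pid, study_id, schedule.sensor_name, ts))
        n_days = int(sub["day_index"].max()) + 1
        enrollment[pid] = ("2016-01-01", n_days)
    return streams, enrollment
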