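import pandas as pd
import pytest

from sensormiss.events import MeasurementGrouping
from sensormiss.panel import (
    build_daily_panel,
    complete_case_filter,
    covariate_summary,
    encode_covariates,
    participant_missingness_summary,
    validate_covariates,
)
from sensormiss.simulate import reference_cohort

DAY_MS = 86_400_000


def _groupings(day_offsets_ms):
    return [MeasurementGrouping(t, t + 1000, 2) for t in day_offsets_ms]


class TestBuildDailyPanel:
    def test_full_and_empty_days(self, gps_schedule, small_covariates):
        # p1: day 0 has all 144 groupings, day 1 has none, day 2 has one
        ts = [k * 600_000 for k in range(144)] + [2 * DAY_MS]
        panel = build_daily_panel(
            {"p1": _groupings(ts)}, gps_schedule, small_covariates
        )
        assert len(panel) == 3
        assert panel["y_missing"].tolist() == [0, 144, 143]
        assert panel["e_expected"].tolist() == [144] * 3
        assert panel["day_index"].tolist() == [0, 1, 2]
        assert panel["week"].tolist() == [0.0, 1 / 7, 2 / 7]

    def test_overcount_clipped_at_zero(self, gps_schedule, small_covariates, caplog):
        # 150 groupings in one day exceeds E=144; y clips to 0
        ts = [k * 500_000 for k in range(150) if k * 500_000 < DAY_MS]
        assert len(ts) > 144
        panel = build_daily_panel({"p1": _groupings(ts)}, gps_schedule, small_covariates)
        assert panel.loc[0, "y_missing"] == 0

    def test_grouping_assigned_to_day_of_its_start(self, gps_schedule, small_covariates):
        # grouping starting 1 ms before midnight belongs entirely to day 0
        g = [MeasurementGrouping(DAY_MS - 1, DAY_MS + 5000, 10)]
        panel = build_daily_panel({"p1": g}, gps_schedule, small_covariates)
        assert len(panel) == 1
        assert panel.loc[0, "y_missing"] == 143

    def test_timezone_shifts_day_boundary(self, gps_schedule, small_covariates):
        # 23:30 UTC on Jan 1 1970 is 18:30 in New York: one event just
        # after UTC midnight lands on the same local day
        g = _groupings([DAY_MS - 1_800_000, DAY_MS + 1_800_000])
        utc = build_daily_panel({"p1": g}, gps_schedule, small_covariates)
        nyc = build_daily_panel(
            {"p1": g}, gps_schedule, small_covariates, timezone="America/New_York"
        )
        assert len(utc) == 2
        assert len(nyc) == 1

    def test_unknown_participant_raises_with_id(self, gps_schedule, small_covariates):
        with pytest.raises(KeyError, match="ghost"):
            build_daily_panel(
                {"ghost": _groupings([0])}, gps_schedule, small_covariates
            )

    def test_zero_event_participant_contributes_no_rows(
        self, gps_schedule, small_covariates, caplog
    ):
        panel = build_daily_panel({"p1": []}, gps_schedule, small_covariates)
        assert panel.empty

    def test_enrollment_window_counts_fully_missing_edge_days(
        self, gps_schedule, small_covariates
    ):
        # events only on 1970-01-02, but enrollment covers Jan 1-3
        g = _groupings([DAY_MS + 600_000])
        panel = build_daily_panel(
            {"p1": g},
            gps_schedule,
            small_covariates,
            enrollment={"p1": ("1970-01-01", 3)},
        )
        assert panel["y_missing"].tolist() == [144, 143, 144]

    def test_drop_partial_edge_days(self, gps_schedule, small_covariates):
        g = _groupings([0, DAY_MS, 2 * DAY_MS])
        panel = build_daily_panel(
            {"p1": g}, gps_schedule, small_covariates, drop_partial_edge_days=True
        )
        assert panel["day_index"].tolist() == [1]

    def test_deterministic(self, gps_schedule, small_covariates):
        g = {"p1": _groupings([0, 600_000]), "p2": _groupings([DAY_MS])}
        a = build_daily_panel(g, gps_schedule, small_covariates)
        b = build_daily_panel(g, gps_schedule, small_covariates)
        pd.testing.assert_frame_equal(a, b)

    def test_panel_bounds_invariant(self, tiny_panel):
        panel, _ = tiny_panel
        assert (panel["y_missing"] >= 0).all()
        assert (panel["y_missing"] <= panel["e_expected"]).all()


class TestMissingnessSummary:
    def test_proportions(self, gps_schedule):
        panel = pd.DataFrame(
            {
                "participant_id": ["a"] * 3 + ["b"] * 2 + ["c"],
                "study_id": "s",
                "y_missing": [14, 28, 86, 0, 0, 144],
                "e_expected": 144,
            }
        )
        out = participant_missingness_summary(panel)
        by = out.set_index("participant_id")
        # a: mean of {0.1/0.2/0.6}-ish fractions of 144
        assert by.loc["a", "mean_prop_missing"] == pytest.approx((14 + 28 + 86) / 3 / 144)
        assert by.loc["b", "mean_prop_missing"] == 0.0
        assert by.loc["c", "mean_prop_missing"] == 1.0
        # sorted ascending by mean proportion
        assert out["participant_id"].tolist() == ["b", "a", "c"]
        assert by.loc["a", "days_observed"] == 3

    def test_empty_panel_rejected(self):
        with pytest.raises(ValueError):
            participant_missingness_summary(pd.DataFrame(columns=["y_missing"]))


class TestCompleteCaseFilter:
    def test_identity_when_complete(self, tiny_panel):
        panel, _ = tiny_panel
        out, report = complete_case_filter(panel)
        pd.testing.assert_frame_equal(out, panel)
        assert report.empty

    def test_drops_participant_with_missing_modeled_covariate(
        self, gps_schedule, small_covariates
    ):
        g = {p: _groupings([0]) for p in ["p1", "p2", "p3", "p4"]}
        panel = build_daily_panel(g, gps_schedule, small_covariates)
        out, report = complete_case_filter(panel)
        # p4 has missing gender
        assert set(out["participant_id"]) == {"p1", "p2", "p3"}
        assert report["participant_id"].tolist() == ["p4"]
        assert "male" in report["missing_covariates"].iloc[0]

    def test_unmodeled_missing_field_retained(self, gps_schedule, small_covariates):
        g = {"p4": _groupings([0]), "p1": _groupings([0])}
        panel = build_daily_panel(g, gps_schedule, small_covariates)
        out, _ = complete_case_filter(panel, modeled=("os_ios", "age_decades"))
        assert set(out["participant_id"]) == {"p1", "p4"}

    def test_reference_cohort_overlap_matches_set_union(self, gps_schedule):
        """Participant losses from overlapping missingness equal the size
        of the union of per-covariate missing sets (197 of 211 retained)."""
        cov = reference_cohort()
        enc = encode_covariates(cov)
        union = (
            enc[["os_ios", "male", "degree_4yr_plus", "race", "age_decades"]]
            .isna()
            .any(axis=1)
            .sum()
        )
        g = {p: _groupings([0]) for p in cov["participant_id"]}
        panel = build_daily_panel(g, gps_schedule, cov)
        out, report = complete_case_filter(panel)
        assert len(report) == union
        assert out["participant_id"].nunique() == 211 - union


class TestCovariateSummary:
    def test_reference_marginals(self):
        s = covariate_summary(reference_cohort())
        tab = s.set_index(["variable", "level"])
        assert tab.loc[("participants", "N"), "count"] == 211
        assert tab.loc[("gender", "Female"), "count"] == 140
        assert tab.loc[("gender", "Female"), "percent"] == 66
        assert tab.loc[("os", "Android"), "count"] == 163
        assert tab.loc[("os", "Android"), "percent"] == 77
        assert tab.loc[("race_ethnicity", "non-Hispanic White"), "percent"] == 55

    def test_validation_rejects_unknown_levels(self, small_covariates):
        bad = small_covariates.copy()
        bad.loc[0, "os"] = "Windows Phone"
        with pytest.raises(ValueError, match="Windows Phone"):
            validate_covariates(bad)

    def test_validation_rejects_duplicate_ids(self, small_covariates):
        bad = pd.concat([small_covariates, small_covariates.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate"):
            validate_covariates(bad)
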