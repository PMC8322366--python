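import numpy as np
import pandas as pd
import pytest

from sensormiss.events import segment_events
from sensormiss.panel import build_daily_panel
from sensormiss.schedule import SensorSchedule
from sensormiss.simulate import (
    ConfigError,
    GPS_TRUE_PARAMS,
    SimConfig,
    TrueParams,
    generate_cohort,
    simulate_panel,
    simulate_streams,
)


class TestGenerateCohort:
    def test_deterministic(self, tiny_config):
        a = generate_cohort(tiny_config)
        b = generate_cohort(tiny_config)
        pd.testing.assert_frame_equal(a, b)

    def test_empty(self):
        cfg = SimConfig(n_studies=2, participants_per_study=0)
        assert generate_cohort(cfg).empty

    def test_marginals_converge(self):
        # 10 000 participants: observed female fraction within 3 SE of 0.66
        cfg = SimConfig(n_studies=10, participants_per_study=1000, seed=5)
        cohort = generate_cohort(cfg)
        n = len(cohort)
        p_female = 1.0 - cfg.p_male  # generator has no missing gender
        se = np.sqrt(p_female * (1 - p_female) / n)
        assert (cohort["gender"] == "Female").mean() == pytest.approx(p_female, abs=3 * se)
        se_ios = np.sqrt(0.23 * 0.77 / n)
        assert (cohort["os"] == "iOS").mean() == pytest.approx(0.23, abs=3 * se_ios)
        assert cohort["age_years"].mean() == pytest.approx(25.4, abs=3 * 10.8 / np.sqrt(n))

    def test_adding_participants_preserves_existing_draws(self):
        small = generate_cohort(SimConfig(n_studies=2, participants_per_study=3, seed=9))
        large = generate_cohort(SimConfig(n_studies=2, participants_per_study=5, seed=9))
        merged = large.merge(small, on="participant_id", suffixes=("", "_small"))
        for col in ["os", "gender", "education", "race_ethnicity", "age_years"]:
            assert (merged[col] == merged[f"{col}_small"]).all()

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(p_ios=1.2)
        with pytest.raises(ConfigError):
            SimConfig(race_probs=(0.5, 0.5, 0.2, 0.0, 0.0))


class TestSimulatePanel:
    def test_degenerate_mean(self):
        # beta=0, no random effects, large omega: y/E concentrates on the rate
        cfg = SimConfig(n_studies=2, participants_per_study=10, days_per_participant=200, seed=3)
        params = TrueParams(alpha0=np.log(0.25), omega=1e6)
        panel, truth = simulate_panel(generate_cohort(cfg), params, cfg)
        frac = (panel["y_missing"] / panel["e_expected"]).mean()
        # Poisson-limit MC error: sd(y/E) ~ sqrt(mu)/E over n rows
        n = len(panel)
        se = np.sqrt(0.25 * 144) / 144 / np.sqrt(n)
        assert frac == pytest.approx(0.25, abs=4 * se)

    def test_lognormal_mean_inflation(self):
        # participant heterogeneity sigma=1 inflates E[y/E] to 0.25*exp(0.5)
        cfg = SimConfig(n_studies=4, participants_per_study=250, days_per_participant=10, seed=8)
        params = TrueParams(alpha0=np.log(0.25), sigma_gamma=1.0, omega=1e6)
        panel, truth = simulate_panel(generate_cohort(cfg), params, cfg)
        frac = (panel["y_missing"] / panel["e_expected"]).mean()
        target = 0.25 * np.exp(0.5)
        # dominant MC error: 1000 participant-level lognormal draws
        se = target * np.sqrt((np.exp(1) - 1) / 1000)
        assert frac == pytest.approx(target, abs=4 * se)

    def test_ground_truth_linear_predictor_identity(self, tiny_panel, tiny_config):
        panel, truth = tiny_panel
        e = panel["e_expected"].to_numpy(dtype=float)
        beta = truth.params.beta
        x_cols = {
            "week": panel["week"],
            "os_ios": panel["os_ios"],
            "male": panel["male"],
            "degree_4yr_plus": panel["degree_4yr_plus"],
            "race_black": (panel["race"] == "non-Hispanic Black").astype(float),
            "race_asian": (panel["race"] == "Asian").astype(float),
            "race_amindian": (panel["race"] == "American Indian/Alaska Native").astype(float),
            "race_other": (panel["race"] == "Other/Hispanic").astype(float),
            "age_decades": panel["age_decades"],
        }
        eta = np.log(e) + truth.params.alpha0
        eta = eta + sum(beta.get(k, 0.0) * np.asarray(v) for k, v in x_cols.items())
        eta = eta + truth.gamma[panel["participant_id"]].to_numpy()
        eta = eta + truth.delta[panel["study_id"]].to_numpy()
        np.testing.assert_allclose(np.exp(eta), truth.mu, rtol=1e-12)

    def test_nb_moments(self):
        # 10^5 draws at fixed mu, omega match NB mean and variance
        cfg = SimConfig(
            n_studies=1, participants_per_study=1, days_per_participant=100_000,
            schedule=SensorSchedule("gps", 1, 0), seed=12,
        )
        # E = 86400 so the ceiling never binds at mu ~ 20
        mu, omega = 20.0, 0.7
        params = TrueParams(alpha0=np.log(mu / 86_400), omega=omega)
        panel, truth = simulate_panel(generate_cohort(cfg), params, cfg)
        y = panel["y_missing"].to_numpy()
        var = mu + mu * mu / omega
        assert y.mean() == pytest.approx(mu, abs=4 * np.sqrt(var / y.size))
        # variance of the sample variance for overdispersed counts: bootstrap-free
        # bound via the fourth moment is loose; accept 5% relative
        assert y.var() == pytest.approx(var, rel=0.05)
        assert truth.n_clipped == 0

    def test_clip_rate_recorded(self):
        cfg = SimConfig(n_studies=1, participants_per_study=5, days_per_participant=50, seed=4)
        params = TrueParams(alpha0=np.log(0.9), omega=0.3)  # near the ceiling
        panel, truth = simulate_panel(generate_cohort(cfg), params, cfg)
        assert truth.n_clipped > 0
        assert truth.clip_rate == truth.n_clipped / len(panel)
        assert (panel["y_missing"] <= panel["e_expected"]).all()

    def test_nonfinite_mean_raises(self):
        cfg = SimConfig(n_studies=1, participants_per_study=2, days_per_participant=2, seed=1)
        params = TrueParams(alpha0=1e4)
        with pytest.raises(ConfigError, match="non-finite"):
            simulate_panel(generate_cohort(cfg), params, cfg)


class TestSimulateStreams:
    def test_all_missing_gives_empty_stream(self, gps_schedule):
        panel = pd.DataFrame(
            {
                "participant_id": ["p1"] * 2,
                "study_id": "s1",
                "day_index": [0, 1],
                "y_missing": [144, 144],
                "e_expected": 144,
            }
        )
        streams, enrollment = simulate_streams(panel, gps_schedule, seed=0)
        assert len(streams[0]) == 0
        assert enrollment["p1"] == ("2016-01-01", 2)

    def test_event_count_at_full_collection(self, gps_schedule):
        panel = pd.DataFrame(
            {
                "participant_id": ["p1"],
                "study_id": "s1",
                "day_index": [0],
                "y_missing": [0],
                "e_expected": 144,
            }
        )
        streams, _ = simulate_streams(panel, gps_schedule, seed=0, within_cycle_hz=1.0)
        # 144 retained cycles x 60 events at 1 Hz
        assert len(streams[0]) == 144 * 60

    @pytest.mark.parametrize("seed", range(6))
    def test_round_trip_recovers_simulated_counts(self, seed):
        """Stream-level and panel-level simulation agree exactly."""
        rng = np.random.default_rng(seed)
        on = int(rng.integers(30, 120))
        off = int(rng.integers(240, 900))
        sched = SensorSchedule("gps", on, off)
        cfg = SimConfig(
            n_studies=2, participants_per_study=3,
            days_per_participant=int(rng.integers(3, 9)),
            schedule=sched, seed=seed,
        )
        cohort = generate_cohort(cfg)
        panel, truth = simulate_panel(cohort, GPS_TRUE_PARAMS, cfg)
        streams, enrollment = simulate_streams(panel, sched, seed=seed)
        groupings = {s.participant_id: segment_events(s, sched) for s in streams}
        rebuilt = build_daily_panel(groupings, sched, cohort, enrollment=enrollment)
        merged = panel.merge(
            rebuilt,
            on=["participant_id", "day_index"],
            suffixes=("_sim", "_rebuilt"),
            validate="one_to_one",
        )
        assert len(merged) == len(panel)
        assert (merged["y_missing_sim"] == merged["y_missing_rebuilt"]).all()

    def test_stream_determinism(self, tiny_panel, gps_schedule):
        panel, _ = tiny_panel
        s1, _ = simulate_streams(panel, gps_schedule, seed=7)
        s2, _ = simulate_streams(panel, gps_schedule, seed=7)
        for a, b in zip(s1, s2):
            np.testing.assert_array_equal(a.timestamps_ms, b.timestamps_ms)
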