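import numpy as np
import pandas as pd
import pytest

from actipredict.activity_io import MINUTES_PER_DAY
from actipredict.features import (ClinicalEncoder, FeatureConfig,
                                  aggregate_patient, cooccurrence_features,
                                  cosinor_fit, day_features, dfa_fluctuation,
                                  first_order_stats, rhythm_features,
                                  rhythm_nonparametric, sedentary_metrics,
                                  sleep_semantics)
from conftest import OMEGA, circadian_day

# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

class TestFirstOrder:
    def test_constant_series_degenerate_convention(self):
        out = first_order_stats([5, 5, 5, 5])
        assert out == {"mean": 5, "maximum": 5, "minimum": 5,
                       "skewness": 0, "kurtosis": 0}

    def test_symmetric_sample_zero_skew(self):
        assert first_order_stats([1, 2, 3, 4, 5])["skewness"] == pytest.approx(0)

    def test_matches_direct_moment_formulas(self):
        x = np.array([1.0, 2.0, 3.0, 10.0])
        d = x - x.mean()
        m2, m3, m4 = (d**2).mean(), (d**3).mean(), (d**4).mean()
        out = first_order_stats(x)
        assert out["skewness"] == pytest.approx(m3 / m2**1.5)
        assert out["kurtosis"] == pytest.approx(m4 / m2**2 - 3)
        assert out["mean"] == pytest.approx(4.0)
        assert (out["maximum"], out["minimum"]) == (10, 1)

    def test_empty_series_raises(self):
        with pytest.raises(ValueError):
            first_order_stats([])


# ---------------------------------------------------------------------------
# co-occurrence statistics
# ---------------------------------------------------------------------------

class TestCooccurrence:
    def test_constant_series_delta_matrix(self):
        out = cooccurrence_features(np.full(100, 7.0))
        assert out["energy"] == pytest.approx(1.0)
        assert out["entropy"] == pytest.approx(0.0)
        assert out["inertia"] == pytest.approx(0.0)
        assert out["local_homogeneity"] == pytest.approx(1.0)
        assert out["correlation"] == 1.0

    def test_alternating_two_level_series(self):
        # odd length so pairs (0,1) and (1,0) each occur exactly 50 times
        x = np.append(np.tile([0.0, 1.0], 50), 0.0)
        out = cooccurrence_features(x, levels=2, lag=1)
        assert out["energy"] == pytest.approx(0.5)
        assert out["entropy"] == pytest.approx(1.0)   # 1 bit
        assert out["inertia"] == pytest.approx(1.0)
        assert out["local_homogeneity"] == pytest.approx(0.5)
        assert out["correlation"] == pytest.approx(-1.0)

    def test_random_series_within_invariant_bounds(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            out = cooccurrence_features(rng.normal(size=500))
            assert 0 < out["energy"] <= 1
            assert out["entropy"] >= 0
            assert out["inertia"] >= 0
            assert 0 < out["local_homogeneity"] <= 1
            assert -1 <= out["correlation"] <= 1


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------

class TestDFA:
    def test_constant_series_perfectly_detrended(self):
        assert dfa_fluctuation(np.full(200, 3.0), 20) == pytest.approx(0.0)

    def test_invariant_to_additive_constant(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=512)
        assert dfa_fluctuation(x, 32) == pytest.approx(
            dfa_fluctuation(x + 100.0, 32))

    def test_too_short_series_raises(self):
        with pytest.raises(ValueError):
            dfa_fluctuation(np.arange(30), 20)

    def test_white_noise_scaling_exponent_near_half(self):
        from actipredict.experiments import dfa_noise_slopes
        slopes = dfa_noise_slopes(range(3), length=2**13)
        for s in slopes:
            assert 0.4 <= s <= 0.6


# ---------------------------------------------------------------------------
# semantic features
# ---------------------------------------------------------------------------

class TestSemantics:
    def test_all_zero_day_single_long_bout(self):
        out = sedentary_metrics(np.zeros(MINUTES_PER_DAY))
        assert out["daily_sedentary_time"] == 1440
        assert out["daily_sedentary_bout_count"] == 1

    def test_alternating_steps_no_bouts(self):
        out = sedentary_metrics(np.tile([0.0, 1.0], 720))
        assert out["daily_sedentary_time"] == 720
        assert out["daily_sedentary_bout_count"] == 0

    def test_crafted_runs_count_only_long_ones(self):
        x = np.ones(MINUTES_PER_DAY)
        x[0:5] = 0      # run of 5 — too short
        x[100:110] = 0  # run of 10 — counts
        x[200:230] = 0  # run of 30 — counts
        out = sedentary_metrics(x, bout_min=10)
        assert out["daily_sedentary_bout_count"] == 2
        assert out["daily_sedentary_time"] == 45

    def test_sleep_episode_from_start(self):
        s = np.full(MINUTES_PER_DAY, np.nan)
        s[0:480] = 1  # asleep from minute 0
        out = sleep_semantics(s)
        assert out["time_in_bed"] == 480
        assert out["minutes_to_fall_asleep"] == 0

    def test_sleep_latency(self):
        s = np.full(MINUTES_PER_DAY, np.nan)
        s[100:120] = 0  # 20 awake minutes
        s[120:400] = 1
        out = sleep_semantics(s)
        assert out["minutes_to_fall_asleep"] == 20

    def test_fragmented_episode_hand_enumeration(self):
        s = np.full(MINUTES_PER_DAY, np.nan)
        s[60:80] = 0     # awake 20 min
        s[80:180] = 1    # light
        s[180:190] = 0   # brief awakening
        s[190:240] = 2   # deep
        out = sleep_semantics(s)
        assert out["time_in_bed"] == 239 - 60 + 1
        assert out["minutes_to_fall_asleep"] == 20

    def test_no_sleep_records_missing(self):
        out = sleep_semantics(np.full(MINUTES_PER_DAY, np.nan))
        assert np.isnan(out["time_in_bed"])
        assert np.isnan(out["minutes_to_fall_asleep"])


# ---------------------------------------------------------------------------
# rhythm features
# ---------------------------------------------------------------------------

class TestRhythm:
    def test_periodic_signal_has_unit_stability(self):
        t = np.arange(MINUTES_PER_DAY)
        day = 50 + 40 * np.cos(OMEGA * (t - 900))
        X = np.tile(day, (7, 1))
        out = rhythm_nonparametric(X)
        assert out["IS"] == pytest.approx(1.0)

    def test_constant_series_degenerate(self):
        out = rhythm_nonparametric(np.full((3, MINUTES_PER_DAY), 5.0))
        assert np.isnan(out["IS"])
        assert out["amplitude"] == 0
        assert out["relative_amplitude"] == 0

    def test_square_wave_profile_closed_form(self):
        # 10 active hours at 100 (hours 9-18 inclusive), the rest 0
        day = np.zeros(MINUTES_PER_DAY)
        day[9 * 60:19 * 60] = 100.0
        out = rhythm_nonparametric(np.tile(day, (3, 1)))
        assert out["M10"] == pytest.approx(100.0)
        assert out["L5"] == pytest.approx(0.0)
        assert out["relative_amplitude"] == pytest.approx(1.0)

    def test_bounds_on_random_nonnegative_series(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            X = rng.gamma(1.0, 2.0, size=(4, MINUTES_PER_DAY))
            out = rhythm_nonparametric(X)
            assert out["M10"] >= out["L5"]
            assert 0 <= out["relative_amplitude"] <= 1


class TestCosinor:
    def test_noiseless_recovery_to_1e6(self):
        t = np.arange(3 * MINUTES_PER_DAY)
        y = 10 + 3 * np.cos(OMEGA * t + 1.0)
        out = cosinor_fit(t, y)
        assert out["MESOR"] == pytest.approx(10.0, abs=1e-6)
        assert out["amplitude"] == pytest.approx(3.0, abs=1e-6)
        assert out["phase"] == pytest.approx(1.0, abs=1e-6)
        assert out["log_amplitude"] == pytest.approx(np.log(3.0), abs=1e-6)

    def test_constant_series(self):
        t = np.arange(2 * MINUTES_PER_DAY)
        out = cosinor_fit(t, np.full(t.size, 7.0))
        assert out["MESOR"] == pytest.approx(7.0)
        assert out["amplitude"] == pytest.approx(0.0, abs=1e-9)

    def test_under_24h_span_raises(self):
        t = np.arange(1000)
        with pytest.raises(ValueError):
            cosinor_fit(t, np.sin(t / 100))

    def test_noisy_amplitude_within_three_standard_errors(self):
        t = np.arange(3 * MINUTES_PER_DAY)
        sigma = 1.0
        se = sigma * np.sqrt(2.0 / t.size)
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = 10 + 3 * np.cos(OMEGA * t + 1.0) + rng.normal(0, sigma, t.size)
            out = cosinor_fit(t, y)
            assert abs(out["amplitude"] - 3.0) <= 3 * se


# ---------------------------------------------------------------------------
# aggregation
# ---------------------------------------------------------------------------

class TestAggregate:
    def _daily(self, values):
        return pd.DataFrame({"mean of steps": values})

    def _rhythm(self):
        return pd.Series({"Relative amplitude of steps": 0.5})

    def test_identical_days_zero_variance(self):
        out = aggregate_patient(self._daily([4.0] * 5), self._rhythm())
        assert out["Mean of mean of steps"] == 4.0
        assert out["Variance of mean of steps"] == 0.0

    def test_sample_variance_two_days(self):
        out = aggregate_patient(self._daily([2.0, 4.0]), self._rhythm())
        assert out["Mean of mean of steps"] == pytest.approx(3.0)
        # sample variance with ddof=1: ((2-3)^2 + (4-3)^2) / 1 = 2
        assert out["Variance of mean of steps"] == pytest.approx(2.0)

    def test_single_day_variance_zero(self):
        out = aggregate_patient(self._daily([2.0]), self._rhythm())
        assert out["Variance of mean of steps"] == 0.0

    @pytest.mark.parametrize("n_days", [2, 5, 9])
    def test_dimension_invariant_to_monitoring_length(self, n_days):
        cfg = FeatureConfig()
        days = [circadian_day(seed=i) for i in range(n_days)]
        daily = pd.DataFrame([day_features(d, cfg) for d in days])
        out = aggregate_patient(daily, rhythm_features(days, cfg))
        if not hasattr(TestAggregate, "_dim"):
            TestAggregate._dim = out.index.tolist()
        assert out.index.tolist() == TestAggregate._dim

    def test_dfa_feature_naming_convention(self):
        days = [circadian_day(seed=i) for i in range(2)]
        daily = pd.DataFrame([day_features(d) for d in days])
        out = aggregate_patient(daily, rhythm_features(days))
        assert "Mean DFA of heart rate with 40-minute window" in out.index
        assert "Intradaily stability of steps with 60-minute window" in out.index


# ---------------------------------------------------------------------------
# clinical encoding
# ---------------------------------------------------------------------------

class TestClinicalEncoder:
    frame = pd.DataFrame({
        "tobacco_category": ["never", "active_gt10py", "active_lt10py",
                             "past_gt30py", "past_lt30py", "never"],
        "prior_surgery": [1, 0, 1, 0, 1, 0],
        "neutrophils": [50.0, 30.0, 40.0, 45.0, 35.0, 55.0],
    })

    def test_five_level_field_gives_five_indicators(self):
        enc = ClinicalEncoder(categorical=("tobacco_category",), continuous=())
        X = enc.fit_transform(self.frame)
        assert X.shape[1] == 5
        assert X.sum(axis=1).tolist() == [1.0] * 6

    def test_binary_field_single_column(self):
        enc = ClinicalEncoder(categorical=("prior_surgery",), continuous=())
        X = enc.fit_transform(self.frame)
        assert list(X.columns) == ["prior_surgery=1"]
        assert X["prior_surgery=1"].tolist() == [1, 0, 1, 0, 1, 0]

    def test_round_trip_decode(self):
        enc = ClinicalEncoder(categorical=("tobacco_category", "prior_surgery"),
                              continuous=("neutrophils",))
        X = enc.fit_transform(self.frame)
        decoded = enc.decode(X)
        assert decoded["tobacco_category"].tolist() == \
            self.frame["tobacco_category"].tolist()
        assert [int(v) for v in decoded["prior_surgery"]] == \
            self.frame["prior_surgery"].tolist()

    def test_unseen_category_all_zero_with_warning(self):
        enc = ClinicalEncoder(categorical=("tobacco_category",), continuous=())
        enc.fit(self.frame)
        new = pd.DataFrame({"tobacco_category": ["pipe_smoker"]})
        with pytest.warns(UserWarning, match="unseen"):
            X = enc.transform(new)
        assert X.iloc[0].sum() == 0
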