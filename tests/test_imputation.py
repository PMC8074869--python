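import numpy as np
import pandas as pd
import pytest

from actipredict.activity_io import MINUTES_PER_DAY, PatientRecord
from actipredict.imputation import (ImputationConfig, ImputationPolicyError,
                                    apply_missing_policy, impute_data_level,
                                    impute_feature_level)
from conftest import circadian_day, make_day


def brute_force_nearest(day, missing_minute, w):
    """Exhaustive nearest-neighbour search under the stated window distance."""
    hr, steps = day.heart_rate, day.steps
    hr_fill, steps_fill = np.nanmean(hr), np.nanmean(steps)

    def window(x, m, fill):
        vals = []
        for i in range(m - w, m + w + 1):
            v = x[i] if 0 <= i < MINUTES_PER_DAY else np.nan
            vals.append(fill if np.isnan(v) else v)
        return np.array(vals)

    query = np.concatenate([window(steps, missing_minute, steps_fill),
                            window(hr, missing_minute, hr_fill)])
    best, best_d = None, np.inf
    for m in range(MINUTES_PER_DAY):
        if np.isnan(hr[m]):
            continue
        cand = np.concatenate([window(steps, m, steps_fill),
                               window(hr, m, hr_fill)])
        d = float(np.sum((cand - query) ** 2))
        if d < best_d:
            best, best_d = m, d
    return hr[best]


class TestDataLevel:
    def test_complete_day_identity(self):
        day = circadian_day(0)
        out = impute_data_level(day, ImputationConfig())
        np.testing.assert_array_equal(out.heart_rate, day.heart_rate)

    def test_single_missing_minute_matches_brute_force(self):
        cfg = ImputationConfig(k_data=1)
        for seed in range(3):
            day = circadian_day(seed)
            truth = day.heart_rate.copy()
            m = 700 + 13 * seed
            day.heart_rate[m] = np.nan
            expected = brute_force_nearest(day, m, cfg.window_minutes)
            out = impute_data_level(day, cfg)
            assert out.heart_rate[m] == pytest.approx(expected)
            # all other minutes untouched
            keep = np.arange(MINUTES_PER_DAY) != m
            np.testing.assert_array_equal(out.heart_rate[keep], truth[keep])

    def test_below_threshold_is_policy_error(self):
        hr = np.full(MINUTES_PER_DAY, np.nan)
        hr[:72] = 70.0  # yield 0.05
        day = make_day(heart_rate=hr)
        with pytest.raises(ImputationPolicyError):
            impute_data_level(day, ImputationConfig())

    def test_observed_values_never_modified_and_idempotent(self):
        rng = np.random.default_rng(9)
        day = circadian_day(4)
        idx = rng.choice(MINUTES_PER_DAY, size=300, replace=False)
        observed_before = np.delete(day.heart_rate.copy(), idx)
        day.heart_rate[idx] = np.nan
        cfg = ImputationConfig()
        out = impute_data_level(day, cfg)
        np.testing.assert_array_equal(
            np.delete(out.heart_rate, idx), observed_before)
        again = impute_data_level(out, cfg)
        np.testing.assert_array_equal(again.heart_rate, out.heart_rate)

    def test_recovery_beats_global_mean_on_circadian_days(self):
        from actipredict.experiments import imputation_benchmark
        for row in imputation_benchmark(range(3)):
            assert row["knn_rmse"] < row["global_mean_rmse"]


class TestFeatureLevel:
    donors = pd.DataFrame({"a": [1.0, 3.0], "b": [10.0, 20.0]})

    def test_no_gaps_identity(self):
        day = pd.Series({"a": 2.0, "b": 15.0})
        out = impute_feature_level(day, self.donors, k_feature=2)
        pd.testing.assert_series_equal(out, day)

    def test_single_donor_copies_value(self):
        day = pd.Series({"a": 1.0, "b": np.nan})
        out = impute_feature_level(day, self.donors.iloc[[1]], k_feature=1)
        assert out["b"] == 20.0

    def test_two_donors_k2_gives_mean(self):
        day = pd.Series({"a": 2.0, "b": np.nan})
        out = impute_feature_level(day, self.donors, k_feature=2)
        assert out["b"] == pytest.approx((10.0 + 20.0) / 2)

    def test_no_donors_raises(self):
        with pytest.raises(ValueError):
            impute_feature_level(pd.Series({"a": np.nan, "b": 1.0}),
                                 self.donors.iloc[[]], k_feature=1)


class TestRouting:
    def _patient(self, yields):
        days = []
        for i, y in enumerate(yields):
            hr = np.full(MINUTES_PER_DAY, np.nan)
            n = int(round(y * MINUTES_PER_DAY))
            hr[:n] = 70.0
            day = circadian_day(i)
            day.heart_rate = np.where(np.arange(MINUTES_PER_DAY) < n,
                                      day.heart_rate, np.nan)
            days.append(day)
        return PatientRecord("X", {}, days)

    def test_routing_table(self):
        patient = self._patient([0.0, 0.05, 0.8])
        routed, audit = apply_missing_policy(patient, ImputationConfig())
        assert list(audit["route"]) == ["discard", "feature_level", "data_level"]
        assert len(routed.days) == 2

    def test_all_complete_days_retained_untouched(self):
        patient = self._patient([1.0, 1.0])
        routed, audit = apply_missing_policy(patient, ImputationConfig())
        assert list(audit["route"]) == ["complete", "complete"]
        assert len(routed.days) == 2

    def test_zero_usable_days_flagged(self):
        patient = self._patient([0.0])
        with pytest.raises(ValueError, match="no usable days"):
            apply_missing_policy(patient, ImputationConfig())

    def test_masked_patient_series_complete_after_policy(self):
        rng = np.random.default_rng(21)
        days = []
        for i in range(10):
            day = circadian_day(i)
            idx = rng.choice(MINUTES_PER_DAY, size=288, replace=False)  # 20%
            day.heart_rate[idx] = np.nan
            days.append(day)
        routed, audit = apply_missing_policy(PatientRecord("Y", {}, days),
                                             ImputationConfig())
        assert (audit["route"] == "data_level").all()
        for day in routed.days:
            assert not np.any(np.isnan(day.heart_rate))
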