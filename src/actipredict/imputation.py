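"""Two-level missing-data handling for wearable heart-rate series.

Routing by daily yield (fraction of the 1440 expected heart-rate minutes
present):

* yield = 0            — the day is discarded;
* 0 < yield < 10%      — too sparse to reconstruct the series; the day's
                         *features* are later imputed from the same patient's
                         other days (feature-level route);
* yield >= 10%         — missing heart-rate minutes are filled in place by
                         KNN over (step-count, heart-rate) sliding-window
                         profiles within the same day (data-level route).

Observed values are never modified by either route.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity_io import MINUTES_PER_DAY, ActivityDay, PatientRecord

ROUTE_DISCARD = "discard"
ROUTE_FEATURE = "feature_level"
ROUTE_DATA = "data_level"
ROUTE_NONE = "complete"


class ImputationPolicyError(ValueError):
    """A day was sent down the wrong imputation route."""


@dataclass
class ImputationConfig:
    """Knobs of the two-level scheme.

    data_level_threshold: minimum yield for series-level (data-level) KNN.
    k_data: neighbours averaged when filling a missing heart-rate minute.
    window_minutes: half-width of the sliding window whose (steps, heart-rate)
        profile defines the neighbour distance.
    k_feature: neighbours (donor days) averaged in feature-level imputation.
    """

    data_level_threshold: float = 0.10
    k_data: int = 5
    window_minutes: int = 5
    k_feature: int = 3

    def __post_init__(self) -> None:
        if not 0 < self.data_level_threshold < 1:
            raise ValueError("data_level_threshold must be in (0, 1)")
        if self.k_data < 1 or self.k_feature < 1 or self.window_minutes < 1:
            raise ValueError("k_data, k_feature, window_minutes must be >= 1")


def _padded_windows(x: np.ndarray, w: int, fill: float) -> np.ndarray:
    """(1440, 2w+1) view of sliding windows, NaNs and edges mean-padded."""
    x = np.where(np.isnan(x), fill, x)
    x = np.pad(x, w, mode="constant", constant_values=fill)
    return np.lib.stride_tricks.sliding_window_view(x, 2 * w + 1)


def impute_data_level(day: ActivityDay, cfg: ImputationConfig) -> ActivityDay:
    """Fill every missing heart-rate minute of a day with yield >= threshold.

    Each missing minute receives the unweighted mean heart rate of its
    ``cfg.k_data`` nearest observed minutes of the same day, where distance is
    Euclidean over the concatenated (steps, heart-rate) profile of a sliding
    window of half-width ``cfg.window_minutes`` around each minute; missing
    entries inside any candidate window are padded with the day's channel
    mean.  Observed values are returned unchanged (idempotent on complete
    days).
    """
    if day.data_yield < cfg.data_level_threshold:
        raise ImputationPolicyError(
            f"day {day.date} has yield {day.data_yield:.3f} < "
            f"{cfg.data_level_threshold}; route it to feature-level imputation"
        )
    hr = day.heart_rate
    missing = np.flatnonzero(np.isnan(hr))
    if missing.size == 0:
        return day

    observed = np.flatnonzero(~np.isnan(hr))
    hr_fill = float(np.nanmean(hr))
    steps_fill = float(np.nanmean(day.steps)) if not np.all(np.isnan(day.steps)) else 0.0
    w = cfg.window_minutes
    prof = np.hstack([
        _padded_windows(day.steps, w, steps_fill),
        _padded_windows(hr, w, hr_fill),
    ])  # (1440, 2*(2w+1))

    out = day.copy()
    k = min(cfg.k_data, observed.size)
    # pairwise squared distances missing x observed
    diff = prof[missing][:, None, :] - prof[observed][None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    # stable argsort: ties broken by candidate minute order
    nn = np.argsort(d2, axis=1, kind="stable")[:, :k]
    out.heart_rate[missing] = hr[observed][nn].mean(axis=1)
    return out


def impute_feature_level(
    day_features: pd.Series,
    donor_features: pd.DataFrame,
    k_feature: int = 3,
) -> pd.Series:
    """Fill missing day-feature values by KNN over the patient's other days.

    Distance between the gappy day and each donor day is Euclidean over the
    features observed in both (each feature z-scored by the donor pool's
    spread so no single scale dominates).  Each missing feature is the
    unweighted mean of the ``k_feature`` nearest donors that observed it.
    Observed entries are untouched.
    """
    if donor_features.shape[0] == 0:
        raise ValueError("no donor days available for feature-level imputation")
    filled = day_features.copy()
    gaps = day_features.index[day_features.isna()]
    if len(gaps) == 0:
        return filled
    observed_cols = day_features.index[day_features.notna()]
    if len(observed_cols) == 0:
        raise ValueError("day has no observed features; cannot anchor donors")

    scale = donor_features[observed_cols].std(ddof=0).replace(0.0, 1.0).fillna(1.0)
    query = (day_features[observed_cols] / scale).to_numpy(dtype=float)
    donors = (donor_features[observed_cols] / scale).to_numpy(dtype=float)
    # mean-pad donor gaps inside the anchor columns
    col_means = np.nanmean(np.vstack([donors, query]), axis=0)
    donors = np.where(np.isnan(donors), col_means, donors)
    d2 = ((donors - query) ** 2).sum(axis=1)
    order = np.argsort(d2, kind="stable")

    for col in gaps:
        have = donor_features[col].notna().to_numpy()
        ranked = [i for i in order if have[i]][:k_feature]
        if ranked:
            filled[col] = float(donor_features[col].to_numpy()[ranked].mean())
    return filled


def route_for_yield(y: float, cfg: ImputationConfig) -> str:
    if y == 0:
        return ROUTE_DISCARD
    if y < cfg.data_level_threshold:
        return ROUTE_FEATURE
    return ROUTE_DATA


def apply_missing_policy(
    patient: PatientRecord, cfg: ImputationConfig | None = None
) -> tuple[PatientRecord, pd.DataFrame]:
    """Route every day of a patient through the two-level scheme.

    Returns the patient with zero-yield days dropped, data-level days fully
    imputed, and feature-level days retained as-is (their features are imputed
    downstream), together with an audit table (patient_id, date, yield, route).
    Raises if no usable day remains.
    """
    cfg = cfg or ImputationConfig()
    kept: list[ActivityDay] = []
    audit_rows = []
    for day in patient.days:
        y = day.data_yield
        route = route_for_yield(y, cfg)
        if route == ROUTE_DATA:
            complete = not np.any(np.isnan(day.heart_rate))
            kept.append(day if complete else impute_data_level(day, cfg))
            route = ROUTE_NONE if complete else ROUTE_DATA
        elif route == ROUTE_FEATURE:
            kept.append(day)
        audit_rows.append(
            {"patient_id": patient.patient_id, "date": day.date,
             "yield": y, "route": route}
        )
    if not kept:
        raise ValueError(f"patient {patient.patient_id} has no usable days")
    routed = PatientRecord(patient.patient_id, patient.clinical, kept,
                           patient.outcome)
    return routed, pd.DataFrame(audit_rows)
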