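"""Feature engineering for minute-level wearable series.

Three families of features are extracted from the daily step-count,
heart-rate and sleep-stage series:

* statistical — first-order moments (mean, maximum, minimum, skewness,
  kurtosis), second-order co-occurrence statistics (energy, entropy,
  correlation, inertia, local homogeneity) of the quantized series, and the
  detrended-fluctuation-analysis (DFA) fluctuation at fixed window lengths;
* semantic — daily activity/sleep summaries: time in bed, minutes to fall
  asleep, daily sedentary time, daily sedentary bout count;
* biobehavioral rhythm — nonparametric circadian metrics (intradaily
  stability IS, intradaily variability IV, L5, M10, amplitude, relative
  amplitude) and a fixed 24-h cosinor fit (MESOR, amplitude, log amplitude,
  phase), computed over the whole monitoring period.

Daily features are aggregated to their per-patient mean and variance so the
final vector has the same dimension regardless of monitoring length; rhythm
features enter once per patient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity_io import MINUTES_PER_DAY, ActivityDay

_OMEGA = 2.0 * np.pi / MINUTES_PER_DAY  # 24-h angular frequency per minute


# ---------------------------------------------------------------------------
# first-order statistics
# ---------------------------------------------------------------------------

def first_order_stats(series) -> dict[str, float]:
    """Mean, maximum, minimum, and moment-based skewness / excess kurtosis.

    Uses the biased moment estimators g1 = m3 / m2^(3/2) and
    g2 = m4 / m2^2 - 3; a constant series (m2 = 0) maps both to 0 by
    convention.  Raises on an empty series.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        raise ValueError("first_order_stats requires a non-empty series")
    m = x.mean()
    d = x - m
    m2 = np.mean(d * d)
    if m2 == 0:
        skew, kurt = 0.0, 0.0
    else:
        skew = np.mean(d**3) / m2**1.5
        kurt = np.mean(d**4) / m2**2 - 3.0
    return {
        "mean": float(m),
        "maximum": float(x.max()),
        "minimum": float(x.min()),
        "skewness": float(skew),
        "kurtosis": float(kurt),
    }


# ---------------------------------------------------------------------------
# co-occurrence (second-order) statistics
# ---------------------------------------------------------------------------

def _quantize(x: np.ndarray, levels: int) -> np.ndarray:
    """Equal-frequency quantization to at most `levels` integer bins."""
    qs = np.quantile(x, np.linspace(0, 1, levels + 1)[1:-1])
    edges = np.unique(qs)
    # side="left": a value equal to an edge stays in the lower bin, so a
    # two-valued series with levels=2 keeps both levels distinct
    return np.searchsorted(edges, x, side="left")


def cooccurrence_features(series, levels: int = 8, lag: int = 1) -> dict[str, float]:
    """Energy, entropy, correlation, inertia and local homogeneity of the
    normalized co-occurrence matrix of (x_t, x_{t+lag}) after equal-frequency
    quantization into `levels` bins.

    The degenerate case of zero marginal spread returns correlation 1.
    """
    x = np.asarray(series, dtype=float)
    if levels < 2:
        raise ValueError("levels must be >= 2")
    ok = ~np.isnan(x)
    pair_ok = ok[:-lag] & ok[lag:]
    if x.size <= lag or not np.any(pair_ok):
        raise ValueError("series too short (or too gappy) for the requested lag")

    q = np.zeros_like(x, dtype=int)
    q[ok] = _quantize(x[ok], levels)
    n_lvl = int(q[ok].max()) + 1
    i, j = q[:-lag][pair_ok], q[lag:][pair_ok]
    counts = np.bincount(i * n_lvl + j, minlength=n_lvl * n_lvl).reshape(n_lvl, n_lvl)
    P = counts / counts.sum()

    ii, jj = np.meshgrid(np.arange(n_lvl), np.arange(n_lvl), indexing="ij")
    nz = P > 0
    energy = float((P * P).sum())
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())
    inertia = float(((ii - jj) ** 2 * P).sum())
    homogeneity = float((P / (1.0 + (ii - jj) ** 2)).sum())
    mu_i, mu_j = (ii * P).sum(), (jj * P).sum()
    var_i = ((ii - mu_i) ** 2 * P).sum()
    var_j = ((jj - mu_j) ** 2 * P).sum()
    if var_i <= 0 or var_j <= 0:
        corr = 1.0
    else:
        corr = float(((ii - mu_i) * (jj - mu_j) * P).sum() / np.sqrt(var_i * var_j))
    return {
        "energy": energy,
        "entropy": entropy,
        "correlation": corr,
        "inertia": inertia,
        "local_homogeneity": homogeneity,
    }


# ---------------------------------------------------------------------------
# detrended fluctuation analysis
# ---------------------------------------------------------------------------

def dfa_fluctuation(series, window_minutes: int) -> float:
    """Root-mean-square fluctuation F(n) of the integrated, per-window
    linearly detrended series, at the single window length ``window_minutes``.

    The series is mean-centered and cumulatively summed (the profile), split
    into non-overlapping windows, a least-squares line is removed per window,
    and F is the RMS of the pooled residuals.  Invariant to adding a constant
    to the input; 0 for a constant series.
    """
    x = np.asarray(series, dtype=float)
    x = x[~np.isnan(x)]
    n = int(window_minutes)
    if x.size < 2 * n:
        raise ValueError(f"need at least {2 * n} points for window {n}")
    profile = np.cumsum(x - x.mean())
    m = x.size // n
    Y = profile[: m * n].reshape(m, n).T  # (n, m)
    t = np.arange(n, dtype=float)
    A = np.column_stack([t, np.ones(n)])
    coef, *_ = np.linalg.lstsq(A, Y, rcond=None)
    resid = Y - A @ coef
    return float(np.sqrt(np.mean(resid * resid)))


def dfa_slope(series, window_lengths) -> float:
    """Log-log slope of F(n) versus n — the DFA scaling exponent utility."""
    fs = np.array([dfa_fluctuation(series, n) for n in window_lengths])
    return float(np.polyfit(np.log(window_lengths), np.log(fs), 1)[0])


# ---------------------------------------------------------------------------
# semantic features
# ---------------------------------------------------------------------------

def sedentary_metrics(step_series, bout_min: int = 10) -> dict[str, float]:
    """Daily sedentary time and sedentary bout count from a 1440-slot day.

    A sedentary minute is an *observed* minute with 0 steps (missing minutes
    are excluded from the accounting and break runs); a bout is a maximal run
    of at least ``bout_min`` consecutive sedentary minutes.
    """
    x = np.asarray(step_series, dtype=float)
    sedentary = (~np.isnan(x)) & (x == 0)
    time = int(np.count_nonzero(sedentary))
    padded = np.concatenate([[False], sedentary, [False]])
    starts = np.flatnonzero(padded[1:] & ~padded[:-1])
    ends = np.flatnonzero(~padded[1:] & padded[:-1])
    bouts = int(np.count_nonzero((ends - starts) >= bout_min))
    return {"daily_sedentary_time": float(time),
            "daily_sedentary_bout_count": float(bouts)}


def sleep_semantics(sleep_series) -> dict[str, float]:
    """Time in bed and sleep-onset latency from a day's sleep-stage series.

    Time in bed spans first to last recorded sleep-stage minute; minutes to
    fall asleep counts from the episode start until the first non-awake
    stage.  With no sleep records both features are missing (NaN), which
    makes them eligible for feature-level imputation downstream.
    """
    s = np.asarray(sleep_series, dtype=float)
    idx = np.flatnonzero(~np.isnan(s))
    if idx.size == 0:
        return {"time_in_bed": np.nan, "minutes_to_fall_asleep": np.nan}
    time_in_bed = float(idx[-1] - idx[0] + 1)
    asleep = idx[s[idx] > 0]
    latency = float(asleep[0] - idx[0]) if asleep.size else np.nan
    return {"time_in_bed": time_in_bed, "minutes_to_fall_asleep": latency}


# ---------------------------------------------------------------------------
# biobehavioral rhythm features
# ---------------------------------------------------------------------------

def rhythm_nonparametric(day_matrix, bin_minutes: int = 60) -> dict[str, float]:
    """Nonparametric circadian metrics from a (n_days, 1440) value matrix.

    IS — intradaily stability: variance of the 24-h mean profile over total
    variance, on ``bin_minutes`` epochs (1 for a perfectly day-periodic
    signal, ~0 for noise); undefined (NaN) for a constant series.
    IV — intradaily variability: normalized mean square successive
    difference, indexing hour-to-hour fragmentation.
    L5 / M10 — mean of the least-active 5 / most-active 10 *contiguous*
    hours of the circular average 24-h profile; amplitude = M10 - L5;
    relative amplitude = (M10 - L5)/(M10 + L5), set to 0 when M10 + L5 = 0.
    """
    X = np.atleast_2d(np.asarray(day_matrix, dtype=float))
    if X.shape[1] != MINUTES_PER_DAY:
        raise ValueError("day_matrix must have 1440 columns")
    p = MINUTES_PER_DAY // bin_minutes
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        binned = np.nanmean(X.reshape(X.shape[0], p, bin_minutes), axis=2)
        flat = binned.reshape(-1)
        ok = ~np.isnan(flat)
        N = int(ok.sum())
        grand = np.nanmean(flat)
        profile = np.nanmean(binned, axis=0)  # 24-h mean profile on epochs
        total_ss = np.nansum((flat - grand) ** 2)
        if total_ss > 0 and N > 1:
            IS = float(N * np.nansum((profile - grand) ** 2) / (p * total_ss))
            seq = flat[ok]
            IV = float(N * np.sum(np.diff(seq) ** 2) / ((N - 1) * total_ss))
        else:
            IS, IV = np.nan, np.nan
        hourly = np.nanmean(
            np.nanmean(X.reshape(X.shape[0], 24, 60), axis=2), axis=0
        )
    wrapped = np.concatenate([hourly, hourly])
    win10 = np.array([wrapped[h:h + 10].mean() for h in range(24)])
    win5 = np.array([wrapped[h:h + 5].mean() for h in range(24)])
    M10, L5 = float(np.nanmax(win10)), float(np.nanmin(win5))
    amplitude = M10 - L5
    denom = M10 + L5
    rel_amp = amplitude / denom if denom > 0 else 0.0
    return {"IS": IS, "IV": IV, "L5": L5, "M10": M10,
            "amplitude": amplitude, "relative_amplitude": float(rel_amp)}


def cosinor_fit(minutes, values) -> dict[str, float]:
    """Least-squares fixed-period (24 h) cosinor fit.

    Fits y(t) = MESOR + A*cos(2*pi*t/1440 + phi) through the linear
    parameterization beta1*cos + beta2*sin; A >= 0 and phi in [-pi, pi).
    ``minutes`` are absolute minute timestamps (may span many days) and must
    cover at least 24 h.  log_amplitude = ln A, missing when A = 0.
    """
    t = np.asarray(minutes, dtype=float)
    y = np.asarray(values, dtype=float)
    ok = ~np.isnan(y) & ~np.isnan(t)
    t, y = t[ok], y[ok]
    if t.size < 3:
        raise ValueError("cosinor fit is under-determined (fewer than 3 points)")
    if t.max() - t.min() < MINUTES_PER_DAY:
        raise ValueError("cosinor fit requires at least 24 h of data")
    A = np.column_stack([np.ones_like(t), np.cos(_OMEGA * t), np.sin(_OMEGA * t)])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    mesor, b1, b2 = beta
    amp = float(np.hypot(b1, b2))
    phase = float(np.arctan2(-b2, b1)) if amp > 0 else 0.0
    if phase >= np.pi:  # wrap to [-pi, pi)
        phase -= 2 * np.pi
    return {
        "MESOR": float(mesor),
        "amplitude": amp,
        "log_amplitude": float(np.log(amp)) if amp > 0 else np.nan,
        "phase": phase,
    }


# ---------------------------------------------------------------------------
# per-day assembly and per-patient aggregation
# ---------------------------------------------------------------------------

@dataclass
class FeatureConfig:
    """Featurization knobs (all with fixed, documented defaults)."""

    dfa_windows: tuple = (30, 40, 50, 60)
    cooccurrence_levels: int = 8
    cooccurrence_lag: int = 1
    bout_min: int = 10
    rhythm_bin_minutes: int = 60


_CHANNEL_LABELS = {"steps": "steps", "heart_rate": "heart rate",
                   "sleep_stage": "sleep stages"}
_FIRST_ORDER = ("mean", "maximum", "minimum", "skewness", "kurtosis")
_COOC = ("energy", "entropy", "correlation", "inertia", "local_homogeneity")
_COOC_LABELS = {"local_homogeneity": "local homogeneity"}
_SEMANTIC_LABELS = {
    "time_in_bed": "time in bed",
    "minutes_to_fall_asleep": "minutes to fall asleep",
    "daily_sedentary_time": "daily sedentary time",
    "daily_sedentary_bout_count": "daily sedentary bout count",
}


def day_features(day: ActivityDay, cfg: FeatureConfig | None = None) -> pd.Series:
    """All daily (statistical + semantic) features of one ActivityDay.

    Features that cannot be computed from the day's observed minutes (e.g.
    DFA on a sparse day, sleep semantics of a day without sleep records) are
    NaN — the feature-level imputation route fills them later.
    """
    cfg = cfg or FeatureConfig()
    out: dict[str, float] = {}
    for chan, label in _CHANNEL_LABELS.items():
        x = getattr(day, chan)
        obs = x[~np.isnan(x)]
        if obs.size:
            fo = first_order_stats(obs)
            for k in _FIRST_ORDER:
                out[f"{k} of {label}"] = fo[k]
            try:
                co = cooccurrence_features(obs, cfg.cooccurrence_levels,
                                           cfg.cooccurrence_lag)
            except ValueError:
                co = {k: np.nan for k in _COOC}
            for k in _COOC:
                out[f"{_COOC_LABELS.get(k, k)} of {label}"] = co[k]
        else:
            for k in _FIRST_ORDER:
                out[f"{k} of {label}"] = np.nan
            for k in _COOC:
                out[f"{_COOC_LABELS.get(k, k)} of {label}"] = np.nan
        for w in cfg.dfa_windows:
            try:
                f = dfa_fluctuation(obs, w)
            except ValueError:
                f = np.nan
            out[f"DFA of {label} with {w}-minute window"] = f
    sed = sedentary_metrics(day.steps, cfg.bout_min)
    slp = sleep_semantics(day.sleep_stage)
    for k, v in {**sed, **slp}.items():
        out[_SEMANTIC_LABELS[k]] = v
    return pd.Series(out, dtype=float)


def rhythm_features(days: list[ActivityDay],
                    cfg: FeatureConfig | None = None) -> pd.Series:
    """Whole-period rhythm features for the steps and heart-rate channels."""
    cfg = cfg or FeatureConfig()
    if len(days) < 2:
        raise ValueError("rhythm features need at least 2 days")
    out: dict[str, float] = {}
    base = min(d.date for d in days)
    for chan in ("steps", "heart_rate"):
        label = _CHANNEL_LABELS[chan]
        mat = np.vstack([getattr(d, chan) for d in days])
        np_feats = rhythm_nonparametric(mat, cfg.rhythm_bin_minutes)
        b = cfg.rhythm_bin_minutes
        out[f"Intradaily stability of {label} with {b}-minute window"] = np_feats["IS"]
        out[f"Intradaily variability of {label} with {b}-minute window"] = np_feats["IV"]
        out[f"L5 of {label}"] = np_feats["L5"]
        out[f"M10 of {label}"] = np_feats["M10"]
        out[f"Amplitude of {label}"] = np_feats["amplitude"]
        out[f"Relative amplitude of {label}"] = np_feats["relative_amplitude"]
        # absolute minute timestamps across the monitoring period
        offsets = np.array([(d.date - base).days for d in days]) * MINUTES_PER_DAY
        t = (offsets[:, None] + np.arange(MINUTES_PER_DAY)[None, :]).reshape(-1)
        y = mat.reshape(-1)
        try:
            cos = cosinor_fit(t, y)
        except ValueError:
            cos = {"MESOR": np.nan, "amplitude": np.nan,
                   "log_amplitude": np.nan, "phase": np.nan}
        out[f"Cosinor MESOR of {label}"] = cos["MESOR"]
        out[f"Cosinor amplitude of {label}"] = cos["amplitude"]
        out[f"Log Cosinor amplitude of {label}"] = cos["log_amplitude"]
        out[f"Cosinor phase of {label}"] = cos["phase"]
    return pd.Series(out, dtype=float)


def aggregate_patient(daily: pd.DataFrame, rhythm: pd.Series) -> pd.Series:
    """Mean and sample variance (ddof=1; 0 for a single day) of each daily
    feature across retained days, plus the whole-period rhythm block.

    Output dimension is independent of the number of monitored days.  DFA
    columns follow the "Mean DFA of ..." naming; all others "Mean of ...".
    """
    if daily.shape[0] == 0:
        raise ValueError("patient has no retained days")
    out: dict[str, float] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = daily.mean(axis=0, skipna=True)
        if daily.shape[0] == 1:
            variances = pd.Series(0.0, index=daily.columns).where(
                daily.iloc[0].notna(), np.nan)
        else:
            variances = daily.var(axis=0, ddof=1, skipna=True)
            n_obs = daily.notna().sum(axis=0)
            variances[n_obs == 1] = 0.0
    for col in daily.columns:
        prefix_mean = "Mean" if col.startswith("DFA") else "Mean of"
        prefix_var = "Variance" if col.startswith("DFA") else "Variance of"
        out[f"{prefix_mean} {col}"] = means[col]
        out[f"{prefix_var} {col}"] = variances[col]
    for name, val in rhythm.items():
        out[name] = val
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# clinical one-hot encoding
# ---------------------------------------------------------------------------

#: clinical column dictionary: how each field of the clinical CSV is treated
CLINICAL_CATEGORICAL = (
    "gender", "race", "tobacco_category", "ASA_class", "prior_surgery",
    "hyperlipidemia", "operation_type", "operative_approach",
)
CLINICAL_CONTINUOUS = (
    "age", "BMI", "comorbidity_count", "medication_count",
    "neutrophils", "calcium",
)
BASELINE_SCORE_COLUMNS = ("SRC_any", "SRC_serious", "SRC_readmit")


class ClinicalEncoder:
    """One-hot encoder for the clinical characteristics table.

    Categories are those observed in the cohort the encoder was fitted on
    (fit inside each training fold to avoid leakage); an unseen category at
    transform time yields all-zero indicators with a warning.  Binary fields
    collapse to a single 0/1 column.  Continuous labs pass through unscaled.
    """

    def __init__(self,
                 categorical=CLINICAL_CATEGORICAL,
                 continuous=CLINICAL_CONTINUOUS):
        self.categorical = tuple(c for c in categorical)
        self.continuous = tuple(c for c in continuous)
        self.categories_: dict[str, list] | None = None

    def fit(self, clinical: pd.DataFrame) -> "ClinicalEncoder":
        self.categories_ = {
            col: sorted(clinical[col].dropna().unique().tolist(), key=str)
            for col in self.categorical if col in clinical.columns
        }
        return self

    def transform(self, clinical: pd.DataFrame) -> pd.DataFrame:
        if self.categories_ is None:
            raise RuntimeError("encoder not fitted")
        blocks = []
        for col, cats in self.categories_.items():
            vals = clinical[col]
            unseen = vals.dropna()[~vals.dropna().isin(cats)]
            if len(unseen):
                warnings.warn(
                    f"unseen categories in {col!r}: {sorted(set(unseen), key=str)};"
                    " encoded as all-zero indicators"
                )
            if len(cats) == 2:
                positive = cats[-1]
                blocks.append(pd.DataFrame(
                    {f"{col}={positive}": (vals == positive).astype(float)}))
            else:
                blocks.append(pd.DataFrame(
                    {f"{col}={c}": (vals == c).astype(float) for c in cats}))
        for col in self.continuous:
            if col in clinical.columns:
                blocks.append(clinical[[col]].astype(float))
        out = pd.concat(blocks, axis=1)
        out.index = clinical.index
        return out

    def fit_transform(self, clinical: pd.DataFrame) -> pd.DataFrame:
        return self.fit(clinical).transform(clinical)

    def decode(self, encoded: pd.DataFrame) -> pd.DataFrame:
        """Invert the categorical block (round-trip on observed categories)."""
        if self.categories_ is None:
            raise RuntimeError("encoder not fitted")
        out = {}
        for col, cats in self.categories_.items():
            if len(cats) == 2:
                positive = cats[-1]
                flag = encoded[f"{col}={positive}"].astype(bool)
                out[col] = np.where(flag, positive, cats[0])
            else:
                sub = encoded[[f"{col}={c}" for c in cats]].to_numpy()
                out[col] = [cats[i] for i in sub.argmax(axis=1)]
        return pd.DataFrame(out, index=encoded.index)

    def feature_types(self, encoded: pd.DataFrame) -> dict[str, str]:
        """Map of encoded column name -> 'categorical' | 'continuous'."""
        cont = set(self.continuous)
        return {c: ("continuous" if c in cont else "categorical")
                for c in encoded.columns}


def encode_clinical(clinical: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, str]]:
    """Fit-and-transform convenience wrapper around :class:`ClinicalEncoder`."""
    enc = ClinicalEncoder()
    X = enc.fit_transform(clinical)
    return X, enc.feature_types(X)
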