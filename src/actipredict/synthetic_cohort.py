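"""Synthetic cohort generator.

Emulates the statistical structure of a preoperative pancreatectomy
monitoring cohort: per-minute step counts as a zero-inflated,
circadian-modulated count process; heart rate as baseline + 24-h cosine +
activity coupling + noise; nightly sleep episodes; a clinical
characteristics table; wear-time missingness with the published daily-yield
distribution; and outcome labels drawn from a logistic model on designated
signal traits (effect size 0 gives a pure null cohort).

Defaults reproduce the published cohort-level statistics: 48 patients, 58%
textbook outcomes, mean 4162.1 (SD 4052.6) steps/day, mean heart rate 75.6
(SD 14.8) bpm, mean daily yield 82.1% (SD 23.5%), mean ~26 monitored days
(range clipped to the published 6-153).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .activity_io import MINUTES_PER_DAY, ActivityDay, PatientRecord
from .cohort_tables import COHORT_STATS
from .outcomes import (ComplicationEvent, ComplicationType, OperationType,
                       textbook_outcome)

_OMEGA = 2.0 * np.pi / MINUTES_PER_DAY
_START_DATE = dt.date(2019, 6, 1)

#: severe-complication type mix observed in pancreatectomy cohorts
_SEVERE_TYPES = (
    (ComplicationType.DELAYED_GASTRIC_EMPTYING, 3),
    (ComplicationType.PANCREATIC_FISTULA, 3),
    (ComplicationType.ORGAN_SPACE_INFECTION, 2),
    (ComplicationType.POSTPANCREATECTOMY_HEMORRHAGE, 4),
    (ComplicationType.ANASTOMOTIC_LEAK_NONPANCREATIC, 1),
    (ComplicationType.MYOCARDIAL_INFARCTION, 1),
    (ComplicationType.OTHER, 5),
)


@dataclass
class CohortConfig:
    """Study conditions of the emulated cohort (identical config + seed
    produce a bit-identical cohort)."""

    n_patients: int = COHORT_STATS["n_patients"]
    textbook_prevalence: float = COHORT_STATS["textbook_fraction"]
    monitoring_days_mean: float = COHORT_STATS["monitoring_days_mean"]
    monitoring_days_range: tuple = COHORT_STATS["monitoring_days_range"]
    steps_per_day_mean: float = COHORT_STATS["steps_per_day_mean"]
    steps_per_day_sd: float = COHORT_STATS["steps_per_day_sd"]
    heart_rate_mean: float = COHORT_STATS["heart_rate_mean"]
    heart_rate_sd: float = COHORT_STATS["heart_rate_sd"]
    daily_yield_mean: float = COHORT_STATS["daily_yield_mean"]
    daily_yield_sd: float = COHORT_STATS["daily_yield_sd"]
    zero_day_prob: float = 0.03       # days forced to yield 0 (discard route)
    sparse_day_prob: float = 0.05     # days forced into (0, 0.1) (feature route)
    effect_size: float = 0.0          # logistic coefficient on the signal score
    signal_features: tuple = ("relative_amplitude", "heart_rate_mean")
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.textbook_prevalence < 1:
            raise ValueError("textbook_prevalence must be in (0, 1)")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        for name in ("steps_per_day_sd", "heart_rate_sd", "daily_yield_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def _rng(cfg_seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg_seed, spawn_key=key))


def _activity_shape(peak_minute: float, contrast: float) -> np.ndarray:
    """Normalized per-minute expected-activity shape with a daytime peak.

    ``contrast`` in (0, 1] sets the day/night amplitude of the profile (high
    contrast => concentrated daytime activity => high relative amplitude).
    """
    t = np.arange(MINUTES_PER_DAY)
    bell = np.maximum(0.0, np.cos(_OMEGA * (t - peak_minute)))
    flat = np.full(MINUTES_PER_DAY, bell.mean())
    u = contrast * bell + (1.0 - contrast) * flat
    return u / u.sum()


def _sleep_stages(rng: np.random.Generator, duration: int,
                  latency: int) -> np.ndarray:
    """Stage sequence for one episode: awake latency, then ~90-min cycles of
    light / deep / REM in 10-minute blocks."""
    stages = np.zeros(duration)
    probs = np.array([0.08, 0.50, 0.22, 0.20])  # awake, light, deep, REM
    n_blocks = int(np.ceil((duration - latency) / 10))
    blocks = rng.choice(4, size=max(n_blocks, 0), p=probs)
    seq = np.repeat(blocks, 10)[: max(duration - latency, 0)]
    stages[latency:] = seq
    return stages


def _simulate_patient(idx: int, cfg: CohortConfig) -> PatientRecord:
    rng = _rng(cfg.seed, idx)

    # between-patient traits
    lo, hi = cfg.monitoring_days_range
    sigma = 0.55
    mu = np.log(max(cfg.monitoring_days_mean, lo + 1)) - sigma**2 / 2
    n_days = int(np.clip(np.round(rng.lognormal(mu, sigma)), lo, hi))

    s_sd, s_mean = cfg.steps_per_day_sd, cfg.steps_per_day_mean
    if s_sd > 0:
        s2 = np.log1p((s_sd / s_mean) ** 2)
        steps_target = float(np.clip(
            rng.lognormal(np.log(s_mean) - s2 / 2, np.sqrt(s2)), 200, 30000))
    else:
        steps_target = s_mean
    hr_base = float(np.clip(rng.normal(cfg.heart_rate_mean, cfg.heart_rate_sd),
                            48, 115))
    hr_amp = float(np.clip(rng.lognormal(np.log(6.5) - 0.125, 0.5), 1.0, 20.0))
    hr_acro = float(rng.normal(16 * 60, 60))      # HR peak mid-afternoon
    contrast = float(np.clip(rng.beta(4, 2), 0.15, 1.0))
    peak = float(rng.normal(14 * 60, 45))
    hr_step_gain = 0.25
    shape = _activity_shape(peak, contrast)
    p_gate = np.clip(0.05 + 0.9 * shape / shape.max(), 0.0, 0.85)

    t = np.arange(MINUTES_PER_DAY)
    days: list[ActivityDay] = []
    for d in range(n_days):
        lam = steps_target * shape / p_gate
        steps = rng.poisson(lam) * (rng.random(MINUTES_PER_DAY) < p_gate)
        hr = (hr_base + hr_amp * np.cos(_OMEGA * (t - hr_acro))
              + hr_step_gain * steps + rng.normal(0, 3.0, MINUTES_PER_DAY))
        hr = np.clip(np.round(hr, 1), 36, 205)
        stage = np.full(MINUTES_PER_DAY, np.nan)
        days.append(ActivityDay(_START_DATE + dt.timedelta(days=d),
                                steps.astype(float), hr, stage))

    # nightly sleep episodes (start ~22:30, may spill past midnight)
    for d in range(n_days):
        start = int(np.clip(rng.normal(22.5 * 60, 40), 21 * 60, 23.9 * 60))
        duration = int(np.clip(rng.normal(470, 45), 330, 600))
        latency = int(np.clip(rng.exponential(12), 0, 90))
        stages = _sleep_stages(rng, duration, latency)
        first = min(MINUTES_PER_DAY - start, duration)
        days[d].sleep_stage[start:start + first] = stages[:first]
        if first < duration and d + 1 < n_days:
            rest = duration - first
            days[d + 1].sleep_stage[:rest] = stages[first:first + rest]

    clinical = _clinical_row(rng)
    patient = PatientRecord(patient_id=f"P{idx:03d}", clinical=clinical,
                            days=days)

    # effective whole-period cosinor parameters of the expected HR curve
    # (closed-form projection onto {1, cos, sin}; activity coupling included)
    mu_t = (hr_base + hr_amp * np.cos(_OMEGA * (t - hr_acro))
            + hr_step_gain * steps_target * shape)
    a1 = 2.0 / MINUTES_PER_DAY * np.sum(mu_t * np.cos(_OMEGA * t))
    b1 = 2.0 / MINUTES_PER_DAY * np.sum(mu_t * np.sin(_OMEGA * t))
    eff_amp = float(np.hypot(a1, b1))
    eff_phase = float(np.arctan2(-b1, a1))
    # expected relative amplitude of the step profile
    hourly = (steps_target * shape).reshape(24, 60).mean(axis=1)
    wrapped = np.concatenate([hourly, hourly])
    m10 = max(wrapped[h:h + 10].mean() for h in range(24))
    l5 = min(wrapped[h:h + 5].mean() for h in range(24))
    rel_amp = (m10 - l5) / (m10 + l5) if m10 + l5 > 0 else 0.0

    patient._truth = {
        "patient_id": patient.patient_id,
        "n_days": n_days,
        "steps_per_day_target": steps_target,
        "heart_rate_mean": hr_base,
        "hr_circ_amplitude": hr_amp,
        "cosinor_mesor": float(mu_t.mean()),
        "cosinor_amplitude": eff_amp,
        "cosinor_phase": eff_phase,
        "relative_amplitude": float(rel_amp),
        "activity_contrast": contrast,
    }
    return patient


def _clinical_row(rng: np.random.Generator) -> dict:
    """Clinical characteristics drawn from cohort-level marginals."""
    return {
        "age": float(np.clip(rng.normal(63.2, 11.6), 30, 85)),
        "gender": rng.choice(["male", "female"], p=[19 / 48, 29 / 48]),
        "race": rng.choice(["white", "non_white"], p=[44 / 48, 4 / 48]),
        "comorbidity_count": int(rng.poisson(4.2)),
        "medication_count": int(rng.poisson(4.0)),
        "tobacco_category": rng.choice(
            ["never", "active_gt10py", "active_lt10py", "past_gt30py",
             "past_lt30py"], p=np.array([30, 4, 1, 11, 2]) / 48),
        "ASA_class": int(rng.choice([1, 2, 3], p=np.array([1, 25, 22]) / 48)),
        "BMI": float(np.clip(rng.normal(28.6, 5.0), 18, 50)),
        "prior_surgery": int(rng.random() < 25 / 48),
        "neutrophils": float(np.clip(rng.normal(39.6, 30.0), 0.5, 120)),
        "calcium": float(np.clip(rng.normal(9.46, 0.60), 7.5, 11.5)),
        "hyperlipidemia": int(rng.random() < 22 / 48),
        "operation_type": rng.choice(
            [e.value for e in OperationType], p=np.array([41, 6, 1]) / 48),
        "operative_approach": rng.choice(
            ["open", "laparoscopic", "robotic"], p=np.array([28, 13, 7]) / 48),
    }


def _assign_outcomes(patients: list[PatientRecord], cfg: CohortConfig) -> None:
    """Draw labels from a logistic model on the designated signal traits and
    materialize consistent complication/readmission events."""
    rng = _rng(cfg.seed, 10_000)
    traits = pd.DataFrame([p._truth for p in patients])
    score = np.zeros(len(patients))
    if cfg.effect_size != 0:
        for name in cfg.signal_features:
            v = traits[name].to_numpy(dtype=float)
            sd = v.std(ddof=0)
            if sd > 0:
                score += (v - v.mean()) / sd
        if len(cfg.signal_features):
            score /= len(cfg.signal_features)
    target_pos = 1.0 - cfg.textbook_prevalence  # P(failure of textbook outcome)
    beta = cfg.effect_size

    def mean_prob(b0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(b0 + beta * score)))))

    b0 = brentq(lambda b: mean_prob(b) - target_pos, -20, 20)
    p_fail = 1.0 / (1.0 + np.exp(-(b0 + beta * score)))
    fail = rng.random(len(patients)) < p_fail

    for i, (patient, failed, prob) in enumerate(zip(patients, fail, p_fail)):
        events, readmit, death = [], False, False
        op = OperationType(patient.clinical["operation_type"])
        drain = False
        drain_day = None
        if failed:
            mode = rng.random()
            if mode < 0.45:  # severe complication only
                events.append(_draw_severe_event(rng))
            elif mode < 0.75:  # severe complication + readmission
                events.append(_draw_severe_event(rng))
                readmit = True
            elif mode < 0.95:  # readmission only
                readmit = True
            else:  # nonsevere fistula (disqualifying at any grade)
                events.append(ComplicationEvent(
                    ComplicationType.PANCREATIC_FISTULA, mags_grade=2,
                    days_post_discharge=int(rng.integers(1, 30))))
        else:
            if rng.random() < 0.25:  # benign grade-1 event, not disqualifying
                events.append(ComplicationEvent(
                    ComplicationType.OTHER, mags_grade=1,
                    days_post_discharge=int(rng.integers(1, 30))))
            if op is OperationType.DISTAL_PANCREATECTOMY and rng.random() < 0.5:
                drain, drain_day = True, int(rng.integers(2, 5))  # <= day 4
        label = textbook_outcome(events, readmitted_30d=readmit,
                                 in_hospital_death=death, op_type=op,
                                 drain_removed_by_day=drain_day,
                                 discharged_with_drain=drain)
        assert label.textbook == (not failed)
        patient.outcome = label
        patient._events = events
        patient._readmitted = readmit
        patient._truth.update({
            "logit": float(b0 + beta * score[i]),
            "p_fail": float(prob),
            "textbook": bool(label.textbook),
        })

    # baseline surgical-risk-calculator columns: correlated with the latent
    # signal score (risk calculators track frailty), published means/SDs
    z = (score - score.mean()) / score.std(ddof=0) if score.std(ddof=0) > 0 \
        else np.zeros_like(score)
    for key, mkey, skey in (("SRC_any", "src_any_mean", "src_any_sd"),
                            ("SRC_serious", "src_serious_mean", "src_serious_sd"),
                            ("SRC_readmit", "src_readmit_mean", "src_readmit_sd")):
        noise = rng.normal(0, 1, len(patients))
        vals = COHORT_STATS[mkey] + COHORT_STATS[skey] * (
            0.5 * z + np.sqrt(1 - 0.25) * noise)
        for patient, v in zip(patients, vals):
            patient.clinical[key] = float(np.clip(v, 0.01, 0.99))


def _draw_severe_event(rng: np.random.Generator) -> ComplicationEvent:
    weights = np.array([w for _, w in _SEVERE_TYPES], dtype=float)
    etype = _SEVERE_TYPES[rng.choice(len(_SEVERE_TYPES),
                                     p=weights / weights.sum())][0]
    grade = int(rng.choice([3, 4], p=[0.8, 0.2]))
    return ComplicationEvent(etype, mags_grade=grade,
                             days_post_discharge=int(rng.integers(1, 30)))


def generate_cohort(cfg: CohortConfig | None = None) -> list[PatientRecord]:
    """Generate a labeled synthetic cohort (complete series, no missingness).

    Apply :func:`apply_missingness` afterwards to exercise the imputation
    routes.  Deterministic given (config, seed).
    """
    cfg = cfg or CohortConfig()
    patients = [_simulate_patient(i, cfg) for i in range(cfg.n_patients)]
    _assign_outcomes(patients, cfg)
    return patients


def apply_missingness(patient: PatientRecord, cfg: CohortConfig,
                      patient_index: int | None = None) -> PatientRecord:
    """Mask minutes to per-day target yields drawn from the configured
    truncated-normal distribution; a mixture of contiguous gap blocks and
    scattered minutes; some days forced to yield 0 (discard route) and some
    into (0, 10%) (feature-level route).  All channels are masked together
    (a device that is off records nothing).
    """
    if patient_index is None:
        patient_index = int(patient.patient_id.lstrip("P"))
    rng = _rng(cfg.seed, 20_000, patient_index)
    target_yields = []
    for day in patient.days:
        u = rng.random()
        if u < cfg.zero_day_prob:
            y = 0.0
        elif u < cfg.zero_day_prob + cfg.sparse_day_prob:
            y = float(rng.uniform(0.01, 0.095))
        else:
            y = float(np.clip(rng.normal(cfg.daily_yield_mean,
                                         cfg.daily_yield_sd), 0.0, 1.0))
        target_yields.append(y)
        n_mask = int(round((1.0 - y) * MINUTES_PER_DAY))
        if n_mask == 0:
            continue
        block_frac = rng.uniform(0.0, 0.7)
        n_block = int(block_frac * n_mask)
        mask = np.zeros(MINUTES_PER_DAY, dtype=bool)
        if n_block > 1:
            start = int(rng.integers(0, MINUTES_PER_DAY - n_block + 1))
            mask[start:start + n_block] = True
        remaining = n_mask - int(mask.sum())
        if remaining > 0:
            candidates = np.flatnonzero(~mask)
            idx = rng.choice(candidates, size=remaining, replace=False)
            mask[idx] = True
        day.steps[mask] = np.nan
        day.heart_rate[mask] = np.nan
        day.sleep_stage[mask] = np.nan
    if hasattr(patient, "_truth"):
        patient._truth["target_yields"] = target_yields
    return patient


def generate_masked_cohort(cfg: CohortConfig | None = None) -> list[PatientRecord]:
    """Convenience: generate then mask every patient."""
    cfg = cfg or CohortConfig()
    return [apply_missingness(p, cfg, i)
            for i, p in enumerate(generate_cohort(cfg))]


def ground_truth(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Per-patient generating parameters (for parameter-recovery tests)."""
    rows = []
    for p in cohort:
        row = dict(getattr(p, "_truth", {"patient_id": p.patient_id}))
        row.pop("target_yields", None)
        rows.append(row)
    df = pd.DataFrame(rows).set_index("patient_id")
    return df


def clinical_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Clinical characteristics table (one row per patient)."""
    df = pd.DataFrame([{"patient_id": p.patient_id, **p.clinical}
                       for p in cohort])
    return df.set_index("patient_id")


def labels_vector(cohort: list[PatientRecord]) -> np.ndarray:
    """1 = failure to achieve a textbook outcome (the positive class)."""
    return np.array([0 if p.outcome.textbook else 1 for p in cohort])


def events_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    rows = []
    for p in cohort:
        for ev in getattr(p, "_events", []):
            rows.append({"patient_id": p.patient_id, "type": ev.type.value,
                         "mags_grade": ev.mags_grade,
                         "days_post_discharge": ev.days_post_discharge})
    return pd.DataFrame(rows, columns=["patient_id", "type", "mags_grade",
                                       "days_post_discharge"])
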