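"""End-to-end orchestration: cohort -> features -> evaluation -> explanation.

The stages mirror the analysis protocol: route days through the missing-data
policy, extract daily statistical/semantic features (imputing the features
of sparse days from the same patient's other days), compute whole-period
rhythm features, aggregate to a fixed-dimension patient vector, one-hot
encode the clinical table, then run sensitivity-anchored LOSO evaluation and
Shapley explanation.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import models as _models
from .activity_io import PatientRecord
from .explain import shapley_importance
from .features import (ClinicalEncoder, FeatureConfig, aggregate_patient,
                       day_features, rhythm_features, BASELINE_SCORE_COLUMNS)
from .imputation import (ImputationConfig, ROUTE_FEATURE, apply_missing_policy,
                         impute_feature_level, route_for_yield)
from .models import CVResult, EvalConfig, ModelSpec, baseline_evaluate, loso_evaluate

log = logging.getLogger("actipredict")


def featurize_patient(patient: PatientRecord,
                      imp_cfg: ImputationConfig | None = None,
                      feat_cfg: FeatureConfig | None = None) -> pd.Series:
    """One patient's fixed-dimension continuous activity feature vector."""
    imp_cfg = imp_cfg or ImputationConfig()
    feat_cfg = feat_cfg or FeatureConfig()
    routed, _ = apply_missing_policy(patient, imp_cfg)
    rows, routes = [], []
    for day in routed.days:
        rows.append(day_features(day, feat_cfg))
        routes.append(route_for_yield(day.data_yield, imp_cfg))
    daily = pd.DataFrame(rows)
    feature_rows = [i for i, r in enumerate(routes) if r == ROUTE_FEATURE]
    donor_rows = [i for i in range(len(routes)) if i not in feature_rows]
    if feature_rows and donor_rows:
        donors = daily.iloc[donor_rows]
        for i in feature_rows:
            daily.iloc[i] = impute_feature_level(daily.iloc[i], donors,
                                                 imp_cfg.k_feature)
    elif feature_rows and not donor_rows:
        warnings.warn(f"patient {patient.patient_id}: no donor days; "
                      "sparse days dropped")
        daily = daily.iloc[[]]
        if daily.shape[0] == 0:
            raise ValueError(f"patient {patient.patient_id} unusable")
    rhythm = rhythm_features(routed.days, feat_cfg)
    return aggregate_patient(daily, rhythm)


def build_feature_matrix(cohort: list[PatientRecord],
                         imp_cfg: ImputationConfig | None = None,
                         feat_cfg: FeatureConfig | None = None
                         ) -> tuple[pd.DataFrame, dict[str, str], dict[str, list]]:
    """Cohort feature matrix, per-column types, and feature-set column lists.

    Returns (X, feature_types, feature_sets) where feature_sets maps
    'clinical_only' / 'activity_only' / 'combined' / 'baseline_score' to
    column lists of X.
    """
    activity = pd.DataFrame(
        {p.patient_id: featurize_patient(p, imp_cfg, feat_cfg)
         for p in cohort}).T
    clinical = pd.DataFrame([{**p.clinical} for p in cohort],
                            index=[p.patient_id for p in cohort])
    enc = ClinicalEncoder()
    clin_X = enc.fit_transform(clinical)
    feature_types = {c: "continuous" for c in activity.columns}
    feature_types.update(enc.feature_types(clin_X))
    baseline_cols = [c for c in BASELINE_SCORE_COLUMNS if c in clinical.columns]
    X = pd.concat([activity, clin_X, clinical[baseline_cols]], axis=1)
    feature_types.update({c: "continuous" for c in baseline_cols})
    feature_sets = {
        "activity_only": list(activity.columns),
        "clinical_only": list(clin_X.columns),
        "combined": list(activity.columns) + list(clin_X.columns),
        "baseline_score": baseline_cols,
    }
    return X, feature_types, feature_sets


def evaluate_feature_set(X: pd.DataFrame, y, feature_types: dict,
                         feature_sets: dict, spec: ModelSpec,
                         cfg: EvalConfig,
                         baseline_column: str = "SRC_any") -> CVResult:
    """LOSO-evaluate one feature-set configuration (or the baseline score)."""
    if cfg.feature_set == "baseline_score":
        return baseline_evaluate(X[baseline_column].to_numpy(), y, cfg)
    cols = feature_sets[cfg.feature_set]
    sub_types = {c: feature_types[c] for c in cols}
    return loso_evaluate(X[cols], y, sub_types, spec, cfg,
                         patient_ids=list(X.index))


def run_pipeline(config, out_dir) -> dict:
    """Execute all stages and write the run artifacts.

    Writes features.csv (+ schema JSON), audit.csv, cv_result.json,
    per_patient.csv, importance.csv, tables.csv and MANIFEST.json into
    ``out_dir``; returns the CV metrics.  Partial outputs are preserved with
    the MANIFEST recording completed stages.
    """
    from .cohort_stats import characteristics_report
    from .synthetic_cohort import (CohortConfig, clinical_frame,
                                   generate_masked_cohort, labels_vector)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []

    def checkpoint(stage: str) -> None:
        manifest.append(stage)
        (out / "MANIFEST.json").write_text(json.dumps({"stages": manifest},
                                                      indent=2))

    cohort_cfg = config.cohort
    cohort = generate_masked_cohort(cohort_cfg)
    y = labels_vector(cohort)
    log.info("ingest: %d patients, %d days", len(cohort),
             sum(len(p.days) for p in cohort))
    checkpoint("ingest")

    audits = []
    for p in cohort:
        _, audit = apply_missing_policy(p, config.imputation)
        audits.append(audit)
    pd.concat(audits).to_csv(out / "audit.csv", index=False)
    checkpoint("missing_policy")

    X, feature_types, feature_sets = build_feature_matrix(
        cohort, config.imputation, config.features)
    X.to_csv(out / "features.csv")
    schema = [{"name": c, "type": feature_types[c],
               "block": next(k for k, v in feature_sets.items() if c in v)}
              for c in X.columns]
    (out / "features_schema.json").write_text(json.dumps(schema, indent=2))
    log.info("features: %d patients x %d columns", *X.shape)
    checkpoint("features")

    spec = ModelSpec(config.model_family, dict(config.model_grid),
                     seed=config.seed)
    result = evaluate_feature_set(X, y, feature_types, feature_sets, spec,
                                  config.evaluation)
    payload = {
        "feature_set": config.evaluation.feature_set,
        "family": spec.family,
        "threshold": result.threshold,
        "metrics": result.metrics,
        "seed": config.seed,
    }
    (out / "cv_result.json").write_text(json.dumps(payload, indent=2,
                                                   sort_keys=True))
    result.to_frame().to_csv(out / "per_patient.csv", index=False)
    log.info("evaluate: %s", result.metrics)
    checkpoint("evaluate")

    if config.evaluation.feature_set != "baseline_score":
        cols = feature_sets[config.evaluation.feature_set]
        sel = _models.select_features(X[cols], y,
                                      {c: feature_types[c] for c in cols},
                                      config.evaluation.selection_k)
        model = _models.train_classifier(spec, X[sel].to_numpy(), y)
        report = shapley_importance(model, X[sel].to_numpy(),
                                    X[sel].to_numpy(),
                                    n_samples=config.explain_samples,
                                    seed=config.seed, feature_names=sel)
        report.mean_abs.to_csv(out / "importance.csv",
                               header=["mean_abs_shap"])
        checkpoint("explain")

    tables = characteristics_report(clinical_frame(cohort), y)
    tables.to_csv(out / "tables.csv", index=False)
    checkpoint("tables")
    return payload
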