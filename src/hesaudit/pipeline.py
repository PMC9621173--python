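"""End-to-end audit pipeline: generate → spells → exclusions → cohort →
features → split/impute/encode → tune → evaluate → attribute → report.

One master seed drives every stochastic stage (generation, splitting,
hyperparameter search, forest fitting), so a fixed seed reproduces every
output file byte for byte.  All artefacts are plain CSV/JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier, cohort as cohort_mod, covariates, metrics, reporting
from .attribution import attribute, importance_report
from .codesets import condition_specs
from .data_model import build_spells
from .synthetic import GeneratorConfig, PlantedTruth, generate_population

__all__ = ["AuditResult", "run_audit", "audit_tables"]


@dataclass
class AuditResult:
    """Everything the pipeline computed for one condition."""

    condition: str
    exclusion_log: dict
    cohort: pd.DataFrame
    features: pd.DataFrame
    split_labels: pd.Series
    tuned: classifier.TunedModel
    encoder: covariates.Encoder
    test_scores: np.ndarray
    test_labels: np.ndarray
    metrics: dict
    importance: pd.DataFrame
    truth: PlantedTruth | None = None
    tables: dict = field(default_factory=dict)


def audit_tables(
    patients: pd.DataFrame,
    episodes: pd.DataFrame,
    condition: str,
    *,
    seed: int = 0,
    grid: dict | None = None,
    n_iter: int = 8,
    max_attribution_rows: int = 1000,
    follow_up_cutoff: str = cohort_mod.DEFAULT_CUTOFF,
    fit_model: bool = True,
) -> AuditResult:
    """Run the audit for one condition on already-loaded tables."""
    specs = condition_specs()
    spec = specs[condition]
    spells = build_spells(episodes)
    kept, exclusion_log = cohort_mod.apply_exclusions(spells, patients, specs)
    cohort = cohort_mod.build_cohort(kept, patients, spec, follow_up_cutoff)
    features = covariates.assemble_features(cohort, kept, patients, spec)

    result = AuditResult(
        condition=condition,
        exclusion_log=exclusion_log,
        cohort=cohort,
        features=features,
        split_labels=pd.Series(dtype=object),
        tuned=None,
        encoder=None,
        test_scores=np.array([]),
        test_labels=np.array([]),
        metrics={},
        importance=pd.DataFrame(),
    )
    result.tables["characteristic_table"] = reporting.characteristic_table(features)
    result.tables["patient_characteristics"] = reporting.patient_characteristic_table(
        patients[patients["patient_id"].isin(cohort["patient_id"].unique())]
    )
    tv_table, tv_summary = reporting.trust_variation(cohort, kept)
    result.tables["trust_variation"] = tv_table
    result.tables["temporal_profile"] = cohort_mod.temporal_profile(cohort, 28)
    result.tables["quarterly_trend"] = cohort_mod.quarterly_trend(cohort)

    n = len(features)
    rate = float(features[covariates.TARGET].mean()) if n else float("nan")
    result.metrics = {
        "n_subsequent_spells": n,
        "inconsistency_rate": rate,
        "trust_variation": tv_summary,
    }
    if not fit_model:
        return result

    labels = classifier.split(features, classifier.SplitSpec(seed=seed))
    result.split_labels = labels
    train_mask = (labels == "train").to_numpy()
    imputed, imputation_log = covariates.impute(features, train_mask)
    encoded, encoder = covariates.encode(imputed)
    result.encoder = encoder
    y = imputed[covariates.TARGET].astype(int).to_numpy()

    parts = {s: (labels == s).to_numpy() for s in classifier.SPLIT_LABELS}
    tuned = classifier.tune(
        encoded[parts["train"]], y[parts["train"]],
        encoded[parts["valid"]], y[parts["valid"]],
        grid=grid, n_iter=n_iter, seed=seed,
    )
    result.tuned = tuned
    X_test = encoded[parts["test"]]
    y_test = y[parts["test"]]
    scores = classifier.score(tuned, X_test)
    result.test_scores = scores
    result.test_labels = y_test

    ci = metrics.delong_ci(scores, y_test)
    result.metrics.update({
        "imputation": imputation_log,
        "chosen_params": {k: (v if v is None or isinstance(v, (int, float, str))
                              else str(v)) for k, v in tuned.params.items()},
        "valid_auprc": tuned.valid_auprc,
        "test_auroc": ci.estimate,
        "test_auroc_ci": [ci.lower, ci.upper],
        "test_auprc": metrics.pr_curve(scores, y_test).area,
        "test_auprg": metrics.prg_curve(scores, y_test).area,
        "test_prevalence": float(np.mean(y_test)),
        "n_train": int(parts["train"].sum()),
        "n_valid": int(parts["valid"].sum()),
        "n_test": int(parts["test"].sum()),
    })

    n_attr = min(max_attribution_rows, len(X_test))
    attr = attribute(tuned, X_test.iloc[:n_attr], encoder)
    feat_test = imputed[parts["test"]].iloc[:n_attr]
    result.importance = importance_report(attr, feat_test)

    for grouping in ("sex", "ethnicity"):
        result.tables[f"subgroup_performance_{grouping}"] = (
            reporting.subgroup_performance(
                tuned, X_test, y_test, imputed[parts["test"]], grouping
            )
        )
    return result


def run_audit(
    config: GeneratorConfig,
    conditions: list[str] | None = None,
    out_dir: str | Path | None = None,
    **kwargs,
) -> dict[str, AuditResult]:
    """Generate a synthetic population and audit each requested condition.

    When ``out_dir`` is given, per-condition artefacts (cohort.csv,
    features.csv, metrics.json, importance.csv and the report tables) are
    written beneath it.
    """
    patients, episodes, truth = generate_population(config)
    conditions = conditions or [c for c, n in config.n_patients.items() if n > 0]
    results: dict[str, AuditResult] = {}
    for condition in conditions:
        res = audit_tables(
            patients, episodes, condition, seed=config.seed, **kwargs
        )
        res.truth = truth
        results[condition] = res
        if out_dir is not None:
            _write_outputs(res, Path(out_dir) / condition)
    return results


def _write_outputs(res: AuditResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cohort = res.cohort.copy()
    cohort["index_discharge_date"] = cohort["index_discharge_date"].dt.strftime(
        "%Y-%m-%d"
    )
    cohort.to_csv(out / "cohort.csv", index=False)
    res.features.to_csv(out / "features.csv", index=False)
    if len(res.importance):
        res.importance.to_csv(out / "importance.csv", index=False)
    for name, table in res.tables.items():
        table.to_csv(out / f"{name}.csv", index=False)
    with open(out / "exclusions.json", "w") as fh:
        json.dump(res.exclusion_log, fh, indent=2, sort_keys=True)
    with open(out / "metrics.json", "w") as fh:
        json.dump(res.metrics, fh, indent=2, sort_keys=True)
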