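"""Shapley attribution aggregated to original features, with importance and
tau-b directionality reporting.

Per-row Shapley contributions are computed on the model's probability
output by the exact path-dependent tree algorithm in
:mod:`hesaudit.treeshap`.  One-hot indicator columns are summed back into
their parent categorical feature through the encoder's column map, so the
report speaks the language of the original covariates.

Importance of a feature is the mean absolute contribution over the
explained rows; directionality is the Kendall tau-b correlation between
the feature's values and its contributions — positive tau-b means high
feature values push predictions toward inconsistency.  Multi-level
categoricals have no single value ordering, so their directionality is
reported per indicator level instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classifier import TunedModel
from .covariates import (
    BOOLEAN_FEATURES,
    CATEGORICAL_FEATURES,
    NUMERIC_FEATURES,
    Encoder,
)
from .metrics import kendall_tau_b
from .treeshap import forest_shap_values

__all__ = ["AttributionMatrix", "attribute", "importance_report"]


@dataclass
class AttributionMatrix:
    """Per-row Shapley contributions on the probability scale.

    ``by_column`` holds one column per encoded matrix column; ``by_feature``
    aggregates one-hot members back onto their parent feature.  Local
    accuracy holds: ``base_value + by_column.sum(axis=1)`` equals the
    model's predicted probability for every row (to numerical tolerance).
    """

    by_column: pd.DataFrame
    by_feature: pd.DataFrame
    base_value: float


def attribute(tuned: TunedModel, X: pd.DataFrame, encoder: Encoder) -> AttributionMatrix:
    """Shapley contributions of every encoded column and original feature."""
    if list(X.columns) != tuned.feature_columns:
        raise ValueError("encoded columns do not match the trained model")
    phi, base = forest_shap_values(tuned.model, X.to_numpy(dtype=float))
    by_column = pd.DataFrame(phi, columns=X.columns, index=X.index)
    by_feature = pd.DataFrame(
        {feat: by_column[cols].sum(axis=1)
         for feat, cols in encoder.column_map.items()},
        index=X.index,
    )
    return AttributionMatrix(by_column=by_column, by_feature=by_feature,
                             base_value=base)


def importance_report(attr: AttributionMatrix, features: pd.DataFrame) -> pd.DataFrame:
    """Feature importance (mean |contribution|) and tau-b directionality.

    Returns one row per original feature, ranked by importance (rank 1 =
    most important), plus unranked per-indicator rows (``sex=female``, ...)
    for each categorical level.  Zero-variance features get NaN
    directionality with a warning.
    """
    rows = []
    for feat in NUMERIC_FEATURES + BOOLEAN_FEATURES + CATEGORICAL_FEATURES:
        contrib = attr.by_feature[feat].to_numpy()
        importance = float(np.abs(contrib).mean())
        if feat in CATEGORICAL_FEATURES and len(attr.by_column.columns) > 0:
            tau = np.nan  # no value ordering across levels
        else:
            vals = features[feat].astype(float).to_numpy()
            tau = _tau_or_nan(vals, contrib, feat)
        rows.append({"feature": feat, "level": "", "importance": importance,
                     "tau_b": tau})
    report = pd.DataFrame(rows)
    order = report["importance"].rank(ascending=False, method="first")
    report["rank"] = order.astype(int)

    level_rows = []
    for feat in CATEGORICAL_FEATURES:
        for col in [c for c in attr.by_column.columns if c.startswith(feat + "=")]:
            level = col.split("=", 1)[1]
            contrib = attr.by_column[col].to_numpy()
            indicator = (features[feat] == level).astype(float).to_numpy()
            level_rows.append({
                "feature": feat, "level": level,
                "importance": float(np.abs(contrib).mean()),
                "tau_b": _tau_or_nan(indicator, contrib, col),
                "rank": np.nan,
            })
    return pd.concat([report, pd.DataFrame(level_rows)], ignore_index=True)


def _tau_or_nan(values: np.ndarray, contrib: np.ndarray, name: str) -> float:
    if len(np.unique(values)) < 2 or len(np.unique(contrib)) < 2:
        warnings.warn(f"{name}: zero variance, directionality undefined",
                      stacklevel=2)
        return float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return kendall_tau_b(values, contrib)
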