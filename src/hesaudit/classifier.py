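"""Random-forest stage: splitting, randomized hyperparameter search
maximizing validation AUPRC, training and scoring.

Rows (spells) are split uniformly at random into 70% training, 15%
validation and 15% test partitions.  Hyperparameters are drawn uniformly
without replacement from a configurable grid; each candidate forest is fit
on the training split and scored by average precision on the validation
split, and the best candidate is refit-free returned together with the full
search log.  Splitting is by spell; a patient can therefore appear on both
sides of a split, which mirrors the spell-level unit of analysis but leaks
patient identity — ``group_by_patient`` trades that leak for a grouped
split.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .metrics import pr_curve

__all__ = ["SplitSpec", "TunedModel", "DEFAULT_GRID", "split", "tune", "score"]

DEFAULT_GRID = {
    "n_estimators": [200, 500],
    "max_depth": [8, 16, None],
    "min_samples_leaf": [1, 5, 20],
    "class_weight": [None, "balanced"],
}

SPLIT_LABELS = ("train", "valid", "test")


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    group_by_patient: bool = False

    def __post_init__(self) -> None:
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")


@dataclass
class TunedModel:
    """A fitted forest with its chosen hyperparameters and search log."""

    model: RandomForestClassifier
    params: dict
    valid_auprc: float
    search_log: list = field(default_factory=list)
    feature_columns: list[str] = field(default_factory=list)


def split(
    features: pd.DataFrame,
    spec: SplitSpec,
    target: str = "inconsistent",
    patient_col: str = "patient_id",
) -> pd.Series:
    """Assign each row to train/valid/test; reproducible under the seed."""
    n = len(features)
    rng = np.random.default_rng(spec.seed)
    if spec.group_by_patient:
        groups = features[patient_col].unique()
        perm = rng.permutation(len(groups))
        cut1 = int(np.floor(len(groups) * spec.fractions[0]))
        cut2 = int(np.floor(len(groups) * (spec.fractions[0] + spec.fractions[1])))
        lab_by_group = {}
        for i, gi in enumerate(perm):
            lab_by_group[groups[gi]] = (
                "train" if i < cut1 else "valid" if i < cut2 else "test"
            )
        labels = features[patient_col].map(lab_by_group)
    else:
        perm = rng.permutation(n)
        cut1 = int(np.floor(n * spec.fractions[0]))
        cut2 = int(np.floor(n * (spec.fractions[0] + spec.fractions[1])))
        lab = np.empty(n, dtype=object)
        lab[perm[:cut1]] = "train"
        lab[perm[cut1:cut2]] = "valid"
        lab[perm[cut2:]] = "test"
        labels = pd.Series(lab, index=features.index)

    counts = labels.value_counts()
    if any(counts.get(s, 0) < 10 for s in SPLIT_LABELS):
        raise ValueError(
            f"too few rows for a 70/15/15 split: {dict(counts)} (need >= 10 each)"
        )
    if target in features.columns:
        for s in SPLIT_LABELS:
            part = features.loc[labels == s, target]
            if part.nunique() < 2:
                warnings.warn(f"split {s!r} contains a single target class",
                              stacklevel=2)
    return labels.rename("split")


def _grid_candidates(grid: dict, n_iter: int, rng: np.random.Generator) -> list[dict]:
    keys = sorted(grid)
    combos = list(itertools.product(*(grid[k] for k in keys)))
    if n_iter < len(combos):
        idx = rng.choice(len(combos), size=n_iter, replace=False)
        combos = [combos[i] for i in idx]
    return [dict(zip(keys, c)) for c in combos]


def tune(
    X_train: pd.DataFrame,
    y_train,
    X_valid: pd.DataFrame,
    y_valid,
    grid: dict | None = None,
    n_iter: int = 20,
    seed: int = 0,
) -> TunedModel:
    """Randomized search over the grid, maximizing validation AUPRC.

    Samples ``min(n_iter, |grid|)`` distinct configurations, fits each on
    the training rows and returns the one with the highest validation
    average precision (ties: first sampled).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    grid = grid if grid is not None else DEFAULT_GRID
    if not grid or any(len(v) == 0 for v in grid.values()):
        raise ValueError("hyperparameter grid must be nonempty")
    y_valid = np.asarray(y_valid).astype(int)
    if len(np.unique(y_valid)) < 2:
        raise ValueError("validation split contains a single class; AUPRC undefined")
    y_train = np.asarray(y_train).astype(int)

    rng = np.random.default_rng(seed)
    fit_seed = int(rng.integers(0, 2**31 - 1))
    candidates = _grid_candidates(grid, n_iter, rng)

    best = None
    log: list[dict] = []
    for params in candidates:
        model = RandomForestClassifier(
            **params, random_state=fit_seed, n_jobs=1
        ).fit(X_train, y_train)
        auprc = pr_curve(model.predict_proba(X_valid)[:, 1], y_valid).area
        log.append({"params": params, "valid_auprc": auprc})
        if best is None or auprc > best[1]:
            best = (model, auprc, params)
    model, auprc, params = best
    return TunedModel(
        model=model,
        params=params,
        valid_auprc=auprc,
        search_log=log,
        feature_columns=list(X_train.columns),
    )


def score(tuned: TunedModel, X: pd.DataFrame) -> np.ndarray:
    """Per-row predicted probability of inconsistency."""
    if list(X.columns) != tuned.feature_columns:
        missing = set(tuned.feature_columns) - set(X.columns)
        extra = set(X.columns) - set(tuned.feature_columns)
        raise ValueError(
            f"feature columns do not match training: missing {sorted(missing)}, "
            f"unexpected {sorted(extra)}"
        )
    return tuned.model.predict_proba(X)[:, 1]
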