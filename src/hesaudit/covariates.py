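"""Feature engineering for subsequent spells: comorbidity scores, spell
features, imputation and one-hot encoding.

Each subsequent spell in a cohort becomes one feature row:

* numeric — age in years at admission, spell length of stay, days since the
  index discharge, Charlson comorbidity index (1-year lookback), hospital
  frailty risk score (2-year lookback), deprivation quintile, and a
  placeholder numeric frailty covariate;
* categorical — sex, ethnicity, admission method, main specialty;
* boolean — day case, change of trust since the index spell, change of
  specialty, and absence of the related-condition code (Parkinson's disease
  G20 for PDD; the learning-disability block F70–F83 for autism; constant
  false for DMPC, which has no related set);
* target — ``inconsistent``, the negation of the audit's consistency flag.

Comorbidity instruments are weighted ICD-10 pattern tables applied to the
pooled codes of the patient's spells admitted inside a lookback window
ending just before (and excluding) the reference admission; each pattern
group counts at most once per window.  The Charlson table ships with the
package (Quan ICD-10 mapping, original weights).  The frailty table is a
synthetic stand-in with the published instrument's structure (3-character
prefix stems, weights 0.1–7.1); see ``resources/hfrs_weights_synthetic.csv``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources as _ilres
from pathlib import Path

import numpy as np
import pandas as pd

from .codesets import CodePattern, ConditionSpec
from .data_model import IntegrityError

__all__ = [
    "WeightTable",
    "charlson_table",
    "hfrs_table",
    "comorbidity_score",
    "assemble_features",
    "impute",
    "Encoder",
    "encode",
    "NUMERIC_FEATURES",
    "CATEGORICAL_FEATURES",
    "BOOLEAN_FEATURES",
    "ID_COLUMNS",
    "TARGET",
]

NUMERIC_FEATURES = [
    "age_years", "length_of_stay", "days_since_index", "charlson", "hfrs",
    "imd_quintile", "frailty_placeholder",
]
CATEGORICAL_FEATURES = ["sex", "ethnicity", "admission_method", "main_specialty"]
BOOLEAN_FEATURES = [
    "day_case", "change_of_trust", "change_of_specialty", "related_code_absent",
]
ID_COLUMNS = ["patient_id", "spell_id", "condition"]
TARGET = "inconsistent"

CHARLSON_LOOKBACK_DAYS = 365
HFRS_LOOKBACK_DAYS = 730


@dataclass(frozen=True)
class WeightTable:
    """Weighted ICD-10 pattern table with a lookback window.

    Each entry is (pattern, group, weight); within one scoring window a
    group contributes at most once, at the maximum weight among its matched
    patterns.
    """

    entries: tuple[tuple[CodePattern, str, float], ...]
    lookback_days: int

    def __post_init__(self) -> None:
        for _, _, w in self.entries:
            if not np.isfinite(w):
                raise ValueError("non-finite weight in weight table")

    @classmethod
    def from_csv(cls, path, lookback_days: int) -> "WeightTable":
        df = pd.read_csv(path)
        entries = tuple(
            (CodePattern(r.stem, r.mode), str(r.group), float(r.weight))
            for r in df.itertuples()
        )
        return cls(entries=entries, lookback_days=lookback_days)

    def matched_groups(self, codes) -> dict[str, float]:
        """Map of matched group -> max weight among its matched patterns."""
        out: dict[str, float] = {}
        for code in codes:
            for pat, group, w in self.entries:
                if pat.matches(code) and w > out.get(group, -np.inf):
                    out[group] = w
        return out

    # Fast lookup structures for the vectorized path ---------------------
    def _maps(self):
        exact: dict[str, list[tuple[str, float]]] = {}
        prefix: dict[str, list[tuple[str, float]]] = {}
        lengths = set()
        for pat, group, w in self.entries:
            if pat.mode == "exact":
                exact.setdefault(pat.stem, []).append((group, w))
            else:
                prefix.setdefault(pat.stem, []).append((group, w))
                lengths.add(len(pat.stem))
        return exact, prefix, sorted(lengths)

    def matched_groups_fast(self, codes) -> dict[str, float]:
        try:
            exact, prefix, lengths = object.__getattribute__(self, "_lookup")
        except AttributeError:
            object.__setattr__(self, "_lookup", self._maps())
            exact, prefix, lengths = object.__getattribute__(self, "_lookup")
        out: dict[str, float] = {}
        for code in codes:
            hits = exact.get(code, ())
            for group, w in hits:
                if w > out.get(group, -np.inf):
                    out[group] = w
            for L in lengths:
                for group, w in prefix.get(code[:L], ()):
                    if w > out.get(group, -np.inf):
                        out[group] = w
        return out


def _resource(name: str) -> Path:
    return Path(str(_ilres.files("hesaudit.resources") / name))


def charlson_table() -> WeightTable:
    """Charlson comorbidity index, Quan ICD-10 mapping, original weights."""
    return WeightTable.from_csv(_resource("charlson_quan.csv"), CHARLSON_LOOKBACK_DAYS)


def hfrs_table() -> WeightTable:
    """Hospital-frailty-style score over a synthetic stand-in weight table."""
    return WeightTable.from_csv(
        _resource("hfrs_weights_synthetic.csv"), HFRS_LOOKBACK_DAYS
    )


def comorbidity_score(
    patient_spells: pd.DataFrame,
    reference_date: pd.Timestamp,
    table: WeightTable,
) -> float:
    """Weighted score over distinct pattern groups in the lookback window.

    Considers spells admitted within ``[reference - lookback, reference)``;
    the reference spell itself (admitted on the reference date) never
    contributes.  An empty window scores 0.
    """
    reference_date = pd.Timestamp(reference_date)
    lo = reference_date - pd.Timedelta(days=table.lookback_days)
    window = patient_spells[
        (patient_spells["admission_date"] >= lo)
        & (patient_spells["admission_date"] < reference_date)
    ]
    codes: set[str] = set()
    for cs in window["pooled_codes"]:
        codes |= set(cs)
    return float(sum(table.matched_groups(codes).values()))


def assemble_features(
    cohort: pd.DataFrame,
    spells: pd.DataFrame,
    patients: pd.DataFrame,
    spec: ConditionSpec,
    charlson: WeightTable | None = None,
    hfrs: WeightTable | None = None,
) -> pd.DataFrame:
    """One feature row per cohort row (see module docstring for columns)."""
    charlson = charlson or charlson_table()
    hfrs = hfrs or hfrs_table()

    sp = spells.set_index("spell_id")
    missing = [s for s in cohort["spell_id"] if s not in sp.index]
    missing += [s for s in cohort["index_spell_id"].unique() if s not in sp.index]
    if missing:
        raise IntegrityError(f"cohort references unknown spells: {missing[:5]}")
    pat = patients.set_index("patient_id")

    # Per-spell matched comorbidity groups, computed once.
    ch_groups = {sid: charlson.matched_groups_fast(codes)
                 for sid, codes in sp["pooled_codes"].items()}
    hf_groups = {sid: hfrs.matched_groups_fast(codes)
                 for sid, codes in sp["pooled_codes"].items()}
    by_patient: dict[str, list[tuple[pd.Timestamp, str]]] = {}
    for sid, row in sp.iterrows():
        by_patient.setdefault(row["patient_id"], []).append(
            (row["admission_date"], sid)
        )
    for lst in by_patient.values():
        lst.sort()

    def _score(pid, ref, groups_by_sid, lookback):
        lo = ref - pd.Timedelta(days=lookback)
        merged: dict[str, float] = {}
        for adm, sid in by_patient.get(pid, ()):
            if adm >= ref:
                break
            if adm < lo:
                continue
            for g, w in groups_by_sid[sid].items():
                if w > merged.get(g, -np.inf):
                    merged[g] = w
        return float(sum(merged.values()))

    rows = []
    for r in cohort.itertuples():
        s = sp.loc[r.spell_id]
        idx = sp.loc[r.index_spell_id]
        p = pat.loc[r.patient_id]
        adm = s["admission_date"]
        rows.append({
            "patient_id": r.patient_id,
            "spell_id": r.spell_id,
            "condition": r.condition,
            "age_years": int(adm.year - p["birth_year"]),
            "length_of_stay": int(s["length_of_stay_days"]),
            "days_since_index": int(r.days_since_index),
            "charlson": _score(r.patient_id, adm, ch_groups,
                               charlson.lookback_days),
            "hfrs": _score(r.patient_id, adm, hf_groups, hfrs.lookback_days),
            "imd_quintile": p["imd_quintile"],
            "frailty_placeholder": p["frailty_placeholder"],
            "sex": p["sex"],
            "ethnicity": p["ethnicity"],
            "admission_method": s["admission_method"],
            "main_specialty": s["main_specialty"],
            "day_case": not bool(s["overnight"]),
            "change_of_trust": s["trust_id"] != idx["trust_id"],
            "change_of_specialty": s["main_specialty"] != idx["main_specialty"],
            "related_code_absent": (
                not spec.has_related(s["pooled_codes"])
                if spec.related_patterns else False
            ),
            TARGET: not r.consistent,
        })
    return pd.DataFrame(rows, columns=ID_COLUMNS + NUMERIC_FEATURES
                        + CATEGORICAL_FEATURES + BOOLEAN_FEATURES + [TARGET])


def impute(
    features: pd.DataFrame, training_mask: np.ndarray
) -> tuple[pd.DataFrame, dict]:
    """Fill missing values from the training split only.

    Numeric features get the training mean; categorical features get the
    training mode (ties broken by the lexicographically smallest level).
    Returns the filled table and a log of the fill values used.  A feature
    with no observed training value raises, naming the feature.
    """
    training_mask = np.asarray(training_mask, dtype=bool)
    if training_mask.sum() == 0:
        raise ValueError("training mask selects no rows")
    out = features.copy()
    log: dict[str, object] = {}
    train = features.loc[training_mask]
    for col in NUMERIC_FEATURES:
        if out[col].isna().any():
            obs = train[col].dropna()
            if len(obs) == 0:
                raise ValueError(f"feature {col!r} entirely missing in training split")
            fill = float(obs.mean())
            out[col] = out[col].fillna(fill)
            log[col] = fill
    for col in CATEGORICAL_FEATURES:
        if out[col].isna().any():
            obs = train[col].dropna()
            if len(obs) == 0:
                raise ValueError(f"feature {col!r} entirely missing in training split")
            modes = sorted(obs.mode())
            out[col] = out[col].fillna(modes[0])
            log[col] = modes[0]
    return out, log


@dataclass
class Encoder:
    """One-hot encoder with a column map linking matrix columns to features.

    ``column_map`` records which encoded columns belong to each original
    feature so per-column attribution values can be aggregated back onto the
    feature they came from.  Categories unseen at transform time encode as
    all-zeros and are logged.
    """

    categories: dict[str, list] = field(default_factory=dict)
    column_map: dict[str, list[str]] = field(default_factory=dict)
    columns: list[str] = field(default_factory=list)
    unseen_log: list[str] = field(default_factory=list)

    def fit(self, features: pd.DataFrame) -> "Encoder":
        self.categories = {
            c: sorted(features[c].dropna().unique()) for c in CATEGORICAL_FEATURES
        }
        self.column_map = {}
        self.columns = []
        for c in NUMERIC_FEATURES + BOOLEAN_FEATURES:
            self.column_map[c] = [c]
            self.columns.append(c)
        for c in CATEGORICAL_FEATURES:
            cols = [f"{c}={lvl}" for lvl in self.categories[c]]
            self.column_map[c] = cols
            self.columns.extend(cols)
        return self

    def transform(self, features: pd.DataFrame) -> pd.DataFrame:
        if not self.columns:
            raise ValueError("Encoder not fitted")
        data = {}
        for c in NUMERIC_FEATURES:
            data[c] = features[c].astype(float).to_numpy()
        for c in BOOLEAN_FEATURES:
            data[c] = features[c].astype(bool).astype(float).to_numpy()
        for c in CATEGORICAL_FEATURES:
            vals = features[c]
            unseen = set(vals.dropna().unique()) - set(self.categories[c])
            for u in sorted(unseen):
                msg = f"unseen category {c}={u!r} encoded as all-zeros"
                self.unseen_log.append(msg)
                warnings.warn(msg, stacklevel=2)
            for lvl in self.categories[c]:
                data[f"{c}={lvl}"] = (vals == lvl).astype(float).to_numpy()
        return pd.DataFrame(data, columns=self.columns, index=features.index)


def encode(features: pd.DataFrame) -> tuple[pd.DataFrame, Encoder]:
    """Fit-and-transform convenience wrapper around :class:`Encoder`."""
    enc = Encoder().fit(features)
    return enc.transform(features), enc
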