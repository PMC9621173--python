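"""Report tables: stratified inconsistency rates, patient characteristics,
per-trust variation and subgroup model performance.

Two published-table conventions are followed:

* spell-characteristic tables report, per stratum, the count of
  inconsistent subsequent spells and that count as a percentage of the
  stratum's subsequent spells (``not_recorded`` strata included);
* patient-characteristic composition percentages are calculated excluding
  unrecorded data, i.e. the denominator is the number of patients with the
  feature recorded.

The module also carries the headline counts printed in the published
national audit of these three conditions, so its percentage arithmetic can
be re-run against the published numerator/denominator pairs.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .classifier import TunedModel, score
from .metrics import delong_ci

__all__ = [
    "AGE_BANDS",
    "age_band",
    "percentage",
    "composition_percentages",
    "characteristic_table",
    "patient_characteristic_table",
    "trust_variation",
    "subgroup_performance",
    "PUBLISHED_SUBSEQUENT_SPELLS",
    "PUBLISHED_AUTISM_DEPRIVATION_PATIENTS",
]

AGE_BANDS = ((0, 17), (18, 39), (40, 59), (60, 79), (80, 200))
_BAND_LABELS = ("0-17", "18-39", "40-59", "60-79", "80+")

# Headline counts printed in the published national audit (inconsistent
# subsequent spells / all subsequent spells, per condition).
PUBLISHED_SUBSEQUENT_SPELLS = {
    "autism": (170_447, 390_220),
    "dmpc": (46_679, 544_341),
    "pdd": (18_975, 60_822),
}
# First-spell deprivation-quintile patient counts for the autism cohort in
# the same publication; "not_recorded" is excluded from percentage
# denominators per the composition-table convention.
PUBLISHED_AUTISM_DEPRIVATION_PATIENTS = {
    "1": 48_539, "2": 38_254, "3": 31_311, "4": 26_332, "5": 22_275,
    "not_recorded": 5_613,
}


def age_band(age_years) -> str:
    """Map age in years to the reporting band label."""
    for (lo, hi), lab in zip(AGE_BANDS, _BAND_LABELS):
        if lo <= age_years <= hi:
            return lab
    raise ValueError(f"age {age_years} outside supported bands")


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """A printed-table percentage: 100*num/den rounded to ``decimals``."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return round(100.0 * numerator / denominator, decimals)


def composition_percentages(
    counts: dict[str, float], not_recorded_key: str = "not_recorded",
    decimals: int = 1,
) -> dict[str, float]:
    """Stratum percentages excluding unrecorded rows from the denominator."""
    recorded = {k: v for k, v in counts.items() if k != not_recorded_key}
    total = sum(recorded.values())
    return {k: percentage(v, total, decimals) for k, v in recorded.items()}


def _strata(features: pd.DataFrame) -> pd.DataFrame:
    s = pd.DataFrame(index=features.index)
    s["age_band"] = features["age_years"].map(age_band)
    s["sex"] = features["sex"].fillna("not_recorded")
    s["deprivation_quintile"] = features["imd_quintile"].map(
        lambda v: "not_recorded" if pd.isna(v) else str(int(v))
    )
    s["ethnicity"] = features["ethnicity"].fillna("not_recorded")
    s["stay"] = np.where(features["day_case"], "day_case", "overnight")
    s["admission_method"] = features["admission_method"].fillna("not_recorded")
    return s


def characteristic_table(features: pd.DataFrame) -> pd.DataFrame:
    """Inconsistent-spell counts and rates per stratum (spell-level table).

    One row per (dimension, stratum): the number of subsequent spells, the
    number inconsistent, and the inconsistent percentage of that stratum.
    """
    strata = _strata(features)
    target = features["inconsistent"].astype(bool)
    rows = []
    for dim in strata.columns:
        for level, idx in strata.groupby(dim, sort=True).groups.items():
            n = len(idx)
            n_inc = int(target.loc[idx].sum())
            rows.append({
                "dimension": dim, "stratum": str(level),
                "n_spells": n, "n_inconsistent": n_inc,
                "pct_inconsistent": percentage(n_inc, n),
            })
    return pd.DataFrame(rows)


def patient_characteristic_table(patients: pd.DataFrame) -> pd.DataFrame:
    """Composition of the patient table (first-spell characteristics).

    Percentages are calculated excluding unrecorded data, matching the
    published-table footnote convention.
    """
    dims = {
        "sex": patients["sex"].map(
            lambda v: "not_recorded" if pd.isna(v) or v == "unknown" else v
        ),
        "deprivation_quintile": patients["imd_quintile"].map(
            lambda v: "not_recorded" if pd.isna(v) else str(int(v))
        ),
        "ethnicity": patients["ethnicity"].map(
            lambda v: "not_recorded" if pd.isna(v) or v == "not_stated" else v
        ),
    }
    rows = []
    for dim, series in dims.items():
        counts = series.value_counts().to_dict()
        pcts = composition_percentages(counts)
        for level, n in sorted(counts.items()):
            rows.append({
                "dimension": dim, "stratum": level, "n_patients": int(n),
                "pct_of_recorded": pcts.get(level, np.nan),
            })
    return pd.DataFrame(rows)


def trust_variation(cohort: pd.DataFrame, spells: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Per-trust inconsistency rates with their median and IQR.

    The trust of each subsequent spell (not the index trust) defines the
    grouping.
    """
    trust = spells.set_index("spell_id")["trust_id"]
    sub = cohort.copy()
    sub["trust_id"] = sub["spell_id"].map(trust)
    grouped = sub.groupby("trust_id")["consistent"]
    table = pd.DataFrame({
        "trust_id": grouped.size().index,
        "n_spells": grouped.size().to_numpy(),
        "rate_inconsistent": (1.0 - grouped.mean()).to_numpy(),
    }).reset_index(drop=True)
    rates = table["rate_inconsistent"].to_numpy()
    summary = {
        "median": float(np.median(rates)),
        "iqr_low": float(np.percentile(rates, 25)),
        "iqr_high": float(np.percentile(rates, 75)),
        "n_trusts": int(len(rates)),
    }
    return table, summary


def subgroup_performance(
    tuned: TunedModel,
    X_test: pd.DataFrame,
    y_test,
    features_test: pd.DataFrame,
    grouping: str,
) -> pd.DataFrame:
    """Test AUROC with DeLong CI per subgroup of ``grouping`` (sex/ethnicity).

    Subgroups whose test rows contain a single target class are skipped
    with a warning.
    """
    if grouping not in ("sex", "ethnicity"):
        raise ValueError("grouping must be 'sex' or 'ethnicity'")
    y_test = np.asarray(y_test).astype(int)
    probs = score(tuned, X_test)
    rows = []
    for level, idx in features_test.groupby(grouping, sort=True).groups.items():
        pos = features_test.index.get_indexer(idx)
        y_g = y_test[pos]
        if len(y_g) < 4 or min(np.bincount(y_g, minlength=2)) < 2:
            warnings.warn(
                f"subgroup {grouping}={level!r}: single class or too small; skipped",
                stacklevel=2,
            )
            continue
        ci = delong_ci(probs[pos], y_g)
        rows.append({
            "grouping": grouping, "level": str(level), "n": int(len(y_g)),
            "auroc": ci.estimate, "ci_lower": ci.lower, "ci_upper": ci.upper,
        })
    return pd.DataFrame(rows)
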