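"""Index-spell detection, exclusion filtering and consistency labelling.

The audit logic: for each condition, find every patient's *index spell* —
the first spell in the study window whose pooled diagnosis codes contain the
condition's mandated code — then label every *subsequent* spell as
consistent (some episode mentions a code from the condition's consistency
set) or inconsistent (none does).  The inconsistency rate is the audit's
headline number.

Before labelling, spells are removed when they carry no diagnostic
information or would bias the denominator:

* spells whose only diagnosis code is R69 (unknown and unspecified causes
  of morbidity), or with an empty diagnosis field;
* regular dialysis attendances (procedure code X40 or X43, or a
  regular-attendance spell coding chronic renal failure N18.5) — such
  day-attendances usually code only the procedure performed;
* every spell of patients in age bands where the index diagnosis is most
  likely mis-coded: PDD under 40 and DMPC under 18 at index.

Follow-up analyses are restricted to a 3-year (1095-day) window after the
index discharge, for patients whose index spell ended before a cutoff date,
so each contributing patient has the same maximum follow-up.
"""

from __future__ import annotations

import pandas as pd

from .codesets import ConditionSpec

__all__ = [
    "apply_exclusions",
    "find_index_spell",
    "label_consistency",
    "build_cohort",
    "inconsistency_rate",
    "temporal_profile",
    "quarterly_trend",
    "FOLLOW_UP_DAYS",
    "DEFAULT_CUTOFF",
]

FOLLOW_UP_DAYS = 1095  # 3 years, leap days ignored
DEFAULT_CUTOFF = "2018-04-01"  # index discharge must precede this for trend analyses

_DIALYSIS_PROCS = {"X40", "X43"}
_RENAL_CODE = "N185"


def label_consistency(pooled_codes, spec: ConditionSpec) -> bool:
    """True iff any episode of the spell mentions a consistency-set code.

    Because the consistency rule is "at least one constituent episode", it
    is equivalent to testing the spell's pooled code union.
    """
    return spec.is_consistent(pooled_codes)


def _age_at(date: pd.Timestamp, birth_year: int) -> int:
    return int(date.year - birth_year)


def find_index_spell(patient_spells: pd.DataFrame, spec: ConditionSpec) -> str | None:
    """Earliest spell whose pooled codes match an index pattern.

    Ties on admission date are broken by discharge date, then by spell_id
    (lexicographic).  Returns ``None`` when the patient never carries the
    index code.
    """
    hits = patient_spells[
        patient_spells["pooled_codes"].map(spec.is_index)
    ]
    if len(hits) == 0:
        return None
    hits = hits.sort_values(
        ["admission_date", "discharge_date", "spell_id"], kind="stable"
    )
    return str(hits.iloc[0]["spell_id"])


def apply_exclusions(
    spells: pd.DataFrame,
    patients: pd.DataFrame,
    specs: dict[str, ConditionSpec],
) -> tuple[pd.DataFrame, dict]:
    """Remove non-informative and bias-prone spells; log counts per reason.

    Removal reasons (in application order):

    ``r69_or_empty``
        pooled codes empty or a subset of {R69};
    ``dialysis``
        procedure X40/X43, or a regular attendance coding N18.5;
    ``age``
        all spells of patients below a condition's minimum index age
        (evaluated at the index spell found after the first two filters).

    Returns the surviving spells and a log with per-reason spell counts and
    the number of age-excluded patients.
    """
    log = {"r69_or_empty": 0, "dialysis": 0, "age": 0, "age_patients": 0}

    r69 = spells["pooled_codes"].map(lambda cs: len(cs - {"R69"}) == 0)
    log["r69_or_empty"] = int(r69.sum())
    kept = spells[~r69]

    dialysis = kept["pooled_procedures"].map(
        lambda ps: bool(_DIALYSIS_PROCS & set(ps))
    ) | (
        (kept["admission_method"] == "regular")
        & kept["pooled_codes"].map(lambda cs: _RENAL_CODE in cs)
    )
    log["dialysis"] = int(dialysis.sum())
    kept = kept[~dialysis]

    birth = patients.set_index("patient_id")["birth_year"]
    excluded_patients: set[str] = set()
    for spec in specs.values():
        if spec.min_age_years is None:
            continue
        idx_rows = _index_spells(kept, spec)
        for r in idx_rows.itertuples():
            if _age_at(r.admission_date, int(birth[r.patient_id])) < spec.min_age_years:
                excluded_patients.add(str(r.patient_id))
    age_mask = kept["patient_id"].isin(excluded_patients)
    log["age"] = int(age_mask.sum())
    log["age_patients"] = len(excluded_patients)
    kept = kept[~age_mask]

    return kept.reset_index(drop=True), log


def _index_spells(spells: pd.DataFrame, spec: ConditionSpec) -> pd.DataFrame:
    """One index-spell row per patient carrying the index code (vectorized
    counterpart of :func:`find_index_spell`, same ordering rules)."""
    hits = spells[spells["pooled_codes"].map(spec.is_index)]
    if len(hits) == 0:
        return hits
    hits = hits.sort_values(
        ["patient_id", "admission_date", "discharge_date", "spell_id"],
        kind="stable",
    )
    return hits.drop_duplicates("patient_id", keep="first")


def build_cohort(
    spells: pd.DataFrame,
    patients: pd.DataFrame,
    spec: ConditionSpec,
    follow_up_cutoff: str | pd.Timestamp = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """One row per subsequent spell of each patient with an index spell.

    A subsequent spell is any spell (other than the index) admitted on or
    after the index admission; overlapping transfer spells therefore count.
    ``days_since_index`` is subsequent admission minus index discharge,
    floored at zero.  ``in_3y_window`` marks rows usable for the fixed
    3-year follow-up analyses.
    """
    cutoff = pd.Timestamp(follow_up_cutoff)
    columns = [
        "patient_id", "condition", "index_spell_id", "spell_id", "consistent",
        "days_since_index", "index_discharge_date", "in_3y_window",
    ]
    idx = _index_spells(spells, spec)
    if len(idx) == 0:
        return pd.DataFrame(columns=columns)
    idx = idx.set_index("patient_id")[
        ["spell_id", "admission_date", "discharge_date"]
    ].rename(columns={
        "spell_id": "index_spell_id",
        "admission_date": "index_admission_date",
        "discharge_date": "index_discharge_date",
    })
    sub = spells[spells["patient_id"].isin(idx.index)].merge(
        idx, left_on="patient_id", right_index=True
    )
    sub = sub[
        (sub["admission_date"] >= sub["index_admission_date"])
        & (sub["spell_id"] != sub["index_spell_id"])
    ]
    days = (
        (sub["admission_date"] - sub["index_discharge_date"]).dt.days.clip(lower=0)
    )
    cohort = pd.DataFrame({
        "patient_id": sub["patient_id"].to_numpy(),
        "condition": spec.name,
        "index_spell_id": sub["index_spell_id"].to_numpy(),
        "spell_id": sub["spell_id"].to_numpy(),
        "consistent": sub["pooled_codes"].map(spec.is_consistent).to_numpy(),
        "days_since_index": days.astype(int).to_numpy(),
        "index_discharge_date": sub["index_discharge_date"].to_numpy(),
        "in_3y_window": (
            (days <= FOLLOW_UP_DAYS)
            & (sub["index_discharge_date"] < cutoff)
        ).to_numpy(),
    }, columns=columns)
    return cohort.sort_values(["patient_id", "spell_id"], kind="stable").reset_index(
        drop=True
    )


def inconsistency_rate(cohort: pd.DataFrame) -> float:
    """Fraction of subsequent spells without the mandated code."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    return float(1.0 - cohort["consistent"].mean())


def temporal_profile(cohort: pd.DataFrame, bin_width_days: int) -> pd.DataFrame:
    """Inconsistency proportion per elapsed-time bin over 3-year follow-up.

    Only rows inside the fixed follow-up window contribute.  Bins with no
    spells are absent from the output rather than reported as zero.
    """
    if bin_width_days <= 0:
        raise ValueError("bin_width_days must be positive")
    sub = cohort[cohort["in_3y_window"]]
    if len(sub) == 0:
        return pd.DataFrame(columns=["bin_start_day", "bin_end_day",
                                     "n_spells", "prop_inconsistent"])
    b = sub["days_since_index"] // bin_width_days
    grouped = sub.groupby(b)["consistent"]
    out = pd.DataFrame({
        "bin_start_day": grouped.size().index * bin_width_days,
        "bin_end_day": (grouped.size().index + 1) * bin_width_days,
        "n_spells": grouped.size().to_numpy(),
        "prop_inconsistent": (1.0 - grouped.mean()).to_numpy(),
    }).reset_index(drop=True)
    return out


def quarterly_trend(cohort: pd.DataFrame) -> pd.DataFrame:
    """3-year inconsistency rate by calendar quarter of index discharge."""
    sub = cohort[cohort["in_3y_window"]]
    if len(sub) == 0:
        return pd.DataFrame(columns=["quarter", "n_spells", "prop_inconsistent"])
    q = pd.PeriodIndex(sub["index_discharge_date"], freq="Q").astype(str)
    grouped = sub.groupby(q)["consistent"]
    return pd.DataFrame({
        "quarter": grouped.size().index,
        "n_spells": grouped.size().to_numpy(),
        "prop_inconsistent": (1.0 - grouped.mean()).to_numpy(),
    }).reset_index(drop=True)
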