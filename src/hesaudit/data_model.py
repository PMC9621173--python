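"""Typed tables for patients, episodes and spells, with CSV I/O.

The unit of hospital activity is the *spell* — a continuous period in
hospital from admission to discharge — which can contain several *episodes*
of care under different consultants, each carrying its own ordered ICD-10
diagnosis list (first entry = primary diagnosis).  Transfers between trusts
appear as separate spells; no linkage is attempted.

Tables are plain :class:`pandas.DataFrame` objects with documented schemas:

``patients.csv``
    patient_id, birth_year, sex, ethnicity, imd_quintile, frailty_placeholder
``episodes.csv``
    patient_id, spell_id, episode_order, trust_id, main_specialty,
    admission_date, discharge_date, admission_method,
    diagnosis_codes (semicolon-delimited), procedure_codes (semicolon-delimited)

Missing values are encoded as empty fields.  Dates are ISO-8601; all date
arithmetic is in whole days.  Diagnosis codes are normalized on ingest
(uppercased, dots stripped) so both circulating dialects are accepted.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .codesets import normalize_code

__all__ = [
    "SchemaError",
    "IntegrityError",
    "PATIENT_COLUMNS",
    "EPISODE_COLUMNS",
    "SEX_LEVELS",
    "ETHNICITY_LEVELS",
    "ADMISSION_METHODS",
    "read_tables",
    "write_tables",
    "build_spells",
    "parse_codes",
    "join_codes",
]

PATIENT_COLUMNS = [
    "patient_id", "birth_year", "sex", "ethnicity",
    "imd_quintile", "frailty_placeholder",
]
EPISODE_COLUMNS = [
    "patient_id", "spell_id", "episode_order", "trust_id", "main_specialty",
    "admission_date", "discharge_date", "admission_method",
    "diagnosis_codes", "procedure_codes",
]

SEX_LEVELS = ("female", "male", "unknown")
ETHNICITY_LEVELS = ("white", "asian", "black", "mixed", "other", "not_stated")
# "regular" marks regular day-attender activity (e.g. dialysis programmes),
# which the exclusion stage inspects.
ADMISSION_METHODS = ("elective", "emergency", "regular", "unknown")


class SchemaError(ValueError):
    """A table is missing mandatory columns or violates the documented schema."""


class IntegrityError(ValueError):
    """Cross-row inconsistency, e.g. two patients sharing one spell."""


def parse_codes(cell, normalize: bool = True) -> tuple[str, ...]:
    """Split a semicolon-delimited code field into a tuple of codes."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return ()
    parts = [p for p in str(cell).split(";") if p.strip()]
    if normalize:
        return tuple(normalize_code(p) for p in parts)
    return tuple(p.strip().upper() for p in parts)


def join_codes(codes) -> str:
    return ";".join(codes)


def _require_columns(df: pd.DataFrame, required, what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table missing mandatory columns: {missing}")


def _parse_dates(df: pd.DataFrame, col: str, what: str, errors: list[str]) -> pd.Series:
    parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    bad = df.index[parsed.isna() & df[col].notna()]
    for i in bad:
        errors.append(f"{what} row {i}: unparseable {col} {df.loc[i, col]!r}")
    return parsed


def read_tables(
    episodes_path: str | Path, patients_path: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the patients and episodes CSV tables.

    Returns ``(patients, episodes)`` with codes normalized and dates parsed.
    Malformed rows are collected and raised together with their row numbers.
    """
    patients = pd.read_csv(patients_path, dtype={"patient_id": str})
    episodes = pd.read_csv(
        episodes_path, dtype={"patient_id": str, "spell_id": str, "trust_id": str}
    )
    _require_columns(patients, PATIENT_COLUMNS, "patients")
    _require_columns(episodes, EPISODE_COLUMNS, "episodes")

    errors: list[str] = []
    episodes = episodes.copy()
    episodes["admission_date"] = _parse_dates(episodes, "admission_date", "episodes", errors)
    episodes["discharge_date"] = _parse_dates(episodes, "discharge_date", "episodes", errors)
    if errors:
        raise SchemaError("; ".join(errors))

    episodes["diagnosis_codes"] = episodes["diagnosis_codes"].map(parse_codes)
    episodes["procedure_codes"] = episodes["procedure_codes"].map(
        lambda c: parse_codes(c, normalize=False)
    )
    episodes["episode_order"] = episodes["episode_order"].astype(int)
    if (episodes["episode_order"] < 1).any():
        raise SchemaError("episode_order must be >= 1")

    if patients["patient_id"].duplicated().any():
        dup = patients.loc[patients["patient_id"].duplicated(), "patient_id"].tolist()
        raise IntegrityError(f"duplicate patient_id in patients table: {dup[:5]}")
    imd = patients["imd_quintile"]
    bad_imd = imd.dropna()[~imd.dropna().isin([1, 2, 3, 4, 5])]
    if len(bad_imd):
        raise SchemaError(f"imd_quintile outside 1..5 at rows {list(bad_imd.index)[:5]}")
    return patients, episodes


def write_tables(
    patients: pd.DataFrame,
    episodes: pd.DataFrame,
    episodes_path: str | Path,
    patients_path: str | Path,
) -> None:
    """Write tables in the documented CSV schema (round-trip safe)."""
    pats = patients[PATIENT_COLUMNS].copy()
    eps = episodes[EPISODE_COLUMNS].copy()
    for col in ("admission_date", "discharge_date"):
        if np.issubdtype(eps[col].dtype, np.datetime64):
            eps[col] = eps[col].dt.strftime("%Y-%m-%d")
    for col in ("diagnosis_codes", "procedure_codes"):
        eps[col] = eps[col].map(
            lambda v: join_codes(v) if isinstance(v, (tuple, list)) else v
        )
    pats.to_csv(patients_path, index=False)
    eps.to_csv(episodes_path, index=False)


def build_spells(episodes: pd.DataFrame) -> pd.DataFrame:
    """Assemble one spell row per ``spell_id`` from its ordered episodes.

    Spell-level attributes (trust, specialty, admission method, dates) come
    from the first episode; ``pooled_codes`` / ``pooled_procedures`` are the
    union over episodes.  A spell whose episodes disagree on trust keeps the
    first episode's trust with an integrity warning; disagreement on patient
    is an error.
    """
    eps = episodes.sort_values(["spell_id", "episode_order"], kind="stable")
    grouped = eps.groupby("spell_id", sort=True)

    n_patients = grouped["patient_id"].nunique()
    clashes = n_patients[n_patients > 1]
    if len(clashes):
        raise IntegrityError(
            f"spells with conflicting patient_id: {list(clashes.index)[:5]}"
        )
    multi_trust = grouped["trust_id"].nunique()
    for sid in multi_trust[multi_trust > 1].index:
        warnings.warn(
            f"spell {sid}: episodes at different trusts; keeping first episode's trust",
            stacklevel=2,
        )

    columns = [
        "spell_id", "patient_id", "trust_id", "main_specialty",
        "admission_date", "discharge_date", "admission_method",
        "n_episodes", "pooled_codes", "pooled_procedures",
        "length_of_stay_days", "overnight",
    ]
    if len(eps) == 0:
        return pd.DataFrame(columns=columns)

    head = eps.drop_duplicates("spell_id", keep="first").sort_values("spell_id")
    pooled_codes = grouped["diagnosis_codes"].agg(
        lambda lists: frozenset(c for codes in lists for c in codes)
    )
    pooled_procs = grouped["procedure_codes"].agg(
        lambda lists: frozenset(p for procs in lists for p in procs)
    )
    n_eps = grouped.size()

    spells = pd.DataFrame(
        {
            "spell_id": head["spell_id"].to_numpy(),
            "patient_id": head["patient_id"].to_numpy(),
            "trust_id": head["trust_id"].to_numpy(),
            "main_specialty": head["main_specialty"].to_numpy(),
            "admission_date": head["admission_date"].to_numpy(),
            "discharge_date": head["discharge_date"].to_numpy(),
            "admission_method": head["admission_method"].to_numpy(),
            "n_episodes": n_eps.loc[head["spell_id"]].to_numpy(),
            "pooled_codes": pooled_codes.loc[head["spell_id"]].to_numpy(),
            "pooled_procedures": pooled_procs.loc[head["spell_id"]].to_numpy(),
        }
    )
    los = (
        pd.to_datetime(spells["discharge_date"]) - pd.to_datetime(spells["admission_date"])
    ).dt.days.astype(int)
    if (los < 0).any():
        bad = spells.loc[los < 0, "spell_id"].tolist()
        raise IntegrityError(f"discharge before admission in spells {bad[:5]}")
    spells["length_of_stay_days"] = los
    spells["overnight"] = los >= 1
    return spells[columns].reset_index(drop=True)
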