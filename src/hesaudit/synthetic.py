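"""Synthetic hospital-episode data with a planted code-omission mechanism.

Real English hospital episode extracts cannot be shared, so every stage of
the audit pipeline is exercised against synthetic tables that emulate their
structure: patients carrying one of the three audited conditions, an index
spell in an eight-year study window, repeated subsequent spells, episode-level
ICD-10 code lists, demographics echoing the published patient-characteristic
marginals (autism young, DMPC mid/late life, PDD old), trust and specialty
changes, and injected exclusion cases (R69-only spells, dialysis regular
attenders, under-age patients).

The mandatory code is omitted from each subsequent spell with probability

    sigmoid( b0 + b_trust*chg_trust + b_spec*chg_spec
             + b_days*log1p(days)/log1p(1095) + b_case*day_case
             + b_age*(age-50)/50 + b_sex*female + b_rel*related_absent )

so classifier and attribution stages face a well-posed recovery problem:
the planted coefficient signs are the ground truth the Shapley/tau-b stage
should report.  Binary features enter as 0/1; elapsed time and age are
scaled to roughly unit range so a coefficient of 1 means about one logit
across the feature's span.

A single master seed fans out to named substreams (demographics, spells,
omission, noise, exclusions) so adding a stage never perturbs earlier draws;
a fixed seed yields byte-identical CSV output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .codesets import CONDITIONS, condition_specs

__all__ = ["GeneratorConfig", "PlantedTruth", "generate_population", "fixture_small"]

# Published first-spell marginals used to calibrate the demographic draws.
_AGE_BANDS = ((0, 17), (18, 39), (40, 59), (60, 79), (80, 95))
_AGE_PROBS = {
    "autism": (0.572, 0.294, 0.093, 0.036, 0.005),
    "dmpc": (0.0001, 0.010, 0.203, 0.515, 0.2719),
    "pdd": (0.0, 0.0004, 0.010, 0.445, 0.5446),
}
_FEMALE_PROB = {"autism": 0.287, "dmpc": 0.307, "pdd": 0.354}
_ETHNICITY_LEVELS = ("white", "asian", "black", "mixed", "other")
_ETHNICITY_PROBS = {
    "autism": (0.779, 0.048, 0.034, 0.025, 0.114),
    "dmpc": (0.848, 0.045, 0.032, 0.004, 0.071),
    "pdd": (0.936, 0.032, 0.019, 0.003, 0.010),
}
_ETHNICITY_MISSING = {"autism": 0.157, "dmpc": 0.018, "pdd": 0.178}
_IMD_PROBS = {
    "autism": (0.291, 0.229, 0.183, 0.158, 0.139),
    "dmpc": (0.254, 0.219, 0.194, 0.159, 0.174),
    "pdd": (0.161, 0.189, 0.209, 0.219, 0.222),
}
_IMD_MISSING = {"autism": 0.033, "dmpc": 0.046, "pdd": 0.014}

_SPECIALTIES = (
    "paediatrics", "general_medicine", "general_surgery", "geriatric_medicine",
    "psychiatry", "trauma_orthopaedics", "urology", "cardiology",
)
_SPECIALTY_PROBS = {
    "autism": (0.40, 0.12, 0.12, 0.02, 0.14, 0.10, 0.05, 0.05),
    "dmpc": (0.0, 0.34, 0.32, 0.08, 0.02, 0.12, 0.06, 0.06),
    "pdd": (0.0, 0.33, 0.10, 0.27, 0.08, 0.12, 0.05, 0.05),
}

# Distractor codes: common acute/comorbidity codes, chosen to be disjoint
# from every condition's consistency set so they can pad any spell.
_DEFAULT_NOISE_POOL = (
    "I10", "J189", "N390", "K590", "R296", "I251", "J449", "M545", "E780",
    "I489", "R073", "K219", "F059", "W190", "S720", "R54", "B962", "L031",
    "N179", "J969", "I639", "G819", "R410", "E86", "R11", "K529", "A099",
    "J22", "R55", "D649", "M159", "I500", "I219", "Z501",
)

_CONSISTENCY_FILLERS = {
    "autism": None,  # the patient's own index code is reused
    "dmpc": ("E115", "E119", "E110", "E109", "E145", "E101"),
    "pdd": ("F023", "F009", "F03", "F019", "G309", "F051"),
}
_RELATED_FILLERS = {
    "autism": ("F700", "F710", "F720", "F730", "F781", "F790",
               "F800", "F810", "F820", "F830"),
    "pdd": ("G20",),
}

#: Index-spell inconsistency rates reported for the three conditions in the
#: published national audit; used as default planted intercepts.
PUBLISHED_RATES = {"autism": 0.437, "dmpc": 0.086, "pdd": 0.312}

_COEFFICIENT_NAMES = (
    "intercept", "change_of_trust", "change_of_specialty",
    "log_days_since_index", "day_case", "age_effect", "female",
    "related_code_absent",
)

_LOG_DAYS_SCALE = float(np.log1p(1095.0))


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic population.

    ``planted_coefficients`` are on the logit scale for the scaled features
    described in the module docstring.  An ``intercept`` of ``None`` uses a
    per-condition intercept matching the published inconsistency rates
    (43.7% autism, 8.6% DMPC, 31.2% PDD).
    """

    n_patients: Mapping[str, int] = field(
        default_factory=lambda: {"autism": 1000, "dmpc": 1000, "pdd": 600}
    )
    study_window: tuple[str, str] = ("2013-04-01", "2021-03-31")
    n_trusts: int = 30
    mean_subsequent_spells: float = 2.5
    planted_coefficients: dict[str, float | None] = field(
        default_factory=lambda: {
            "intercept": None,
            "change_of_trust": 1.0,
            "change_of_specialty": 0.7,
            "log_days_since_index": 0.8,
            "day_case": 0.6,
            "age_effect": 0.5,
            "female": 0.4,
            "related_code_absent": 1.0,
        }
    )
    related_present_rate: float = 0.5
    mean_gap_days: float = 240.0
    noise_code_pool: tuple[str, ...] = _DEFAULT_NOISE_POOL
    exclusion_rates: dict[str, float] = field(
        default_factory=lambda: {
            "r69_spells": 0.01, "dialysis_patients": 0.01, "underage_patients": 0.01
        }
    )
    seed: int = 0

    def validate(self) -> None:
        for k, v in self.exclusion_rates.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"exclusion rate {k}={v} outside [0, 1]")
        if not 0.0 <= self.related_present_rate <= 1.0:
            raise ValueError("related_present_rate outside [0, 1]")
        if self.mean_subsequent_spells <= 0:
            raise ValueError("mean_subsequent_spells must be > 0")
        start, end = map(pd.Timestamp, self.study_window)
        if (end - start).days < 30:
            raise ValueError("study window too short to place index and subsequent spells")
        unknown = set(self.planted_coefficients) - set(_COEFFICIENT_NAMES)
        if unknown:
            raise ValueError(f"unknown planted coefficients: {sorted(unknown)}")

    def intercept_for(self, condition: str) -> float:
        b0 = self.planted_coefficients.get("intercept")
        if b0 is None:
            return _logit(PUBLISHED_RATES[condition])
        return float(b0)


@dataclass
class PlantedTruth:
    """Ground truth of the omission mechanism for recovery tests.

    ``table`` has one row per generated subsequent target spell with the
    planted omission probability and drawn indicator, plus the feature
    values that entered the linear predictor; ``coefficients`` is the
    per-condition coefficient vector actually used.
    """

    table: pd.DataFrame
    coefficients: dict[str, dict[str, float]]


# Substream indices are frozen: adding a stage must append, never renumber.
_STREAMS = {"demographics": 0, "spells": 1, "omission": 2, "noise": 3, "exclusions": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream],))
    )


def _sample_ages(rng: np.random.Generator, condition: str, n: int) -> np.ndarray:
    probs = np.asarray(_AGE_PROBS[condition], dtype=float)
    probs = probs / probs.sum()
    bands = rng.choice(len(_AGE_BANDS), size=n, p=probs)
    lo = np.array([_AGE_BANDS[b][0] for b in bands])
    hi = np.array([_AGE_BANDS[b][1] for b in bands])
    return rng.integers(lo, hi + 1)


def generate_population(
    config: GeneratorConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, PlantedTruth]:
    """Generate (patients, episodes, truth) under the planted mechanism."""
    config.validate()
    specs = condition_specs()
    start, end = map(pd.Timestamp, config.study_window)
    window_days = (end - start).days

    demo = _rng(config.seed, "demographics")
    sp = _rng(config.seed, "spells")
    om = _rng(config.seed, "omission")
    nz = _rng(config.seed, "noise")
    ex = _rng(config.seed, "exclusions")

    patient_rows: list[dict] = []
    episode_rows: list[dict] = []
    truth_rows: list[dict] = []
    coefficients: dict[str, dict[str, float]] = {}

    trusts = [f"TR{i:02d}" for i in range(1, config.n_trusts + 1)]

    for condition in CONDITIONS:
        n = int(config.n_patients.get(condition, 0))
        if n == 0:
            continue
        spec = specs[condition]
        coefs = {k: float(v) for k, v in config.planted_coefficients.items()
                 if k != "intercept" and v is not None}
        coefs["intercept"] = config.intercept_for(condition)
        coefficients[condition] = coefs

        prefix = {"autism": "AU", "dmpc": "DM", "pdd": "PD"}[condition]
        pids = [f"{prefix}{i:06d}" for i in range(n)]

        ages = _sample_ages(demo, condition, n)
        # Planted under-age patients (mis-coded index diagnoses, later excluded)
        if condition in ("dmpc", "pdd") and config.exclusion_rates["underage_patients"] > 0:
            under = ex.random(n) < config.exclusion_rates["underage_patients"]
            lo, hi = (5, 17) if condition == "dmpc" else (18, 39)
            ages = np.where(under, ex.integers(lo, hi + 1, size=n), ages)
        else:
            under = np.zeros(n, dtype=bool)

        female = demo.random(n) < _FEMALE_PROB[condition]
        sex = np.where(female, "female", "male")
        sex = np.where(demo.random(n) < 0.002, "unknown", sex)
        eth = demo.choice(_ETHNICITY_LEVELS, size=n, p=np.asarray(
            _ETHNICITY_PROBS[condition]) / np.sum(_ETHNICITY_PROBS[condition]))
        eth = np.where(demo.random(n) < _ETHNICITY_MISSING[condition], "not_stated", eth)
        imd = demo.choice([1, 2, 3, 4, 5], size=n, p=np.asarray(
            _IMD_PROBS[condition]) / np.sum(_IMD_PROBS[condition])).astype(float)
        imd = np.where(demo.random(n) < _IMD_MISSING[condition], np.nan, imd)
        frailty = np.round(demo.gamma(2.0, 1.5, size=n), 2)

        index_offset = sp.integers(0, window_days - 20, size=n)
        index_daycase = sp.random(n) < 0.35
        index_los = np.where(index_daycase, 0, 1 + sp.geometric(0.35, size=n))
        index_los = np.minimum(index_los, 30)
        index_trust = sp.choice(trusts, size=n)
        spec_probs = np.asarray(_SPECIALTY_PROBS[condition], dtype=float)
        index_spcy = sp.choice(_SPECIALTIES, size=n, p=spec_probs / spec_probs.sum())
        index_method = np.where(sp.random(n) < 0.5, "elective", "emergency")

        birth_year = np.array([
            (start + pd.Timedelta(days=int(o))).year for o in index_offset
        ]) - ages

        dialysis = ex.random(n) < config.exclusion_rates["dialysis_patients"]

        for i, pid in enumerate(pids):
            patient_rows.append({
                "patient_id": pid, "birth_year": int(birth_year[i]),
                "sex": str(sex[i]), "ethnicity": str(eth[i]),
                "imd_quintile": imd[i], "frailty_placeholder": frailty[i],
            })
            adm0 = start + pd.Timedelta(days=int(index_offset[i]))
            dis0 = adm0 + pd.Timedelta(days=int(index_los[i]))
            index_codes = [spec.index_patterns[
                sp.integers(0, len(spec.index_patterns))].stem]
            index_codes += _draw_noise(nz, config.noise_code_pool, spec)
            _emit_spell(
                episode_rows, nz, pid, f"{pid}-S000", index_trust[i],
                index_spcy[i], adm0, dis0, index_method[i], index_codes, (),
            )

            n_sub = sp.poisson(config.mean_subsequent_spells)
            gaps = np.sort(1 + np.floor(
                sp.exponential(config.mean_gap_days, size=n_sub)).astype(int))
            k_emitted = 0
            for j in range(n_sub):
                adm = dis0 + pd.Timedelta(days=int(gaps[j]))
                if adm > end:
                    continue
                k_emitted += 1
                sid = f"{pid}-S{k_emitted:03d}"
                day_case = sp.random() < 0.45
                los = 0 if day_case else min(int(1 + sp.geometric(0.4)), 30)
                dis = min(adm + pd.Timedelta(days=los), end)
                chg_trust = sp.random() < 0.15
                trust = (
                    trusts[sp.integers(0, len(trusts))] if chg_trust else index_trust[i]
                )
                if chg_trust and trust == index_trust[i]:
                    trust = trusts[(trusts.index(trust) + 1) % len(trusts)]
                chg_trust = trust != index_trust[i]
                chg_spcy = sp.random() < 0.40
                spcy = (
                    _SPECIALTIES[sp.integers(0, len(_SPECIALTIES))]
                    if chg_spcy else index_spcy[i]
                )
                chg_spcy = spcy != index_spcy[i]
                method = "elective" if sp.random() < 0.45 else "emergency"

                related_absent = False
                related_codes: list[str] = []
                if condition in _RELATED_FILLERS:
                    if sp.random() < config.related_present_rate:
                        pool = _RELATED_FILLERS[condition]
                        related_codes = [pool[sp.integers(0, len(pool))]]
                    else:
                        related_absent = True

                days_since = int((adm - dis0).days)
                age_now = (adm.year - birth_year[i])
                lp = (
                    coefs["intercept"]
                    + coefs.get("change_of_trust", 0.0) * chg_trust
                    + coefs.get("change_of_specialty", 0.0) * chg_spcy
                    + coefs.get("log_days_since_index", 0.0)
                    * np.log1p(days_since) / _LOG_DAYS_SCALE
                    + coefs.get("day_case", 0.0) * day_case
                    + coefs.get("age_effect", 0.0) * (age_now - 50) / 50.0
                    + coefs.get("female", 0.0) * (sex[i] == "female")
                    + coefs.get("related_code_absent", 0.0) * related_absent
                )
                p_omit = float(1.0 / (1.0 + np.exp(-lp)))
                omitted = bool(om.random() < p_omit)

                codes = _draw_noise(nz, config.noise_code_pool, spec)
                codes += related_codes
                if not omitted:
                    fillers = _CONSISTENCY_FILLERS[condition]
                    codes.insert(0, index_codes[0] if fillers is None
                                 else fillers[sp.integers(0, len(fillers))])
                if not codes:
                    codes = [str(config.noise_code_pool[
                        nz.integers(0, len(config.noise_code_pool))])]
                _emit_spell(
                    episode_rows, nz, pid, sid, trust, spcy, adm, dis,
                    method, codes, (),
                )
                truth_rows.append({
                    "patient_id": pid, "spell_id": sid, "condition": condition,
                    "omission_prob": p_omit, "omitted": omitted,
                    "change_of_trust": chg_trust, "change_of_specialty": chg_spcy,
                    "days_since_index": days_since, "day_case": day_case,
                    "age_years": int(age_now), "female": bool(sex[i] == "female"),
                    "related_code_absent": related_absent,
                    "patient_underage": bool(under[i]),
                })

            # Injected exclusion-case activity
            if ex.random() < config.exclusion_rates["r69_spells"]:
                adm = dis0 + pd.Timedelta(days=int(1 + ex.integers(0, 200)))
                if adm <= end:
                    codes = [] if ex.random() < 0.3 else ["R69"]
                    _emit_spell(
                        episode_rows, nz, pid, f"{pid}-SR69", index_trust[i],
                        index_spcy[i], adm, adm, "emergency", codes, (),
                    )
            if dialysis[i]:
                for d in range(2):
                    adm = dis0 + pd.Timedelta(days=int(7 + 7 * d))
                    if adm <= end:
                        _emit_spell(
                            episode_rows, nz, pid, f"{pid}-SDIA{d}",
                            index_trust[i], "general_medicine", adm, adm,
                            "regular", ["N185"], ("X40",),
                        )

    patients = pd.DataFrame(patient_rows)
    episodes = pd.DataFrame(episode_rows)
    truth = PlantedTruth(table=pd.DataFrame(truth_rows), coefficients=coefficients)
    return patients, episodes, truth


def _draw_noise(rng: np.random.Generator, pool, spec) -> list[str]:
    """Distractor codes for one spell, never matching the consistency set."""
    k = 1 + rng.poisson(1.2)
    codes = [str(c) for c in rng.choice(pool, size=min(k, len(pool)), replace=False)]
    return [c for c in codes if not spec.is_consistent([c])]


def _emit_spell(
    rows, rng, pid, sid, trust, spcy, adm, dis, method, codes, procedures
) -> None:
    """Append 1–2 episode rows for a spell, distributing its code list."""
    codes = list(codes)
    two_eps = len(codes) >= 2 and rng.random() < 0.25
    splits = [codes[: max(1, len(codes) // 2)], codes[max(1, len(codes) // 2):]] \
        if two_eps else [codes]
    for k, ep_codes in enumerate(splits, start=1):
        rows.append({
            "patient_id": pid, "spell_id": sid, "episode_order": k,
            "trust_id": trust, "main_specialty": spcy,
            "admission_date": adm, "discharge_date": dis,
            "admission_method": method,
            "diagnosis_codes": tuple(ep_codes),
            "procedure_codes": tuple(procedures) if k == 1 else (),
        })


# ---------------------------------------------------------------------------
# Hand-auditable fixture

def fixture_small() -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """A deterministic, hand-enumerated fixture covering every filter.

    One patient per condition with at least one consistent and one
    inconsistent subsequent spell; one R69-only spell; one empty-diagnosis
    spell; one dialysis regular-attender spell (procedure X40); one under-age
    DMPC patient and one under-age PDD patient.  The returned ``expected``
    dict holds the hand-enumerated counts for every exclusion reason and the
    per-condition cohort composition.
    """
    P = [
        # patient_id, birth_year, sex, ethnicity, imd, frailty
        ("PA1", 2005, "female", "white", 1.0, 1.00),
        ("PA2", 1960, "male", "asian", 3.0, 2.50),
        ("PA3", 1940, "female", "white", 4.0, 5.10),
        ("PA4", 2000, "male", "black", 2.0, 0.40),
        ("PA5", 1980, "male", "white", np.nan, 3.30),
    ]
    patients = pd.DataFrame(P, columns=[
        "patient_id", "birth_year", "sex", "ethnicity",
        "imd_quintile", "frailty_placeholder",
    ])

    E = [
        # pid, sid, order, trust, specialty, adm, dis, method, dx, proc
        # PA1: autism, index + consistent + inconsistent + R69-only
        ("PA1", "S-PA1-1", 1, "TR01", "paediatrics", "2015-01-05", "2015-01-07",
         "elective", ("F840",), ()),
        ("PA1", "S-PA1-2", 1, "TR01", "paediatrics", "2015-03-01", "2015-03-02",
         "emergency", ("F840", "J189"), ()),
        ("PA1", "S-PA1-3", 1, "TR02", "general_surgery", "2015-06-01", "2015-06-01",
         "elective", ("J189",), ()),
        ("PA1", "S-PA1-4", 1, "TR01", "general_medicine", "2015-07-01", "2015-07-01",
         "emergency", ("R69",), ()),
        # PA2: dmpc, with a two-episode consistent spell and a dialysis spell
        ("PA2", "S-PA2-1", 1, "TR02", "general_medicine", "2014-05-10", "2014-05-15",
         "emergency", ("E115", "I10"), ()),
        ("PA2", "S-PA2-2", 1, "TR02", "general_medicine", "2014-08-01", "2014-08-03",
         "elective", ("I10",), ()),
        ("PA2", "S-PA2-2", 2, "TR02", "general_medicine", "2014-08-01", "2014-08-03",
         "elective", ("E109",), ()),
        ("PA2", "S-PA2-3", 1, "TR02", "urology", "2015-01-20", "2015-01-20",
         "elective", ("I10",), ()),
        ("PA2", "S-PA2-4", 1, "TR02", "general_medicine", "2015-02-01", "2015-02-01",
         "regular", ("N185",), ("X40",)),
        # PA3: pdd, consistent via F03, inconsistent, empty-diagnosis spell
        ("PA3", "S-PA3-1", 1, "TR03", "geriatric_medicine", "2016-02-01", "2016-02-10",
         "emergency", ("F023", "G20"), ()),
        ("PA3", "S-PA3-2", 1, "TR03", "geriatric_medicine", "2016-05-01", "2016-05-04",
         "emergency", ("F03", "I10"), ()),
        ("PA3", "S-PA3-3", 1, "TR04", "general_medicine", "2016-09-01", "2016-09-02",
         "emergency", ("I639",), ()),
        ("PA3", "S-PA3-4", 1, "TR03", "geriatric_medicine", "2016-10-01", "2016-10-01",
         "elective", (), ()),
        # PA4: dmpc aged 15 at index -> whole patient excluded
        ("PA4", "S-PA4-1", 1, "TR01", "general_medicine", "2015-03-03", "2015-03-04",
         "emergency", ("E115",), ()),
        ("PA4", "S-PA4-2", 1, "TR01", "general_medicine", "2015-06-06", "2015-06-07",
         "elective", ("E119",), ()),
        # PA5: pdd aged 35 at index -> excluded
        ("PA5", "S-PA5-1", 1, "TR05", "general_medicine", "2015-04-04", "2015-04-05",
         "emergency", ("F023",), ()),
    ]
    episodes = pd.DataFrame(E, columns=[
        "patient_id", "spell_id", "episode_order", "trust_id", "main_specialty",
        "admission_date", "discharge_date", "admission_method",
        "diagnosis_codes", "procedure_codes",
    ])
    episodes["admission_date"] = pd.to_datetime(episodes["admission_date"])
    episodes["discharge_date"] = pd.to_datetime(episodes["discharge_date"])

    expected = {
        "n_spells_total": 15,
        "exclusions": {"r69_or_empty": 2, "dialysis": 1, "age": 3},
        "index_spells": {"autism": "S-PA1-1", "dmpc": "S-PA2-1", "pdd": "S-PA3-1"},
        "cohort": {
            "autism": {"n_subsequent": 2, "n_inconsistent": 1,
                       "inconsistent_spells": ["S-PA1-3"]},
            "dmpc": {"n_subsequent": 2, "n_inconsistent": 1,
                     "inconsistent_spells": ["S-PA2-3"]},
            "pdd": {"n_subsequent": 2, "n_inconsistent": 1,
                    "inconsistent_spells": ["S-PA3-3"]},
        },
    }
    return patients, episodes, expected
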