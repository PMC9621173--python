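"""Comorbidity scoring, feature assembly, imputation and encoding."""

import numpy as np
import pandas as pd
import pytest

from hesaudit.codesets import CodePattern, condition_specs
from hesaudit.cohort import apply_exclusions, build_cohort
from hesaudit.covariates import (
    CATEGORICAL_FEATURES,
    NUMERIC_FEATURES,
    Encoder,
    WeightTable,
    assemble_features,
    charlson_table,
    comorbidity_score,
    encode,
    hfrs_table,
    impute,
)
from hesaudit.data_model import IntegrityError


def _toy_table(lookback=365):
    return WeightTable(
        entries=(
            (CodePattern("F00", "prefix"), "F00", 7.1),
            (CodePattern("W19", "prefix"), "W19", 3.2),
        ),
        lookback_days=lookback,
    )


def _spells(rows):
    return pd.DataFrame(
        [{"spell_id": f"S{i}", "admission_date": pd.Timestamp(adm),
          "pooled_codes": frozenset(codes)} for i, (adm, codes) in enumerate(rows)]
    )


class TestComorbidityScore:
    def test_sum_of_matched_weights(self):
        spells = _spells([("2015-01-01", {"F001", "W19"})])
        assert comorbidity_score(spells, "2015-06-01", _toy_table()) == \
            pytest.approx(10.3)

    def test_repeated_code_counts_once(self):
        spells = _spells([("2015-01-01", {"W19"}), ("2015-03-01", {"W190"})])
        assert comorbidity_score(spells, "2015-06-01", _toy_table()) == \
            pytest.approx(3.2)

    def test_spell_outside_lookback_contributes_nothing(self):
        spells = _spells([("2013-01-01", {"F001"})])
        assert comorbidity_score(spells, "2015-03-11", _toy_table(730)) == 0.0

    def test_reference_day_spell_excluded(self):
        spells = _spells([("2015-06-01", {"F001"})])
        assert comorbidity_score(spells, "2015-06-01", _toy_table()) == 0.0

    def test_agrees_with_brute_force_oracle(self):
        """Random patients vs an enumerate-everything oracle (both tables)."""
        rng = np.random.default_rng(17)
        pool = ["F001", "F00", "W19", "I219", "I50", "J449", "E115", "E112",
                "G819", "N185", "C509", "C780", "B20", "R296", "K259", "I10"]
        for table in (charlson_table(), hfrs_table()):
            for _ in range(40):
                n_spells = rng.integers(1, 8)
                rows = []
                for _ in range(n_spells):
                    day = int(rng.integers(0, 1000))
                    codes = set(rng.choice(pool, size=rng.integers(1, 5),
                                           replace=False))
                    rows.append((pd.Timestamp("2013-01-01")
                                 + pd.Timedelta(days=day), codes))
                spells = _spells([(str(d.date()), c) for d, c in rows])
                ref = pd.Timestamp("2013-01-01") + pd.Timedelta(
                    days=int(rng.integers(100, 1200)))
                # oracle: expand every (pattern, spell) pair by hand
                lo = ref - pd.Timedelta(days=table.lookback_days)
                codes_in_window = set()
                for d, c in rows:
                    if lo <= d < ref:
                        codes_in_window |= c
                best: dict[str, float] = {}
                for pat, group, w in table.entries:
                    for c in codes_in_window:
                        hit = c == pat.stem if pat.mode == "exact" \
                            else c.startswith(pat.stem)
                        if hit and w > best.get(group, -np.inf):
                            best[group] = w
                assert comorbidity_score(spells, ref, table) == \
                    pytest.approx(sum(best.values()))


class TestAssembleFeatures:
    @pytest.fixture()
    def assembled(self, fixture_tables, fixture_spells, specs):
        patients, _, _ = fixture_tables
        kept, _ = apply_exclusions(fixture_spells, patients, specs)
        out = {}
        for cond in specs:
            cohort = build_cohort(kept, patients, specs[cond])
            out[cond] = assemble_features(cohort, kept, patients, specs[cond])
        return out

    def test_fixture_rows_match_hand_computation(self, assembled):
        autism = assembled["autism"].set_index("spell_id")
        row = autism.loc["S-PA1-3"]
        assert row["change_of_trust"]  # TR02 vs index TR01
        assert row["change_of_specialty"]  # general_surgery vs paediatrics
        assert row["day_case"]
        assert row["days_since_index"] == 145  # 2015-06-01 minus 2015-01-07
        assert row["inconsistent"]
        assert row["age_years"] == 10
        row2 = autism.loc["S-PA1-2"]
        assert not row2["change_of_trust"] and not row2["inconsistent"]
        assert row2["days_since_index"] == 53

    def test_related_code_flags(self, assembled):
        pdd = assembled["pdd"].set_index("spell_id")
        assert pdd.loc["S-PA3-2", "related_code_absent"]  # no G20 coded
        assert pdd.loc["S-PA3-3", "related_code_absent"]
        dmpc = assembled["dmpc"]
        assert not dmpc["related_code_absent"].any()  # no related set for dmpc

    def test_charlson_sees_prior_diabetes(self, assembled):
        dmpc = assembled["dmpc"].set_index("spell_id")
        # E11.5 (complicated diabetes, weight 2) coded 83 days before S-PA2-2
        assert dmpc.loc["S-PA2-2", "charlson"] == pytest.approx(2.0)

    def test_dangling_spell_reference_raises(self, fixture_tables,
                                             fixture_spells, specs):
        patients, _, _ = fixture_tables
        kept, _ = apply_exclusions(fixture_spells, patients, specs)
        cohort = build_cohort(kept, patients, specs["autism"])
        bad = cohort.copy()
        bad.loc[bad.index[0], "spell_id"] = "NOPE"
        with pytest.raises(IntegrityError):
            assemble_features(bad, kept, patients, specs["autism"])


def _feature_frame():
    n = 12
    return pd.DataFrame({
        "patient_id": [f"P{i}" for i in range(n)],
        "spell_id": [f"S{i}" for i in range(n)],
        "condition": "autism",
        "age_years": np.arange(n, dtype=float),
        "length_of_stay": 1.0, "days_since_index": 10.0,
        "charlson": 0.0, "hfrs": 0.0,
        "imd_quintile": [np.nan, 1, 5, 3, 3, 3, np.nan, 2, 4, 1, 5, 2],
        "frailty_placeholder": 1.0,
        "sex": ["female", "male"] * 6,
        "ethnicity": [None, "white", "asian", "white", "asian", "white",
                      "asian", "white", "asian", "white", "asian", "white"],
        "admission_method": "elective", "main_specialty": "paediatrics",
        "day_case": False, "change_of_trust": False,
        "change_of_specialty": False, "related_code_absent": False,
        "inconsistent": [True, False] * 6,
    })


class TestImpute:
    def test_no_missing_values_is_identity(self):
        f = _feature_frame().fillna({"imd_quintile": 3}).assign(
            ethnicity=lambda d: d["ethnicity"].fillna("white"))
        out, log = impute(f, np.ones(len(f), dtype=bool))
        pd.testing.assert_frame_equal(out, f)
        assert log == {}

    def test_numeric_filled_with_training_mean(self):
        f = _feature_frame()
        mask = np.zeros(len(f), dtype=bool)
        mask[1:6] = True  # training rows 1..5: imd 1,5,3,3,3 -> mean 3.0
        out, log = impute(f, mask)
        assert log["imd_quintile"] == pytest.approx(3.0)
        assert out["imd_quintile"].iloc[0] == pytest.approx(3.0)

    def test_imputation_ignores_non_training_rows(self):
        f = _feature_frame()
        mask = np.zeros(len(f), dtype=bool)
        mask[1:6] = True
        _, log1 = impute(f, mask)
        perturbed = f.copy()
        perturbed.loc[~mask, "imd_quintile"] = 5.0  # corrupt held-out rows
        perturbed.loc[0, "imd_quintile"] = np.nan
        _, log2 = impute(perturbed, mask)
        assert log1["imd_quintile"] == log2["imd_quintile"]

    def test_mode_tie_broken_lexicographically(self):
        f = _feature_frame()
        mask = np.zeros(len(f), dtype=bool)
        mask[1:5] = True  # ethnicity white, asian, white, asian -> tie
        out, log = impute(f, mask)
        assert log["ethnicity"] == "asian"
        assert out["ethnicity"].iloc[0] == "asian"

    def test_entirely_missing_training_feature_raises(self):
        f = _feature_frame()
        f["imd_quintile"] = np.nan
        with pytest.raises(ValueError, match="imd_quintile"):
            impute(f, np.ones(len(f), dtype=bool))


class TestEncode:
    def test_booleans_and_one_hot(self):
        f = _feature_frame().fillna({"imd_quintile": 3}).assign(
            ethnicity=lambda d: d["ethnicity"].fillna("white"))
        X, enc = encode(f)
        assert set(X["day_case"].unique()) <= {0.0, 1.0}
        assert enc.column_map["sex"] == ["sex=female", "sex=male"]
        assert X["sex=female"].sum() == 6
        # column map covers the matrix exactly, grouped by original feature
        flat = [c for cols in enc.column_map.values() for c in cols]
        assert flat == list(X.columns)

    def test_unseen_category_encodes_all_zeros_and_logs(self):
        f = _feature_frame().fillna({"imd_quintile": 3}).assign(
            ethnicity=lambda d: d["ethnicity"].fillna("white"))
        enc = Encoder().fit(f)
        new = f.copy()
        new.loc[0, "ethnicity"] = "martian"
        with pytest.warns(UserWarning, match="martian"):
            X = enc.transform(new)
        eth_cols = enc.column_map["ethnicity"]
        assert X.loc[0, eth_cols].sum() == 0.0
        assert any("martian" in m for m in enc.unseen_log)
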