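"""Exclusion filtering, index-spell detection and consistency labelling."""

import numpy as np
import pandas as pd
import pytest

from hesaudit.cohort import (
    apply_exclusions,
    build_cohort,
    find_index_spell,
    inconsistency_rate,
    label_consistency,
    quarterly_trend,
    temporal_profile,
)
from hesaudit.codesets import condition_specs


def _spell(sid, pid, adm, dis, codes, procs=(), method="elective", trust="TR01"):
    return {
        "spell_id": sid, "patient_id": pid, "trust_id": trust,
        "main_specialty": "general_medicine",
        "admission_date": pd.Timestamp(adm), "discharge_date": pd.Timestamp(dis),
        "admission_method": method, "n_episodes": 1,
        "pooled_codes": frozenset(codes), "pooled_procedures": frozenset(procs),
        "length_of_stay_days": (pd.Timestamp(dis) - pd.Timestamp(adm)).days,
        "overnight": (pd.Timestamp(dis) - pd.Timestamp(adm)).days >= 1,
    }


class TestExclusions:
    def test_fixture_counts_match_hand_enumeration(self, fixture_tables,
                                                   fixture_spells, specs):
        patients, _, expected = fixture_tables
        kept, log = apply_exclusions(fixture_spells, patients, specs)
        assert log["r69_or_empty"] == expected["exclusions"]["r69_or_empty"]
        assert log["dialysis"] == expected["exclusions"]["dialysis"]
        assert log["age"] == expected["exclusions"]["age"]
        assert len(kept) == expected["n_spells_total"] - sum(
            expected["exclusions"].values()
        )

    def test_dialysis_spell_removed_but_patient_retained(self, fixture_tables,
                                                         fixture_spells, specs):
        patients, _, _ = fixture_tables
        kept, _ = apply_exclusions(fixture_spells, patients, specs)
        assert "S-PA2-4" not in set(kept["spell_id"])
        assert "S-PA2-1" in set(kept["spell_id"])

    def test_underage_patients_lose_all_spells(self, fixture_tables,
                                               fixture_spells, specs):
        patients, _, _ = fixture_tables
        kept, log = apply_exclusions(fixture_spells, patients, specs)
        assert not kept["patient_id"].isin(["PA4", "PA5"]).any()
        assert log["age_patients"] == 2

    def test_regular_attendance_with_renal_code_removed(self, specs):
        spells = pd.DataFrame([
            _spell("S1", "P1", "2015-01-01", "2015-01-01", {"N185"},
                   method="regular"),
            _spell("S2", "P1", "2015-02-01", "2015-02-01", {"N185"},
                   method="elective"),
        ])
        patients = pd.DataFrame({"patient_id": ["P1"], "birth_year": [1950]})
        kept, log = apply_exclusions(spells, patients, specs)
        assert log["dialysis"] == 1
        assert set(kept["spell_id"]) == {"S2"}


class TestFindIndexSpell:
    def test_first_matching_spell_even_if_third(self, specs):
        spells = pd.DataFrame([
            _spell("S1", "P1", "2014-01-01", "2014-01-02", {"I10"}),
            _spell("S2", "P1", "2014-06-01", "2014-06-02", {"J189"}),
            _spell("S3", "P1", "2015-01-01", "2015-01-02", {"E115"}),
            _spell("S4", "P1", "2015-06-01", "2015-06-02", {"E115"}),
        ])
        assert find_index_spell(spells, specs["dmpc"]) == "S3"

    def test_no_match_returns_none(self, specs):
        spells = pd.DataFrame([_spell("S1", "P1", "2014-01-01", "2014-01-02",
                                      {"I10"})])
        assert find_index_spell(spells, specs["dmpc"]) is None

    def test_tie_breaks_discharge_then_spell_id(self, specs):
        base = dict(pid="P1", adm="2015-01-01", codes={"F023"})
        spells = pd.DataFrame([
            _spell("S9", base["pid"], base["adm"], "2015-01-05", base["codes"]),
            _spell("S2", base["pid"], base["adm"], "2015-01-03", base["codes"]),
        ])
        assert find_index_spell(spells, specs["pdd"]) == "S2"  # earlier discharge
        spells2 = pd.DataFrame([
            _spell("S9", base["pid"], base["adm"], "2015-01-03", base["codes"]),
            _spell("S2", base["pid"], base["adm"], "2015-01-03", base["codes"]),
        ])
        assert find_index_spell(spells2, specs["pdd"]) == "S2"  # smaller id


class TestLabelConsistency:
    @pytest.mark.parametrize(
        "condition, codes, expected",
        [
            ("pdd", {"F03", "I10"}, True),
            ("dmpc", {"E115"}, True),
            ("dmpc", {"I10"}, False),
            ("autism", {"F849"}, False),
            ("autism", {"F845", "J18"}, True),
        ],
    )
    def test_examples(self, specs, condition, codes, expected):
        assert label_consistency(codes, specs[condition]) is expected

    def test_agrees_with_prefix_expansion_oracle(self, specs):
        """1000 random synthetic spells vs brute-force expansion."""
        rng = np.random.default_rng(13)
        pool = ["F840", "F841", "F845", "F849", "E115", "E10", "E109", "E149",
                "E119", "F023", "F03", "F019", "G309", "G301", "G300", "F051",
                "F059", "I10", "J189", "G20", "R69", "N185", "F700", "F83"]
        for spec in specs.values():
            stems = [(p.stem, p.mode) for p in spec.consistency_patterns]
            for _ in range(334):
                codes = set(rng.choice(pool, size=rng.integers(1, 5),
                                       replace=False))
                oracle = any(
                    (c == s if m == "exact" else c.startswith(s))
                    for c in codes for s, m in stems
                )
                assert label_consistency(codes, spec) == oracle


class TestBuildCohort:
    def test_fixture_cohorts_match_hand_enumeration(self, fixture_tables,
                                                    fixture_spells, specs):
        patients, _, expected = fixture_tables
        kept, _ = apply_exclusions(fixture_spells, patients, specs)
        for cond, spec in specs.items():
            cohort = build_cohort(kept, patients, spec)
            exp = expected["cohort"][cond]
            assert len(cohort) == exp["n_subsequent"]
            assert int((~cohort["consistent"]).sum()) == exp["n_inconsistent"]
            assert list(cohort.loc[~cohort["consistent"], "spell_id"]) == \
                exp["inconsistent_spells"]
            assert set(cohort["index_spell_id"]) == \
                {expected["index_spells"][cond]}

    def test_patient_with_only_index_spell_yields_no_rows(self, specs):
        spells = pd.DataFrame([
            _spell("S1", "P1", "2015-01-01", "2015-01-02", {"E115"})
        ])
        patients = pd.DataFrame({"patient_id": ["P1"], "birth_year": [1950]})
        assert len(build_cohort(spells, patients, specs["dmpc"])) == 0

    def test_overlapping_transfer_spell_floors_days_at_zero(self, specs):
        spells = pd.DataFrame([
            _spell("S1", "P1", "2015-01-01", "2015-01-10", {"E115"}),
            _spell("S2", "P1", "2015-01-05", "2015-01-06", {"I10"}, trust="TR02"),
        ])
        patients = pd.DataFrame({"patient_id": ["P1"], "birth_year": [1950]})
        cohort = build_cohort(spells, patients, specs["dmpc"])
        assert len(cohort) == 1
        assert cohort["days_since_index"].iloc[0] == 0

    def test_rate_is_one_minus_mean_consistent(self, fixture_tables,
                                               fixture_spells, specs):
        patients, _, _ = fixture_tables
        kept, _ = apply_exclusions(fixture_spells, patients, specs)
        cohort = build_cohort(kept, patients, specs["autism"])
        assert inconsistency_rate(cohort) == 1.0 - cohort["consistent"].mean()


class TestTemporalProfiles:
    @pytest.fixture()
    def cohort(self, fixture_tables, fixture_spells, specs):
        patients, _, _ = fixture_tables
        kept, _ = apply_exclusions(fixture_spells, patients, specs)
        return build_cohort(kept, patients, specs["autism"])

    def test_single_bin_equals_overall_rate(self, cohort):
        prof = temporal_profile(cohort, 1096)
        assert len(prof) == 1
        sub = cohort[cohort["in_3y_window"]]
        assert prof["prop_inconsistent"].iloc[0] == pytest.approx(
            1.0 - sub["consistent"].mean()
        )
        assert prof["n_spells"].iloc[0] == len(sub)

    def test_empty_cohort_gives_empty_table(self, cohort):
        assert len(temporal_profile(cohort.iloc[:0], 28)) == 0

    def test_nonpositive_bin_width_rejected(self, cohort):
        with pytest.raises(ValueError):
            temporal_profile(cohort, 0)

    def test_empty_bins_absent_not_zero(self, cohort):
        prof = temporal_profile(cohort, 7)  # two spells ~8 and ~20 weeks out
        assert (prof["n_spells"] > 0).all()
        assert len(prof) == 2

    def test_quarterly_trend_all_consistent_is_zero(self, cohort):
        forced = cohort.copy()
        forced["consistent"] = True
        trend = quarterly_trend(forced)
        assert (trend["prop_inconsistent"] == 0).all()
        assert set(trend["quarter"]) == {"2015Q1"}

    def test_rising_time_effect_shows_in_profile(self):
        """A planted positive log-time coefficient raises later bins."""
        from hesaudit.synthetic import GeneratorConfig, generate_population
        from hesaudit.data_model import build_spells

        cfg = GeneratorConfig(
            n_patients={"autism": 800, "dmpc": 0, "pdd": 0},
            planted_coefficients={
                "intercept": -2.0, "change_of_trust": 0.0,
                "change_of_specialty": 0.0, "log_days_since_index": 3.0,
                "day_case": 0.0, "age_effect": 0.0, "female": 0.0,
                "related_code_absent": 0.0,
            },
            exclusion_rates={"r69_spells": 0, "dialysis_patients": 0,
                             "underage_patients": 0},
            seed=21,
        )
        patients, episodes, _ = generate_population(cfg)
        specs = condition_specs()
        spells = build_spells(episodes)
        kept, _ = apply_exclusions(spells, patients, specs)
        cohort = build_cohort(kept, patients, specs["autism"])
        prof = temporal_profile(cohort, 180)
        big = prof[prof["n_spells"] >= 30]
        assert big["prop_inconsistent"].iloc[-1] > big["prop_inconsistent"].iloc[0]
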