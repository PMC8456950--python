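"""Design-constraint triage, shortlisting and SAR analytics."""

import random
from dataclasses import replace

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bitopic.chemio import parse_smiles
from bitopic.libgen import LibraryProduct, enumerate_library
from bitopic.properties import CnsRuleSet
from bitopic.select import (
    check_design_constraints,
    fold_improvement,
    rank_and_shortlist,
    read_scores,
    round_half_away,
    sar_summary,
)


class TestDesignConstraints:
    def test_bitopic_hit_satisfies_both_interactions(self, compound2):
        report = check_design_constraints(compound2)
        assert report.has_basic_amine
        assert report.has_junction_hbond_pair

    def test_benzene_fails_everything(self):
        report = check_design_constraints("c1ccccc1")
        assert not report.has_basic_amine
        assert not report.has_junction_hbond_pair
        assert not report.overall

    def test_tight_mw_rule_fails_overall(self, compound2):
        report = check_design_constraints(
            compound2, CnsRuleSet(mw_max=300.0))
        assert report.has_basic_amine
        assert not report.property_pass.flags["mw"]
        assert not report.overall

    def test_whole_clean_library_has_basic_amine(self, methyl_synthons,
                                                 clean_catalog):
        products = enumerate_library(methyl_synthons, clean_catalog)
        assert products
        for p in products:
            assert check_design_constraints(p).has_basic_amine


def _mock_products(n: int):
    base = parse_smiles("CN(CCCCC(=O)Nc1ccccc1)C1Cc2ccccc2C1", id="base")
    return [LibraryProduct(molecule=replace(base, id=f"P{i:04d}"),
                           core_id="c", linker_id="l", block_id=f"b{i}",
                           rule_name="amide_coupling")
            for i in range(n)]


class TestShortlist:
    def test_top3_in_score_order(self):
        products = _mock_products(10)
        scores = pd.DataFrame({
            "compound_id": [p.molecule.id for p in products],
            "target": "A2AAR",
            "score": [5.0, -12.0, 3.0, -40.0, 8.0, -7.0, 0.0, 2.0, -1.0, 9.0],
        })
        shortlist = rank_and_shortlist(products, scores, top_n=3,
                                       apply_constraints=False)
        assert [p.molecule.id for p, _, _ in shortlist] == ["P0003", "P0001",
                                                            "P0005"]
        assert [rank for _, _, rank in shortlist] == [1, 2, 3]

    def test_equal_scores_tie_break_by_id(self):
        products = _mock_products(4)
        scores = pd.DataFrame({
            "compound_id": ["P0002", "P0000", "P0003", "P0001"],
            "target": "A2AAR",
            "score": [-5.0, -5.0, -5.0, -1.0],
        })
        shortlist = rank_and_shortlist(products, scores, top_n=3,
                                       apply_constraints=False)
        assert [p.molecule.id for p, _, _ in shortlist] == ["P0000", "P0002",
                                                            "P0003"]

    def test_matches_brute_force_sort_oracle(self):
        rng = random.Random(5)
        products = _mock_products(1000)
        ids = [p.molecule.id for p in products]
        values = [round(rng.uniform(-60, 0), 1) for _ in ids]  # forces ties
        scores = pd.DataFrame({"compound_id": ids, "target": "A2AAR",
                               "score": values})
        shortlist = rank_and_shortlist(products, scores, top_n=500,
                                       apply_constraints=False)
        expected = sorted(zip(values, ids))[:500]
        assert [(s, p.molecule.id) for p, s, _ in shortlist] == expected
        assert len(shortlist) <= 500

    def test_row_order_invariance(self):
        products = _mock_products(20)
        rng = random.Random(9)
        rows = [{"compound_id": p.molecule.id, "target": "A2AAR",
                 "score": rng.uniform(-30, 0)} for p in products]
        straight = rank_and_shortlist(products, pd.DataFrame(rows), 10,
                                      apply_constraints=False)
        rng.shuffle(rows)
        shuffled = rank_and_shortlist(products, pd.DataFrame(rows), 10,
                                      apply_constraints=False)
        assert ([p.molecule.id for p, _, _ in straight]
                == [p.molecule.id for p, _, _ in shuffled])

    def test_missing_scores_excluded_with_warning(self, caplog):
        products = _mock_products(5)
        scores = pd.DataFrame({"compound_id": ["P0000", "P0001"],
                               "target": "A2AAR", "score": [-3.0, -2.0]})
        with caplog.at_level("WARNING"):
            shortlist = rank_and_shortlist(products, scores, top_n=10,
                                           apply_constraints=False)
        assert len(shortlist) == 2
        assert any("excluded" in r.message for r in caplog.records)

    def test_unresolvable_id_rejected(self):
        products = _mock_products(2)
        scores = pd.DataFrame({"compound_id": ["GHOST"], "target": "A2AAR",
                               "score": [-1.0]})
        with pytest.raises(ValueError, match="resolve"):
            rank_and_shortlist(products, scores, top_n=1)

    def test_score_table_validation(self):
        with pytest.raises(ValueError, match="lacks columns"):
            read_scores(pd.DataFrame({"compound_id": ["a"], "score": [1.0]}))


class TestFoldImprovement:
    def test_secondary_pocket_gain_at_adenosine_receptor(self):
        fold = fold_improvement(8.1, 1.2)
        assert fold == pytest.approx(6.75)
        assert round_half_away(fold) == 7

    def test_secondary_pocket_gain_at_dopamine_receptor(self):
        fold = fold_improvement(5.0, 0.90)
        assert fold == pytest.approx(5.556, abs=0.001)
        assert round_half_away(fold) == 6

    def test_identity(self):
        assert fold_improvement(3.3, 3.3) == 1.0

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            fold_improvement(0.0, 1.0)
        with pytest.raises(ValueError):
            fold_improvement(1.0, -2.0)

    @settings(deadline=None, derandomize=True)
    @given(a=st.floats(1e-6, 1e6), b=st.floats(1e-6, 1e6))
    def test_reciprocal_product_is_unity(self, a, b):
        assert (fold_improvement(a, b) * fold_improvement(b, a)
                == pytest.approx(1.0, abs=1e-12))

    def test_round_half_away_from_zero(self):
        assert round_half_away(6.5) == 7
        assert round_half_away(6.49) == 6
        assert round_half_away(-6.5) == -7


class TestSarSummary:
    def test_optimization_fold_change_vs_first_hit(self):
        from bitopic.fixtures import load_assay_table
        summary = sar_summary(load_assay_table(), reference_id="2")
        row = summary.table.loc["30"]
        assert row["fold_vs_2_A2AAR"] == pytest.approx(1.2 / 0.16)
        assert row["fold_vs_2_A2AAR"] == pytest.approx(7.5)

    def test_dual_flag_thresholding(self):
        from bitopic.fixtures import load_assay_table
        summary = sar_summary(load_assay_table(), reference_id="2",
                              dual_threshold_um=1.0)
        # the first hit misses the 1 uM bar at the adenosine receptor
        assert not summary.table.loc["2", "dual_target"]
        assert summary.table.loc["30", "dual_target"]

    def test_missing_target_flags_incomplete(self):
        df = pd.DataFrame({
            "compound_id": ["x", "x", "y"],
            "target": ["A2AAR", "D2R", "A2AAR"],
            "ki_um": [0.5, 0.4, 0.3],
        })
        summary = sar_summary(df, reference_id="x")
        assert not summary.table.loc["x", "incomplete"]
        assert summary.table.loc["y", "incomplete"]
        assert not summary.table.loc["y", "dual_target"]

    def test_non_positive_concentration_rejected(self):
        df = pd.DataFrame({"compound_id": ["x"], "target": ["A2AAR"],
                           "ki_um": [-1.0]})
        with pytest.raises(ValueError):
            sar_summary(df, reference_id="x")
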