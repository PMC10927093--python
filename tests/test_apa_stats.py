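"""Length metrics, switching calls, Fisher/BH primitives, target-set logic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from apakit.config import ApaConfig
from apakit.io import GeneModel
from apakit.stats import (bh_adjust, call_apa_switching, define_target_genes,
                          fisher_de, fisher_exact_two_sided,
                          normalized_utr_length, weighted_utr_length)

from oracles import bh_stepup_naive, fisher_two_sided_exact


class TestLengthMetrics:
    @pytest.mark.parametrize("lengths,counts,expect", [
        ([100, 400], [80, 20], 160.0),
        ([100, 400], [0, 7], 400.0),
        ([100, 300], [5, 5], 200.0),
    ])
    def test_weighted_length(self, lengths, counts, expect):
        assert weighted_utr_length(lengths, counts) == pytest.approx(expect)

    def test_all_zero_counts_is_error(self):
        with pytest.raises(ValueError, match="unquantified"):
            weighted_utr_length([100, 400], [0, 0])

    def test_normalized_length(self):
        assert normalized_utr_length(160, 400) == pytest.approx(40.0)
        assert normalized_utr_length(400, 400) == pytest.approx(100.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(50, 500), st.integers(501, 2000),
           st.integers(0, 100), st.integers(1, 100), st.integers(1, 50))
    def test_proximal_shift_never_lengthens(self, l1, l2, c1, c2, move):
        """Moving count mass from the distal to the proximal isoform never
        increases the weighted length (strictly decreases when it can)."""
        move = min(move, c2)
        before = weighted_utr_length([l1, l2], [c1, c2])
        after = weighted_utr_length([l1, l2], [c1 + move, c2 - move])
        assert after <= before + 1e-9
        if move and l1 < l2:
            assert after < before


class TestFisher:
    def test_worked_example(self):
        assert fisher_exact_two_sided([[3, 1], [1, 3]]) == pytest.approx(
            0.4857142857142857, rel=1e-12)

    def test_extreme_table_tiny_p(self):
        p = fisher_exact_two_sided([[10, 999990], [100, 999900]])
        oracle = fisher_two_sided_exact(10, 999990, 100, 999900)
        assert p == pytest.approx(oracle, rel=1e-9)
        assert p < 1e-10

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_two_sided([[1, -1], [0, 2]])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30),
           st.integers(0, 30))
    def test_matches_exact_enumeration_and_scipy(self, a, b, c, d):
        p = fisher_exact_two_sided([[a, b], [c, d]])
        assert p == pytest.approx(fisher_two_sided_exact(a, b, c, d), rel=1e-12,
                                  abs=1e-300)
        assert p == pytest.approx(sps.fisher_exact([[a, b], [c, d]])[1],
                                  rel=1e-9, abs=1e-300)


class TestBH:
    def test_stepup_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]).tolist() == pytest.approx(
            [0.04, 0.04, 0.04, 0.04])

    def test_single_and_ties(self):
        assert bh_adjust([0.37]).tolist() == [0.37]
        assert bh_adjust([0.5] * 100).tolist() == [0.5] * 100

    def test_nan_propagates_without_entering_ranking(self):
        q = bh_adjust([0.01, np.nan, 0.04])
        assert np.isnan(q[1])
        assert q[[0, 2]].tolist() == pytest.approx(
            bh_stepup_naive(np.array([0.01, 0.04])).tolist())

    def test_matches_naive_oracle(self, rng):
        for m in (1, 2, 10, 100, 500):
            p = rng.uniform(size=m)
            assert np.allclose(bh_adjust(p), bh_stepup_naive(p), rtol=1e-12)


def _cluster_frame(lengths, counts_by_sample, gene="g1"):
    """Minimal cluster table for one plus-strand gene (utr starts at 0)."""
    g = GeneModel(gene, "chr1", "+", 0, max(lengths) + 10)
    rows = []
    for i, l in enumerate(lengths):
        row = {"gene_id": gene, "chrom": "chr1", "strand": "+",
               "rep_pos": l - 1, "tpos": l - 1, "location": "3UTR"}
        for s, counts in counts_by_sample.items():
            row[f"count_{s}"] = counts[i]
        rows.append(row)
    return pd.DataFrame(rows), [g]


class TestSwitching:
    def test_worked_two_isoform_example(self):
        """Isoforms 100/400 nt, usage (0.5,0.5) -> (0.8,0.2): normalized
        lengths 62.5% -> 40%, TSI -0.225, shortened at q < 0.01."""
        clusters, genes = _cluster_frame(
            [100, 400], {"s1": [500, 500], "s2": [800, 200]})
        res = call_apa_switching(clusters, genes, ["s1", "s2"])
        row = res.iloc[0]
        assert row["norm_len_s1"] == pytest.approx(62.5)
        assert row["norm_len_s2"] == pytest.approx(40.0)
        assert row["tsi"] == pytest.approx(-0.225)
        assert row["p"] == pytest.approx(
            fisher_two_sided_exact(500, 500, 800, 200), rel=1e-12)
        assert row["q"] < 0.01
        assert row["switch_class"] == "shortened"

    def test_identical_usage_is_null(self):
        clusters, genes = _cluster_frame(
            [100, 400], {"s1": [50, 50], "s2": [50, 50]})
        res = call_apa_switching(clusters, genes, ["s1", "s2"])
        assert res.iloc[0]["tsi"] == 0.0
        assert res.iloc[0]["switch_class"] == "none"

    def test_label_symmetry(self):
        """Swapping the two samples negates TSI and swaps the label; the
        Fisher p is unchanged."""
        clusters, genes = _cluster_frame(
            [100, 400], {"s1": [500, 500], "s2": [800, 200]})
        fwd = call_apa_switching(clusters, genes, ["s1", "s2"]).iloc[0]
        rev = call_apa_switching(clusters, genes, ["s2", "s1"]).iloc[0]
        assert rev["tsi"] == pytest.approx(-fwd["tsi"])
        assert rev["p"] == pytest.approx(fwd["p"], rel=1e-12)
        assert (fwd["switch_class"], rev["switch_class"]) == ("shortened",
                                                              "lengthened")

    def test_three_samples_use_ols_trend(self):
        clusters, genes = _cluster_frame(
            [100, 400], {"s1": [100, 900], "s2": [500, 500], "s3": [900, 100]})
        res = call_apa_switching(clusters, genes, ["s1", "s2", "s3"])
        row = res.iloc[0]
        assert row["tsi"] < -0.1
        # perfectly linear normalized lengths: slope test is degenerate-exact
        norm = [row[f"norm_len_s{i}"] for i in (1, 2, 3)]
        slope = sps.linregress([0, 1, 2], norm)
        assert row["p"] == pytest.approx(slope.pvalue)

    def test_constant_normalized_length_p_one(self):
        clusters, genes = _cluster_frame(
            [100, 400], {"s1": [10, 10], "s2": [10, 10], "s3": [10, 10]})
        res = call_apa_switching(clusters, genes, ["s1", "s2", "s3"])
        assert res.iloc[0]["p"] == 1.0
        assert res.iloc[0]["switch_class"] == "none"

    def test_tsi_sign_matches_normalized_length_change(self, small_dataset):
        ds = small_dataset
        from apakit.pas import call_pas
        clusters, _ = call_pas(ds.tags, ds.genes, ds.genome,
                               ds.config.sample_names)
        res = call_apa_switching(clusters, ds.genes, ds.config.sample_names)
        tested = res[res["excluded"] == ""]
        s_first, s_last = ds.config.sample_names[0], ds.config.sample_names[-1]
        diff = tested[f"norm_len_{s_last}"] - tested[f"norm_len_{s_first}"]
        assert np.allclose(tested["tsi"], diff / 100.0)
        assert (tested["tsi"].abs() <= 1.0 + 1e-12).all()
        for col in (f"norm_len_{s_first}", f"norm_len_{s_last}"):
            assert ((tested[col] > 0) & (tested[col] <= 100 + 1e-9)).all()


class TestFisherDe:
    def test_fold_and_significance(self):
        """A gene at 10 vs 100 tags in two deep libraries: ~10x fold and an
        astronomically small p."""
        rows = []
        for i in range(3):
            rows.append({"gene_id": f"g{i}", "chrom": "chr1", "strand": "+",
                         "rep_pos": 100 * i, "tpos": 100 * i, "location": "3UTR",
                         "count_s1": [10, 500_000, 499_990][i],
                         "count_s2": [100, 500_000, 499_900][i]})
        de = fisher_de(pd.DataFrame(rows), "s1", "s2")
        row = de.set_index("gene_id").loc["g0"]
        assert row["fold"] == pytest.approx(10.0, rel=0.05)
        assert row["p"] < 1e-10
        assert row["p"] == pytest.approx(
            fisher_two_sided_exact(100, 999_900, 10, 999_990), rel=1e-9)

    def test_equal_cpm_direction_none(self):
        rows = [{"gene_id": "g0", "chrom": "c", "strand": "+", "rep_pos": 1,
                 "tpos": 1, "location": "3UTR", "count_s1": 50, "count_s2": 50},
                {"gene_id": "g1", "chrom": "c", "strand": "+", "rep_pos": 900,
                 "tpos": 900, "location": "3UTR", "count_s1": 950,
                 "count_s2": 950}]
        de = fisher_de(pd.DataFrame(rows), "s1", "s2")
        assert de["fold"].tolist() == pytest.approx([1.0, 1.0])
        assert (de["direction"] == "none").all()

    def test_corrupt_counts_hard_error(self):
        rows = [{"gene_id": "g0", "chrom": "c", "strand": "+", "rep_pos": 1,
                 "tpos": 1, "location": "3UTR", "count_s1": 5, "count_s2": 5}]
        clusters = pd.DataFrame(rows)
        with pytest.raises(ValueError):
            fisher_de(clusters, "s1", "missing")


class TestTargets:
    def test_set_algebra(self):
        assert define_target_genes({"A", "B", "C"}, {"B", "C", "D"}) == {"B", "C"}
        assert define_target_genes({"A"}, {"B"}) == set()
        assert define_target_genes({"A", "B"}, {"A", "B"}, de_up={"B"}) == {"B"}
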