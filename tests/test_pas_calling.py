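"""Poly(A)-site calling: internal-priming filter, clustering, hexamer
annotation, CPM, location classes, and tag accounting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from apakit.config import CallPasConfig
from apakit.pas import (annotate_hexamer, assign_location, call_pas,
                        cluster_cleavage_sites, filter_internal_priming,
                        normalize_cpm)
from apakit.io import GeneModel
from apakit.stats import call_apa_switching

from oracles import a_rich_window_oracle, connected_components_clusters


def _genome_with_downstream(downstream, pos=100):
    return "C" * (pos + 1) + downstream + "C" * 30


class TestInternalPrimingFilter:
    @pytest.mark.parametrize("window,expect", [
        ("AAAAAAAAAAAAAAAAAAAA", True),    # saturating
        ("ACGTACGTACGTACGTACGT", False),   # max run 1
        ("AAAAAACGTACGTACGTACG", True),    # 6-A run at the start
        ("AACAATAACGAACAATAACG", False),   # A-rich but no criterion met
        ("AACAAACATCGGGGGGGGGG", False),   # 6 A in 10, below both cut-offs
        ("AACAAACAACGGGGGGGGGG", True),    # 7 A within a 10-nt sub-window
    ])
    def test_default_thresholds(self, window, expect):
        seq = _genome_with_downstream(window)
        flagged, evaluable = filter_internal_priming(100, "+", seq)
        assert evaluable
        assert flagged is expect
        assert a_rich_window_oracle(window) is expect

    def test_minus_strand_reverse_complements(self):
        # 20 genomic T's upstream of the site read as A's on the minus strand
        seq = "G" * 30 + "T" * 20 + "G" * 30
        flagged, _ = filter_internal_priming(50, "-", seq)
        assert flagged
        flagged_plus, _ = filter_internal_priming(50, "+", seq)
        assert not flagged_plus

    def test_truncated_window_unevaluable(self):
        seq = "C" * 105  # only 4 bases downstream of position 100
        flagged, evaluable = filter_internal_priming(100, "+", seq)
        assert flagged and not evaluable

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=20))
    def test_matches_window_scanning_oracle(self, window):
        seq = _genome_with_downstream(window)
        flagged, _ = filter_internal_priming(100, "+", seq, window=len(window))
        assert flagged == a_rich_window_oracle(window)


class TestClustering:
    def test_large_gap_splits(self):
        labels = cluster_cleavage_sites(np.array([100, 101, 102, 400]), 24)
        assert labels.tolist() == [0, 0, 0, 1]

    def test_chained_single_linkage_merges(self):
        labels = cluster_cleavage_sites(np.array([100, 124, 148]), 24)
        assert labels.tolist() == [0, 0, 0]

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.integers(0, 2000), min_size=1, max_size=50),
           st.integers(1, 50))
    def test_agrees_with_connected_components_oracle(self, positions, window):
        positions = np.array(positions)
        labels = cluster_cleavage_sites(positions, window)
        comps = connected_components_clusters(positions, window)
        expected = {frozenset(c) for c in comps}
        got = {frozenset(np.nonzero(labels == lab)[0].tolist())
               for lab in np.unique(labels)}
        assert got == expected


class TestHexamer:
    def _seq_plus(self, upstream):
        """Genome where `upstream` ends right at the cleavage site (pos=len)."""
        return upstream + "G" * 30, len(upstream)

    def test_direct_hit_with_offset(self):
        up = "C" * 60 + "AATAAA" + "C" * 15  # first base 21 nt upstream
        seq, pos = self._seq_plus(up)
        assert annotate_hexamer(pos, "+", seq) == ("AATAAA", 21)

    def test_canonical_priority_beats_proximity(self):
        # ATTAAA at offset 15 and AATAAA at offset 30: class follows priority
        up = "C" * 51 + "AATAAA" + "C" * 9 + "ATTAAA" + "C" * 9
        seq, pos = self._seq_plus(up)
        assert annotate_hexamer(pos, "+", seq) == ("AATAAA", 30)

    def test_nearest_occurrence_within_class(self):
        up = "C" * 41 + "AATAAA" + "C" * 4 + "AATAAA" + "C" * 24
        seq, pos = self._seq_plus(up)
        assert annotate_hexamer(pos, "+", seq) == ("AATAAA", 30)

    def test_variant_class(self):
        up = "C" * 60 + "TATAAA" + "C" * 15
        seq, pos = self._seq_plus(up)
        assert annotate_hexamer(pos, "+", seq) == ("other-variant", 21)

    def test_no_match_returns_none(self):
        seq, pos = self._seq_plus("CG" * 40)
        assert annotate_hexamer(pos, "+", seq) == ("none", None)

    def test_minus_strand_hit(self):
        # motif on the minus strand 21 nt upstream of cleavage at pos
        pos = 30
        genomic = "G" * (pos + 16) + "TTTATT" + "G" * 40  # revcomp(AATAAA)
        assert annotate_hexamer(pos, "-", genomic) == ("AATAAA", 21)

    def test_truncated_upstream_unevaluable(self):
        assert annotate_hexamer(5, "+", "A" * 200) == ("none", None)


class TestCpmAndLocation:
    def test_cpm_arithmetic(self):
        out = normalize_cpm(np.array([[10.0], [90.0]]))
        assert out[:, 0].tolist() == [1e5, 9e5]

    def test_scale_invariance_and_sum(self):
        counts = pd.DataFrame({"s1": [3, 7, 10], "s2": [30, 70, 100]})
        cpm = normalize_cpm(counts)
        assert np.allclose(cpm["s1"], cpm["s2"])
        assert np.allclose(cpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_zero_total_names_sample(self):
        with pytest.raises(ValueError, match="s2"):
            normalize_cpm(pd.DataFrame({"s1": [5], "s2": [0]}))

    def test_location_precedence(self):
        g = GeneModel("g", "chr1", "+", 500, 1000, cds_start=100, cds_end=500)
        assert assign_location(700, "+", "chr1", [g]) == "3UTR"
        assert assign_location(2000, "+", "chr1", [g]) == "extended"
        assert assign_location(6000, "+", "chr1", [g]) == "other"
        assert assign_location(300, "+", "chr1", [g]) == "CDS"
        assert assign_location(700, "-", "chr1", [g]) == "other"  # wrong strand


class TestCallPas:
    def test_filter_before_cluster_and_accounting(self, small_dataset):
        """Flagged tags never reach a cluster, and the audit reconciles:
        tags_in = retained + flagged + dropped + unassigned."""
        ds = small_dataset
        clusters, audit = call_pas(ds.tags, ds.genes, ds.genome,
                                   ds.config.sample_names)
        assert audit.reconciles()
        assert audit.flagged > 0  # artifacts were planted
        artifact_pos = {(p.model.chrom, p.artifact_genomic)
                        for p in ds.plans if p.artifact_genomic is not None}
        called = set(zip(clusters["chrom"], clusters["rep_pos"]))
        assert not (called & artifact_pos)

    def test_jitter_zero_reps_exact_and_hexamer_recall(self, small_dataset):
        """With jitter 0 and the artifacts filtered, representatives equal
        true cleavage sites exactly and every planted hexamer is recovered."""
        ds = small_dataset
        clusters, _ = call_pas(ds.tags, ds.genes, ds.genome,
                               ds.config.sample_names)
        truth = {}
        for p in ds.plans:
            for g, m, off in zip(p.pas_genomic, p.hexamer_motifs,
                                 p.hexamer_offsets):
                truth[(p.model.gene_id, int(g))] = (m, int(off))
        for r in clusters.itertuples():
            assert (r.gene_id, r.rep_pos) in truth
            assert truth[(r.gene_id, r.rep_pos)] == (r.hexamer_class,
                                                     r.hexamer_offset)
        assert len(clusters) == len(truth)

    def test_jittered_two_site_gene_recovers_two_clusters(self):
        """1000 tags jittered (sd 3) around two sites give exactly two
        clusters with representatives within 2 nt of truth."""
        rng = np.random.default_rng(42)
        g = GeneModel("g", "chr1", "+", 1000, 2400)
        true_sites = [1500, 1900]
        pos = np.concatenate([
            s + np.rint(rng.normal(0, 3, 500)).astype(int) for s in true_sites])
        tags = pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                             "sample": "s1"})
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 3000))}
        clusters, _ = call_pas(tags, [g], genome, ["s1"])
        assert len(clusters) == 2
        for rep, s in zip(sorted(clusters["rep_pos"]), true_sites):
            assert abs(rep - s) <= 2

    def test_min_count_drops_sparse_clusters(self):
        g = GeneModel("g", "chr1", "+", 100, 1000)
        pos = np.array([500] * 10 + [800] * 3)  # 3 < default min_count 5
        tags = pd.DataFrame({"chrom": "chr1", "pos": pos, "strand": "+",
                             "sample": "s1"})
        genome = {"chr1": "C" * 1200}
        clusters, audit = call_pas(tags, [g], genome, ["s1"])
        assert clusters["rep_pos"].tolist() == [500]
        assert audit.dropped_min_count == 3
        assert audit.reconciles()

    def test_zero_tag_gene_reported_unquantified(self):
        g1 = GeneModel("hit", "chr1", "+", 100, 1000)
        g2 = GeneModel("miss", "chr1", "+", 8000, 9000)
        tags = pd.DataFrame({"chrom": "chr1", "pos": [500] * 6, "strand": "+",
                             "sample": "s1"})
        genome = {"chr1": "C" * 14000}
        _, audit = call_pas(tags, [g1, g2], genome, ["s1"])
        assert audit.unquantified_genes == ["miss"]


def test_single_pas_gene_excluded_from_switching(small_dataset):
    ds = small_dataset
    clusters, _ = call_pas(ds.tags, ds.genes, ds.genome, ds.config.sample_names)
    one_pas = clusters.groupby("gene_id").size()
    apa = call_apa_switching(clusters, ds.genes, ds.config.sample_names)
    single = set(one_pas.index[one_pas == 1])
    if single:
        sub = apa[apa["gene_id"].isin(single)]
        assert (sub["excluded"] == "single_pas").all()
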