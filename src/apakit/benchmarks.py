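"""Parameter-recovery experiments on the synthetic-data generator.

Each function simulates a dataset under stated study conditions, runs the
relevant pipeline stage, and scores the result against the generator's
truth table.  The analysis drivers and the reproduction script both call
these; they are ordinary package code, deterministic given their seed.
"""

from __future__ import annotations

import numpy as np

from .config import ApaConfig, SimConfig
from .pas import call_pas
from .simulate import simulate_dataset
from .stats import call_apa_switching, define_target_genes

__all__ = ["ip_filter_benchmark", "pas_recovery_benchmark",
           "hexamer_recall_benchmark", "switching_recovery_benchmark",
           "null_call_rate_benchmark", "target_recovery_benchmark"]


def _called_clusters(ds):
    cfg = ds.config
    return call_pas(ds.tags, ds.genes, ds.genome, cfg.sample_names)


def ip_filter_benchmark(seed: int, n_genes: int = 100) -> dict:
    """Plant A-tract artifacts (rate 0.2, jitter 0) and score the filter.

    Returns the fraction of artifact sites flagged and of true sites
    flagged, measured over every simulated cleavage position.
    """
    from .pas import filter_internal_priming
    cfg = SimConfig(n_genes=n_genes, seed=seed, ip_artifact_rate=0.2,
                    cleavage_jitter_sd=0.0, depth_per_gene=500)
    ds = simulate_dataset(cfg)
    art_flagged = art_total = true_flagged = true_total = 0
    for p in ds.plans:
        seq = ds.genome[p.model.chrom]
        for g in p.pas_genomic:
            flagged, _ = filter_internal_priming(int(g), p.model.strand, seq)
            true_total += 1
            true_flagged += flagged
        if p.artifact_genomic is not None:
            flagged, _ = filter_internal_priming(int(p.artifact_genomic),
                                                 p.model.strand, seq)
            art_total += 1
            art_flagged += flagged
    return {"artifact_sites": art_total,
            "artifact_flagged_fraction": art_flagged / art_total,
            "true_sites": true_total,
            "true_flagged_fraction": true_flagged / true_total}


def pas_recovery_benchmark(seed: int, n_genes: int = 150,
                           tolerance_nt: int = 2) -> dict:
    """Cluster jittered tags (sd 3 nt, depth 1000) and score representative
    recovery: the fraction of true sites with a called representative within
    the tolerance."""
    cfg = SimConfig(n_genes=n_genes, seed=seed, depth_per_gene=1000,
                    cleavage_jitter_sd=3.0)
    ds = simulate_dataset(cfg)
    clusters, _ = _called_clusters(ds)
    reps = {gid: sub["rep_pos"].to_numpy()
            for gid, sub in clusters.groupby("gene_id")}
    hit = total = 0
    for p in ds.plans:
        r = reps.get(p.model.gene_id, np.array([]))
        for g in p.pas_genomic:
            total += 1
            if r.size and np.min(np.abs(r - g)) <= tolerance_nt:
                hit += 1
    return {"true_sites": total, "recovered_fraction": hit / total}


def hexamer_recall_benchmark(seed: int, n_genes: int = 150) -> dict:
    """With jitter 0 every representative equals its true site; score the
    fraction of true sites whose annotated hexamer class and offset match
    the planted signal exactly (canonical-only simulation)."""
    cfg = SimConfig(n_genes=n_genes, seed=seed, depth_per_gene=1000,
                    cleavage_jitter_sd=0.0)
    ds = simulate_dataset(cfg)
    clusters, _ = _called_clusters(ds)
    ann = {(r.gene_id, int(r.rep_pos)): (r.hexamer_class, r.hexamer_offset)
           for r in clusters.itertuples()}
    hit = exact_rep = total = 0
    for p in ds.plans:
        for g, motif, off in zip(p.pas_genomic, p.hexamer_motifs,
                                 p.hexamer_offsets):
            total += 1
            got = ann.get((p.model.gene_id, int(g)))
            if got is not None:
                exact_rep += 1
                if got == (motif, int(off)):
                    hit += 1
    return {"true_sites": total, "rep_exact_fraction": exact_rep / total,
            "hexamer_recall": hit / total}


def switching_recovery_benchmark(seed: int, n_genes: int = 200,
                                 n_shifted: int = 50, depth: float = 500.0,
                                 ) -> dict:
    """Two-sample proximal-shift recovery (delta 0.3): sensitivity among
    truly shifted genes (called shortened with the correct sign) and the
    empirical false-discovery fraction among all switching calls."""
    cfg = SimConfig(n_genes=n_genes, n_shortened=n_shifted, shift_delta=0.3,
                    depth_per_gene=depth, n_samples=2, seed=seed,
                    cleavage_jitter_sd=3.0)
    ds = simulate_dataset(cfg)
    clusters, _ = _called_clusters(ds)
    apa = call_apa_switching(clusters, ds.genes, cfg.sample_names)
    truth = ds.truth.set_index("gene_id")["switch_class"]
    called = apa[apa["switch_class"] != "none"]
    true_short = set(truth.index[truth == "shortened"])
    correct = set(called.loc[called["switch_class"] == "shortened", "gene_id"])
    n_false = sum(1 for r in called.itertuples()
                  if truth[r.gene_id] != r.switch_class)
    return {"n_shifted": len(true_short),
            "sensitivity": len(correct & true_short) / len(true_short),
            "n_called": int(len(called)),
            "false_discovery_fraction": (n_false / len(called)) if len(called) else 0.0}


def null_call_rate_benchmark(seed: int, n_genes: int = 500,
                             n_seeds: int = 20) -> dict:
    """All-null simulations: mean fraction of testable genes called
    switching, which BH at FDR 0.01 must keep at or below the nominal level."""
    rates = []
    for i in range(n_seeds):
        cfg = SimConfig(n_genes=n_genes, n_shortened=0, shift_delta=0.0,
                        depth_per_gene=500, n_samples=2, seed=seed + i,
                        cleavage_jitter_sd=3.0)
        ds = simulate_dataset(cfg)
        clusters, _ = _called_clusters(ds)
        apa = call_apa_switching(clusters, ds.genes, cfg.sample_names)
        tested = apa[apa["excluded"] == ""]
        rates.append((tested["switch_class"] != "none").mean())
    return {"n_seeds": n_seeds, "n_genes": n_genes,
            "mean_call_rate": float(np.mean(rates)),
            "binomial_se": float(np.sqrt(0.01 * 0.99 / (n_genes * n_seeds)))}


def target_recovery_benchmark(seed: int, n_genes: int = 150,
                              n_shifted: int = 40) -> dict:
    """Knockout/rescue design: condition B shifts ``n_shifted`` genes
    proximal, condition C reverses the shift exactly.  The target set
    (shortened in A->B, lengthened in B->C) should equal the true shifted
    set at depth 1000, jitter 0."""
    cfg = SimConfig(n_genes=n_genes, n_shortened=n_shifted, shift_delta=0.3,
                    depth_per_gene=1000, n_samples=3, shift_profile=[0.0, 1.0, 0.0],
                    seed=seed, cleavage_jitter_sd=0.0)
    ds = simulate_dataset(cfg)
    clusters, _ = _called_clusters(ds)
    apa1 = call_apa_switching(clusters, ds.genes, ["s1", "s2"], ApaConfig())
    apa2 = call_apa_switching(clusters, ds.genes, ["s2", "s3"], ApaConfig())
    shortened = set(apa1.loc[apa1["switch_class"] == "shortened", "gene_id"])
    lengthened = set(apa2.loc[apa2["switch_class"] == "lengthened", "gene_id"])
    targets = define_target_genes(shortened, lengthened)
    truth = ds.truth
    true_set = set(truth.loc[truth["switch_class"] == "shortened", "gene_id"])
    return {"n_true": len(true_set), "n_targets": len(targets),
            "exact_match": targets == true_set,
            "jaccard": (len(targets & true_set) / len(targets | true_set))
            if targets | true_set else 1.0}
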