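"""End-to-end orchestration behind the CLI (and importable directly).

Stages run in order: simulate (optional) -> callpas -> apa-test -> de-test
-> targets -> utr-features.  A run manifest records the config snapshot,
input digests, seed and per-stage tag/gene counts; counts reconcile across
stages and the manifest is written before the run is declared complete.
Given identical inputs and seed, every output table is byte-identical
across runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import read_annotation, read_fasta, read_tags
from .pas import call_pas, write_clusters
from .simulate import simulate_dataset, write_dataset
from .stats import call_apa_switching, define_target_genes, fisher_de
from .utr import find_seed_sites, localize_sites, segment_utr, utr_sequence

log = logging.getLogger("apakit")

__all__ = ["run_all", "DataError"]


class DataError(ValueError):
    """Raised when inputs are structurally valid but inconsistent."""


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _load_inputs(cfg: PipelineConfig, outdir: Path):
    if cfg.simulate is not None:
        sim = cfg.simulate.model_copy(update={"seed": cfg.seed})
        log.info("stage=simulate n_genes=%d samples=%d seed=%d",
                 sim.n_genes, sim.n_samples, cfg.seed)
        ds = simulate_dataset(sim)
        paths = write_dataset(ds, outdir / "sim")
        samples = sim.sample_names
        inputs = {k: str(v) for k, v in paths.items()}
        return ds.genome, ds.genes, ds.tags, samples, inputs
    genome = read_fasta(cfg.genome_fasta)
    genes = read_annotation(cfg.annotation, cfg.annotation_dialect)
    tags, skipped = read_tags(cfg.tags)
    if skipped:
        log.warning("stage=read_tags skipped %d strandless records", skipped)
    samples = list(cfg.tags.keys())
    inputs = {"genome": cfg.genome_fasta, "annotation": cfg.annotation,
              **{f"tags_{s}": p for s, p in cfg.tags.items()}}
    return genome, genes, tags, samples, inputs


def run_all(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Execute every configured stage; returns the run manifest."""
    outdir = Path(outdir if outdir is not None else cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, genes, tags, samples, inputs = _load_inputs(cfg, outdir)
    if tags.empty:
        raise DataError("no tags to analyse")

    log.info("stage=callpas tags_in=%d genes=%d", len(tags), len(genes))
    clusters, audit = call_pas(tags, genes, genome, samples, cfg.callpas)
    if clusters.empty:
        raise DataError("no PAS clusters retained")
    write_clusters(clusters, outdir / "pas_clusters.tsv",
                   outdir / "pas_clusters.bed", samples)

    log.info("stage=apa-test samples=%s", ",".join(samples))
    apa = call_apa_switching(clusters, genes, samples, cfg.apa)
    apa.to_csv(outdir / "apa_results.tsv", sep="\t", index=False)

    control = cfg.de.control or samples[0]
    treatment = cfg.de.treatment or samples[-1]
    log.info("stage=de-test control=%s treatment=%s", control, treatment)
    de = fisher_de(clusters, control, treatment, cfg.de)
    de.to_csv(outdir / "de_results.tsv", sep="\t", index=False)

    targets: set[str] = set()
    if cfg.contrasts:
        if len(cfg.contrasts) != 2:
            raise DataError("target-set logic needs exactly two contrasts")
        (a1, b1), (a2, b2) = cfg.contrasts
        apa1 = call_apa_switching(clusters, genes, [a1, b1], cfg.apa)
        apa2 = call_apa_switching(clusters, genes, [a2, b2], cfg.apa)
        shortened = set(apa1.loc[apa1["switch_class"] == "shortened", "gene_id"])
        lengthened = set(apa2.loc[apa2["switch_class"] == "lengthened", "gene_id"])
        targets = define_target_genes(shortened, lengthened)
        log.info("stage=targets shortened=%d lengthened=%d targets=%d",
                 len(shortened), len(lengthened), len(targets))
        (outdir / "target_genes.txt").write_text(
            "".join(f"{g}\n" for g in sorted(targets)))

    _utr_features(cfg, outdir, clusters, genes, genome)

    manifest = {
        "apakit_version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "input_digests": {k: _digest(Path(v)) for k, v in inputs.items()
                          if Path(str(v)).exists()},
        "counts": {
            "tags_in": audit.tags_in,
            "unassigned": audit.unassigned,
            "flagged_internal_priming": audit.flagged,
            "dropped_min_count": audit.dropped_min_count,
            "retained": audit.retained,
            "clusters": int(len(clusters)),
            "genes_tested_apa": int((apa["excluded"] == "").sum()) if len(apa) else 0,
            "genes_called_switching": int((apa.get("switch_class", pd.Series(dtype=object))
                                           != "none").sum()) if len(apa) else 0,
            "genes_tested_de": int(len(de)),
            "target_genes": len(targets),
        },
    }
    if not audit.reconciles():
        raise DataError("tag accounting failed to reconcile")
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    log.info("stage=done outdir=%s", outdir)
    return manifest


def _utr_features(cfg: PipelineConfig, outdir: Path, clusters: pd.DataFrame,
                  genes: list, genome: dict[str, str]) -> None:
    gene_map = {g.gene_id: g for g in genes}
    seg_rows, site_rows = [], []
    mirnas = []
    if cfg.mirna_tsv:
        mdf = pd.read_csv(cfg.mirna_tsv, sep="\t", header=None,
                          names=["mirna_id", "sequence"], comment="#")
        mirnas = list(mdf.itertuples(index=False))
    usable = clusters[clusters["location"].isin(["3UTR", "extended"])]
    for gene_id, block in usable.groupby("gene_id"):
        if len(block) < 2:
            continue
        block = block.sort_values("tpos")
        g = gene_map[gene_id]
        seg = segment_utr(g, int(block["rep_pos"].iloc[0]),
                          int(block["rep_pos"].iloc[-1]))
        seg_rows.append({"gene_id": gene_id, "strand": g.strand,
                         "cutr_length": seg.cutr_length,
                         "autr_length": seg.autr_length})
        if mirnas:
            seq = utr_sequence(g, genome, int(block["rep_pos"].iloc[-1]))
            for m in mirnas:
                sites = find_seed_sites(m.mirna_id, m.sequence, seq)
                loc = localize_sites(sites, seg)
                for r in loc.itertuples(index=False):
                    site_rows.append({"gene_id": gene_id, **r._asdict()})
    pd.DataFrame(seg_rows, columns=["gene_id", "strand", "cutr_length",
                                    "autr_length"]).to_csv(
        outdir / "utr_segmentation.tsv", sep="\t", index=False)
    if mirnas:
        pd.DataFrame(site_rows, columns=["gene_id", "mirna_id", "start", "end",
                                         "site_type", "compartment",
                                         "spans_boundary"]).to_csv(
            outdir / "seed_sites.tsv", sep="\t", index=False)
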