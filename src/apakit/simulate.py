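"""Synthetic 3'-end sequencing data with known ground truth.

The generator builds a small genome and annotation in which every gene
carries 2-4 tandem poly(A) sites in one 3'UTR territory, each with a
canonical polyadenylation hexamer planted 10-30 nt upstream of its cleavage
site.  Tag counts follow a negative-binomial total per gene per sample,
allocated multinomially to sites by per-sample usage vectors; cleavage-site
microheterogeneity is a rounded Normal jitter.  Condition-dependent
proximal-usage shifts, expression fold changes, library-size differences and
internal-priming artifact sites over genomic A-tracts are all recorded in a
truth table so downstream stages can be scored.

Two deliberate idealisations (documented in the methods note):

* the 20-nt window downstream of every *true* cleavage site is re-drawn
  until it is not A-rich — genuine poly(A) sites lack the genomic A-tract
  the internal-priming filter targets, and this makes the
  zero-false-positive contract of the filter exact on simulated data;
* internal-priming artifact tags end exactly at the A-tract's 5' edge
  (oligo-d(T) mispriming is positionally precise at the tract).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .config import SimConfig
from .io import GeneModel, write_annotation, write_fasta, write_tags_bed6

__all__ = ["GenePlan", "SimulatedDataset", "simulate_annotation",
           "inject_internal_priming", "simulate_tags", "simulate_dataset",
           "write_dataset"]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
#: common single-base variants of the canonical signal, by prevalence
VARIANT_HEXAMERS = ["TATAAA", "AGTAAA", "AAGAAA", "AATATA", "AATACA",
                    "CATAAA", "GATAAA", "AATGAA", "TTTAAA", "ACTAAA"]
_COMP = bytes.maketrans(b"ACGT", b"TGCA")


def _revcomp_bytes(s: bytes) -> bytes:
    return s.translate(_COMP)[::-1]


@dataclass
class GenePlan:
    """Ground truth for one simulated gene."""

    model: GeneModel
    utr_length: int
    #: ordered proximal -> distal cleavage sites, transcript coordinates
    pas_transcript: np.ndarray
    hexamer_offsets: np.ndarray
    hexamer_motifs: list[str]
    #: (n_samples, k) per-sample usage probabilities
    usage: np.ndarray
    fold: float
    switch_class: str  # shortened | lengthened | null
    artifact_transcript: int | None = None

    @property
    def pas_genomic(self) -> np.ndarray:
        return np.array([self.model.genomic_pos(int(t)) for t in self.pas_transcript])

    @property
    def artifact_genomic(self) -> int | None:
        if self.artifact_transcript is None:
            return None
        return self.model.genomic_pos(self.artifact_transcript)


@dataclass
class SimulatedDataset:
    config: SimConfig
    genome: dict[str, str]
    plans: list[GenePlan]
    tags: pd.DataFrame = field(repr=False)

    @property
    def genes(self) -> list[GeneModel]:
        return [p.model for p in self.plans]

    @property
    def truth(self) -> pd.DataFrame:
        rows = []
        for p in self.plans:
            rows.append({
                "gene_id": p.model.gene_id,
                "chrom": p.model.chrom,
                "strand": p.model.strand,
                "n_pas": len(p.pas_transcript),
                "switch_class": p.switch_class,
                "fold": p.fold,
                "pas_genomic": ",".join(map(str, p.pas_genomic)),
                "isoform_lengths": ",".join(str(int(t) + 1) for t in p.pas_transcript),
                "usage": ";".join(",".join(f"{u:.6f}" for u in row) for row in p.usage),
                "artifact_pos": -1 if p.artifact_genomic is None else p.artifact_genomic,
            })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# internal-priming style A-richness check (mirrors pas_calling defaults; kept
# local so the generator can sanitise windows without importing the caller)


def _a_rich(window: bytes, max_run: int = 6, max_in_10: int = 7) -> bool:
    run = best = 0
    for b in window:
        run = run + 1 if b in (65, 97) else 0
        best = max(best, run)
    if best >= max_run:
        return True
    is_a = [1 if b in (65, 97) else 0 for b in window]
    for i in range(max(1, len(is_a) - 9)):
        if sum(is_a[i:i + 10]) >= max_in_10:
            return True
    return False


def _downstream_slice(chrom_seq: bytearray, pos: int, strand: str, n: int) -> tuple[int, int]:
    """Genomic half-open interval of the n bases downstream of a cleavage site."""
    if strand == "+":
        return pos + 1, min(pos + 1 + n, len(chrom_seq))
    return max(pos - n, 0), pos


# ---------------------------------------------------------------------------
# stage 1: annotation + genome


def _draw_pas_positions(rng: np.random.Generator, L: int, k: int, min_gap: int) -> np.ndarray:
    """k ordered cleavage sites, approximately evenly spaced, distal at L-1."""
    spacing = L / k
    amp = int(min(0.15 * spacing, (spacing - min_gap) / 2))
    amp = max(amp, 0)
    pos = []
    for i in range(k):
        base = round(spacing * (i + 1)) - 1
        if i == k - 1:
            pos.append(L - 1)
        else:
            pos.append(base + int(rng.integers(-amp, amp + 1)) if amp else base)
    arr = np.array(pos, dtype=int)
    if np.any(np.diff(arr) < min_gap):  # pragma: no cover - geometry precludes it
        raise ValueError("PAS placement violated the minimum gap")
    return arr


def _draw_motifs(rng: np.random.Generator, k: int, cfg: SimConfig) -> list[str]:
    motifs = []
    for _ in range(k):
        if rng.random() < cfg.noncanonical_fraction:
            motifs.append(VARIANT_HEXAMERS[int(rng.integers(len(VARIANT_HEXAMERS)))])
        elif rng.random() < cfg.aataaa_fraction:
            motifs.append("AATAAA")
        else:
            motifs.append("ATTAAA")
    return motifs


def _usage_matrix(cfg: SimConfig, k: int, switch_class: str) -> np.ndarray:
    base = np.array(cfg.usage_baseline if cfg.usage_baseline else [1.0 / k] * k)
    profile = cfg.resolved_shift_profile()
    rows = []
    for f in profile:
        if switch_class == "null" or f == 0.0:
            rows.append(base.copy())
            continue
        delta = cfg.shift_delta * f
        prox = base[0] + delta if switch_class == "shortened" else base[0] - delta
        rest = base[1:] * (1.0 - prox) / (1.0 - base[0])
        rows.append(np.concatenate([[prox], rest]))
    u = np.vstack(rows)
    assert np.allclose(u.sum(axis=1), 1.0, atol=1e-9)
    return u


def _read_oriented(seq: bytearray, model: GeneModel, t: int) -> str:
    g = model.genomic_pos(t)
    b = chr(seq[g])
    return b if model.strand == "+" else chr(_COMP[ord(b)])


def _write_oriented(seq: bytearray, model: GeneModel, t: int, base: str) -> None:
    g = model.genomic_pos(t)
    seq[g] = ord(base) if model.strand == "+" else _COMP[ord(base)]


def _remove_spurious_canonical(seq: bytearray, model: GeneModel, pas_t: int,
                               planted_start: int) -> None:
    """Break chance AATAAA/ATTAAA occurrences in the 10-40 nt upstream scan
    window of a cleavage site so the planted signal is the only one."""
    planted = set(range(planted_start, planted_start + 6))
    for ts in range(max(pas_t - 40, 0), pas_t - 9):
        if ts == planted_start:
            continue
        word = "".join(_read_oriented(seq, model, ts + j) for j in range(6))
        if word in ("AATAAA", "ATTAAA"):
            for j in range(6):
                if ts + j not in planted:
                    _write_oriented(seq, model, ts + j, "C")
                    break


def simulate_annotation(config: SimConfig,
                        rng: np.random.Generator | None = None,
                        ) -> tuple[dict[str, bytearray], list[GenePlan]]:
    """Lay out genes on both strands and write hexamers into a random genome.

    Returns mutable chromosome sequences (so artifact injection can edit
    them) and per-gene plans carrying the full ground truth.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k_lo, k_hi = config.pas_per_gene
    off_lo, off_hi = config.hexamer_offset_range
    gap = config.intergenic_gap

    # class assignment: a fixed random permutation of gene indices
    order = rng.permutation(config.n_genes)
    classes = np.array(["null"] * config.n_genes, dtype=object)
    classes[order[:config.n_shortened]] = "shortened"
    classes[order[config.n_shortened:config.n_shortened + config.n_lengthened]] = "lengthened"
    de_idx = set(rng.permutation(config.n_genes)[:config.n_de_up].tolist())

    plans: list[GenePlan] = []
    chrom_cursors: dict[str, int] = {}
    layouts = []  # (chrom, gene_start, strand, L, k, pas_t, offsets, motifs, i)
    for i in range(config.n_genes):
        chrom = f"chr{i // config.genes_per_chrom + 1}"
        cursor = chrom_cursors.get(chrom, gap)
        k = int(rng.integers(k_lo, k_hi + 1))
        L = int(rng.integers(*config.utr_length_range))
        pas_t = _draw_pas_positions(rng, L, k, config.min_pas_gap)
        offsets = None
        for _ in range(100):
            cand = rng.integers(off_lo, off_hi + 1, size=k)
            # hexamer windows must not collide with each other or cross t=0
            starts = pas_t - cand
            if np.all(starts >= 0) and np.all(np.diff(np.sort(starts)) >= 6):
                offsets = cand
                break
        if offsets is None:
            raise ValueError(f"gene {i}: could not place hexamers in 100 tries")
        strand = "+" if rng.random() < 0.5 else "-"
        motifs = _draw_motifs(rng, k, config)
        layouts.append((chrom, cursor, strand, L, k, pas_t, offsets, motifs, i))
        chrom_cursors[chrom] = cursor + config.cds_length + L + gap

    # random 50% GC chromosomes, then strand-aware hexamer writing
    genome: dict[str, bytearray] = {}
    for chrom, end in chrom_cursors.items():
        seq = rng.integers(0, 4, size=end + gap)
        genome[chrom] = bytearray(_BASES[seq].tobytes())

    for chrom, start, strand, L, k, pas_t, offsets, motifs, i in layouts:
        if strand == "+":
            utr_start = start + config.cds_length
            model = GeneModel(f"g{i + 1:04d}", chrom, "+", utr_start, utr_start + L,
                              cds_start=start, cds_end=utr_start)
        else:
            model = GeneModel(f"g{i + 1:04d}", chrom, "-", start, start + L,
                              cds_start=start + L, cds_end=start + L + config.cds_length)
        seq = genome[chrom]
        for t, off, motif in zip(pas_t, offsets, motifs):
            m = motif.encode()
            g_start = model.genomic_pos(int(t - off))  # genomic pos of motif's first base
            if strand == "+":
                seq[g_start:g_start + 6] = m
            else:
                seq[g_start - 5:g_start + 1] = _revcomp_bytes(m)
        for t, off in zip(pas_t, offsets):
            _remove_spurious_canonical(seq, model, int(t), int(t - off))
        # sanitise the 20 nt downstream of each true cleavage site
        for t in pas_t:
            g = model.genomic_pos(int(t))
            lo, hi = _downstream_slice(seq, g, strand, 20)
            for _ in range(100):
                win = bytes(seq[lo:hi])
                if strand == "-":
                    win = _revcomp_bytes(win)
                if not _a_rich(win):
                    break
                seq[lo:hi] = _BASES[rng.integers(0, 4, size=hi - lo)].tobytes()
            else:  # pragma: no cover
                raise ValueError("could not sanitise a downstream window")
        k_ = len(pas_t)
        plans.append(GenePlan(
            model=model, utr_length=L, pas_transcript=pas_t,
            hexamer_offsets=np.asarray(offsets), hexamer_motifs=motifs,
            usage=_usage_matrix(config, k_, str(classes[i])),
            fold=config.de_fold if i in de_idx else 1.0,
            switch_class=str(classes[i])))
    return genome, plans


# ---------------------------------------------------------------------------
# stage 2: internal-priming artifacts


def inject_internal_priming(genome: dict[str, bytearray], plans: list[GenePlan],
                            config: SimConfig,
                            rng: np.random.Generator | None = None) -> list[int]:
    """Plant genomic A-tracts inside gene bodies, away from true PASs.

    For ``round(ip_artifact_rate * n_genes)`` genes an A-tract of
    ``ip_tract_length`` nt is written into the UTR so that a false cleavage
    site at the tract's 5' edge has 20 downstream A's; the artifact position
    is recorded in the gene's plan.  Returns the genomic artifact positions.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    n_art = int(round(config.ip_artifact_rate * len(plans)))
    if n_art == 0:
        return []
    chosen = rng.permutation(len(plans))[:n_art]
    positions = []
    tract = config.ip_tract_length
    for gi in sorted(chosen.tolist()):
        p = plans[gi]
        L = p.utr_length
        placed = False
        for _ in range(100):
            t_a = int(rng.integers(0, L - tract - 1))
            if np.all(np.abs(p.pas_transcript - t_a) >= 60):
                placed = True
                break
        if not placed:
            raise ValueError(f"{p.model.gene_id}: could not site an A-tract in 100 tries")
        seq = genome[p.model.chrom]
        for dt in range(1, tract + 1):
            g = p.model.genomic_pos(t_a + dt)
            seq[g:g + 1] = b"A" if p.model.strand == "+" else b"T"
        p.artifact_transcript = t_a
        positions.append(p.artifact_genomic)
    return positions


# ---------------------------------------------------------------------------
# stage 3: tags


def simulate_tags(config: SimConfig, plans: list[GenePlan],
                  rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw per-sample tag positions for every gene.

    Totals are negative binomial (Gamma-Poisson; Poisson when dispersion is
    0) with mean ``depth_per_gene x libsize_factor x fold``; tags are
    allocated multinomially to sites by the sample's usage vector, with a
    ``ip_tag_fraction`` share diverted to the gene's artifact site if it has
    one; each true-site tag's 3' end is jittered by rounded
    Normal(0, cleavage_jitter_sd) along the transcript.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    libsize = config.resolved_libsize()
    profile = config.resolved_shift_profile()
    samples = config.sample_names
    out_chrom, out_pos, out_strand, out_sample = [], [], [], []
    for s_idx, sample in enumerate(samples):
        if libsize[s_idx] == 0:
            warnings.warn(f"sample {sample}: zero library-size factor, no tags emitted")
            continue
        for p in plans:
            fold = p.fold if (p.fold != 1.0 and profile[s_idx] > 0) else 1.0
            mean = config.depth_per_gene * libsize[s_idx] * fold
            if config.dispersion > 0:
                lam = rng.gamma(1.0 / config.dispersion, mean * config.dispersion)
                total = int(rng.poisson(lam))
            else:
                total = int(rng.poisson(mean))
            if total == 0:
                continue
            usage = p.usage[s_idx]
            if p.artifact_transcript is not None and config.ip_tag_fraction > 0:
                f = config.ip_tag_fraction
                probs = np.concatenate([usage * (1 - f), [f]])
            else:
                probs = usage
            alloc = rng.multinomial(total, probs)
            t_positions = []
            for site_i, n in enumerate(alloc[:len(usage)]):
                if n == 0:
                    continue
                t = np.full(n, p.pas_transcript[site_i], dtype=int)
                if config.cleavage_jitter_sd > 0:
                    t = t + np.rint(rng.normal(0, config.cleavage_jitter_sd, n)).astype(int)
                t_positions.append(t)
            if len(alloc) > len(usage) and alloc[-1] > 0:
                t_positions.append(np.full(alloc[-1], p.artifact_transcript, dtype=int))
            t_all = np.concatenate(t_positions)
            if p.model.strand == "+":
                g_all = p.model.utr_start + t_all
            else:
                g_all = (p.model.utr_end - 1) - t_all
            out_chrom.append(np.full(len(g_all), p.model.chrom, dtype=object))
            out_pos.append(g_all)
            out_strand.append(np.full(len(g_all), p.model.strand, dtype=object))
            out_sample.append(np.full(len(g_all), sample, dtype=object))
    if not out_pos:
        return pd.DataFrame(columns=["chrom", "pos", "strand", "sample"])
    return pd.DataFrame({
        "chrom": np.concatenate(out_chrom),
        "pos": np.concatenate(out_pos).astype(int),
        "strand": np.concatenate(out_strand),
        "sample": np.concatenate(out_sample),
    })


# ---------------------------------------------------------------------------
# orchestration


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run all generator stages under one seed and return the full dataset."""
    rng = np.random.default_rng(config.seed)
    genome_ba, plans = simulate_annotation(config, rng)
    inject_internal_priming(genome_ba, plans, config, rng)
    tags = simulate_tags(config, plans, rng)
    genome = {c: s.decode() for c, s in genome_ba.items()}
    return SimulatedDataset(config=config, genome=genome, plans=plans, tags=tags)


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA, BED12 + GFF3 annotation, per-sample BED6 tags, truth TSV
    and the config YAML; returns the paths written."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["genome"] = outdir / "genome.fa"
    write_fasta(ds.genome, paths["genome"])
    paths["annotation_bed12"] = outdir / "annotation.bed12"
    write_annotation(ds.genes, paths["annotation_bed12"], "bed12")
    paths["annotation_gff3"] = outdir / "annotation.gff3"
    write_annotation(ds.genes, paths["annotation_gff3"], "gff3")
    tagdir = outdir / "tags"
    tagdir.mkdir(exist_ok=True)
    for sample in ds.config.sample_names:
        sub = ds.tags[ds.tags["sample"] == sample]
        path = tagdir / f"{sample}.bed"
        write_tags_bed6(sub, path)
        paths[f"tags_{sample}"] = path
    paths["truth"] = outdir / "truth.tsv"
    ds.truth.to_csv(paths["truth"], sep="\t", index=False)
    paths["config"] = outdir / "sim_config.yaml"
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(ds.config.model_dump(), fh, sort_keys=True)
    return paths
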