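"""Poly(A)-site calling from cleavage-site tags.

Stages, in order: assign tags to genes (strand-aware territory plus a
downstream extension), flag internal-priming artifacts by examining the
genomic sequence 1-20 nt downstream of each cleavage site, single-linkage
cluster the retained cleavage coordinates, annotate each cluster with its
polyadenylation hexamer and genomic-location class, and normalize per-sample
counts to counts-per-million.  Flagged tags never contribute to any cluster;
per-gene tag counts reconcile exactly: input = clustered + flagged +
below-min-count + unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CallPasConfig
from .io import GeneModel, revcomp
from .simulate import VARIANT_HEXAMERS

__all__ = ["filter_internal_priming", "cluster_cleavage_sites", "annotate_hexamer",
           "normalize_cpm", "assign_location", "call_pas", "PasAudit"]

#: hexamer search priority: canonical signals before single-base variants
HEXAMER_PRIORITY = ["AATAAA", "ATTAAA"] + VARIANT_HEXAMERS


# ---------------------------------------------------------------------------
# internal-priming filter


def filter_internal_priming(pos: int, strand: str, chrom_seq: str,
                            max_run: int = 6, max_in_10: int = 7,
                            window: int = 20) -> tuple[bool, bool]:
    """Flag a cleavage site as a putative internal-priming artifact.

    Examines the ``window`` genomic bases 1..window downstream of the
    cleavage site (reverse-complemented on the minus strand).  The site is
    flagged iff the window contains >= ``max_run`` consecutive A, or >=
    ``max_in_10`` A within any 10-nt sub-window.  If fewer than 10 bases are
    available before the contig end, the site is unevaluable (and treated as
    flagged so it never enters downstream statistics).

    Returns ``(flagged, evaluable)``.
    """
    if strand == "+":
        seq = chrom_seq[pos + 1:pos + 1 + window]
    else:
        seq = revcomp(chrom_seq[max(pos - window, 0):pos])
    if len(seq) < 10:
        return True, False
    seq = seq.upper()
    run = best = 0
    for b in seq:
        run = run + 1 if b == "A" else 0
        if run > best:
            best = run
    if best >= max_run:
        return True, True
    is_a = np.frombuffer(seq.encode(), dtype="S1") == b"A"
    if len(is_a) >= 10:
        csum = np.concatenate([[0], np.cumsum(is_a)])
        if np.max(csum[10:] - csum[:-10]) >= max_in_10:
            return True, True
    return False, True


# ---------------------------------------------------------------------------
# clustering


def cluster_cleavage_sites(positions: np.ndarray, window: int = 24) -> np.ndarray:
    """Single-linkage cluster sorted-or-unsorted cleavage coordinates.

    Consecutive sorted coordinates with a gap <= ``window`` share a cluster.
    Returns an integer cluster label per input position (labels ordered by
    genomic coordinate).
    """
    positions = np.asarray(positions)
    if positions.size == 0:
        return np.array([], dtype=int)
    order = np.argsort(positions, kind="stable")
    sorted_pos = positions[order]
    breaks = np.diff(sorted_pos) > window
    labels_sorted = np.concatenate([[0], np.cumsum(breaks)])
    labels = np.empty(len(positions), dtype=int)
    labels[order] = labels_sorted
    return labels


def _representative(positions: np.ndarray, strand: str) -> int:
    """Modal coordinate; ties broken toward the stop codon (proximal side)."""
    vals, counts = np.unique(positions, return_counts=True)
    tied = vals[counts == counts.max()]
    return int(tied.min() if strand == "+" else tied.max())


# ---------------------------------------------------------------------------
# hexamer annotation


def annotate_hexamer(rep_pos: int, strand: str, chrom_seq: str,
                     scan: tuple[int, int] = (10, 40)) -> tuple[str, int | None]:
    """Polyadenylation-signal class and offset for a cluster representative.

    Scans ``scan[0]``..``scan[1]`` nt upstream of the cleavage site
    (strand-aware) for AATAAA, then ATTAAA, then the common single-base
    variants; the first motif class with a hit wins, the occurrence nearest
    the cleavage site breaks ties within a class.  The offset is the
    distance (nt) from the cleavage site to the motif's first (5'-most)
    base.  Returns ``("none", None)`` when nothing matches or the upstream
    window is truncated.
    """
    lo, hi = scan
    need = hi + 1  # motif starting `hi` upstream still ends within hi-5
    if strand == "+":
        if rep_pos - need < -1:
            return "none", None
        region = chrom_seq[rep_pos - hi:rep_pos - lo + 6]
    else:
        if rep_pos + need > len(chrom_seq):
            return "none", None
        region = revcomp(chrom_seq[rep_pos + lo - 5:rep_pos + hi + 1])
    region = region.upper()
    # region[i] is `hi - i` nt upstream of the cleavage site
    for motif in HEXAMER_PRIORITY:
        best: int | None = None
        start = region.find(motif)
        while start != -1:
            offset = hi - start
            if lo <= offset <= hi and (best is None or offset < best):
                best = offset
            start = region.find(motif, start + 1)
        if best is not None:
            cls = motif if motif in ("AATAAA", "ATTAAA") else "other-variant"
            return cls, best
    return "none", None


# ---------------------------------------------------------------------------
# CPM and location


def normalize_cpm(counts: pd.DataFrame | np.ndarray,
                  totals: np.ndarray | None = None):
    """Per-sample counts-per-million.

    ``counts`` has one column (or axis-1 entry) per sample; ``totals``
    defaults to the column sums.  A zero library total is a hard error.
    """
    arr = np.asarray(counts, dtype=float)
    tot = arr.sum(axis=0) if totals is None else np.asarray(totals, dtype=float)
    if np.any(tot <= 0):
        bad = np.nonzero(tot <= 0)[0]
        names = (list(counts.columns[bad]) if isinstance(counts, pd.DataFrame)
                 else bad.tolist())
        raise ValueError(f"zero library total for sample(s): {names}")
    cpm = arr * 1e6 / tot
    if isinstance(counts, pd.DataFrame):
        return pd.DataFrame(cpm, index=counts.index, columns=counts.columns)
    return cpm


def assign_location(rep_pos: int, strand: str, chrom: str,
                    genes: list[GeneModel], extension_bp: int = 4000) -> str:
    """Genomic-location class with precedence 3'UTR > extended > intron > CDS > other."""
    in_ext = in_cds = False
    for g in genes:
        if g.chrom != chrom or g.strand != strand:
            continue
        if g.utr_start <= rep_pos < g.utr_end:
            return "3UTR"
        if strand == "+" and g.utr_end <= rep_pos < g.utr_end + extension_bp:
            in_ext = True
        if strand == "-" and g.utr_start - extension_bp <= rep_pos < g.utr_start:
            in_ext = True
        if (g.cds_start is not None and g.cds_start <= rep_pos < g.cds_end):
            in_cds = True
    if in_ext:
        return "extended"
    # intron class would sit here; the tandem-UTR model carries no introns
    if in_cds:
        return "CDS"
    return "other"


# ---------------------------------------------------------------------------
# the full caller


@dataclass
class PasAudit:
    """Per-run tag accounting; all categories sum to tags_in."""

    tags_in: int = 0
    unassigned: int = 0
    flagged: int = 0
    dropped_min_count: int = 0
    retained: int = 0
    unevaluable_sites: int = 0
    unquantified_genes: list[str] = field(default_factory=list)

    def reconciles(self) -> bool:
        return self.tags_in == (self.unassigned + self.flagged
                                + self.dropped_min_count + self.retained)


def _assign_tags_to_genes(tags: pd.DataFrame, genes: list[GeneModel],
                          extension_bp: int) -> pd.Series:
    """Gene id per tag (NaN when no gene claims it).

    A tag belongs to a gene when it lies on the gene's strand within the PAS
    territory or at most ``extension_bp`` downstream of the annotated end.
    """
    gene_ids = pd.Series(pd.NA, index=tags.index, dtype=object)
    for (chrom, strand), sub in tags.groupby(["chrom", "strand"], sort=False):
        cands = [g for g in genes if g.chrom == chrom and g.strand == strand]
        if not cands:
            continue
        if strand == "+":
            starts = np.array([g.utr_start for g in cands])
            ends = np.array([g.utr_end + extension_bp for g in cands])
        else:
            starts = np.array([g.utr_start - extension_bp for g in cands])
            ends = np.array([g.utr_end for g in cands])
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        names = np.array([cands[i].gene_id for i in order], dtype=object)
        idx = np.searchsorted(starts, sub["pos"].to_numpy(), side="right") - 1
        ok = (idx >= 0) & (sub["pos"].to_numpy() < ends[np.clip(idx, 0, None)])
        assigned = np.where(ok, names[np.clip(idx, 0, None)], pd.NA)
        gene_ids.loc[sub.index] = assigned
    return gene_ids


def call_pas(tags: pd.DataFrame, genes: list[GeneModel], genome: dict[str, str],
             samples: list[str] | None = None,
             config: CallPasConfig | None = None) -> tuple[pd.DataFrame, PasAudit]:
    """Turn cleavage-site tags into filtered, annotated, normalized clusters.

    Tags are pooled across samples for clustering, then counted per sample.
    Returns a cluster table (one row per retained PAS cluster, with
    per-sample raw and CPM counts, hexamer class/offset, location class) and
    a :class:`PasAudit` whose categories reconcile with the input count.
    """
    cfg = config or CallPasConfig()
    if samples is None:
        samples = sorted(tags["sample"].unique().tolist())
    audit = PasAudit(tags_in=len(tags))
    by_gene = dict(list(tags.groupby(
        _assign_tags_to_genes(tags, genes, cfg.extension_bp), sort=False)))
    audit.unassigned = audit.tags_in - sum(len(v) for v in by_gene.values())

    rows = []
    gene_map = {g.gene_id: g for g in genes}
    for g in genes:
        sub = by_gene.get(g.gene_id)
        if sub is None or sub.empty:
            audit.unquantified_genes.append(g.gene_id)
            continue
        chrom_seq = genome[g.chrom]
        pos = sub["pos"].to_numpy()
        uniq = np.unique(pos)
        flag_map: dict[int, bool] = {}
        for p in uniq:
            flagged, evaluable = filter_internal_priming(
                int(p), g.strand, chrom_seq, cfg.ip_max_run, cfg.ip_max_in_10,
                cfg.ip_window)
            if not evaluable:
                audit.unevaluable_sites += 1
            flag_map[int(p)] = flagged
        tag_flagged = np.array([flag_map[int(p)] for p in pos])
        audit.flagged += int(tag_flagged.sum())
        kept = sub[~tag_flagged]
        if kept.empty:
            audit.unquantified_genes.append(g.gene_id)
            continue
        labels = cluster_cleavage_sites(kept["pos"].to_numpy(), cfg.window)
        for lab in np.unique(labels):
            members = kept[labels == lab]
            pooled = len(members)
            if pooled < cfg.min_count:
                audit.dropped_min_count += pooled
                continue
            audit.retained += pooled
            rep = _representative(members["pos"].to_numpy(), g.strand)
            counts = {s: int((members["sample"] == s).sum()) for s in samples}
            hex_cls, hex_off = annotate_hexamer(rep, g.strand, chrom_seq,
                                                cfg.hexamer_scan)
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "rep_pos": rep,
                "cluster_start": int(members["pos"].min()),
                "cluster_end": int(members["pos"].max()) + 1,
                **{f"count_{s}": counts[s] for s in samples},
                "hexamer_class": hex_cls, "hexamer_offset": hex_off,
            })
    clusters = pd.DataFrame(rows)
    if clusters.empty:
        return clusters, audit
    for s in samples:
        if clusters[f"count_{s}"].sum() == 0:
            clusters[f"cpm_{s}"] = 0.0
    count_cols = [f"count_{s}" for s in samples]
    nonzero = [c for c in count_cols if clusters[c].sum() > 0]
    cpm = normalize_cpm(clusters[nonzero])
    for c in nonzero:
        clusters[c.replace("count_", "cpm_")] = cpm[c]
    clusters["location"] = [
        assign_location(int(r.rep_pos), r.strand, r.chrom,
                        [gene_map[r.gene_id]], cfg.extension_bp)
        for r in clusters.itertuples()]
    # proximal -> distal rank within each gene (strand-aware)
    clusters["tpos"] = [
        gene_map[r.gene_id].transcript_pos(int(r.rep_pos))
        for r in clusters.itertuples()]
    clusters = clusters.sort_values(["gene_id", "tpos"]).reset_index(drop=True)
    clusters["rank"] = clusters.groupby("gene_id").cumcount() + 1
    return clusters, audit


def write_clusters(clusters: pd.DataFrame, tsv_path, bed_path=None,
                   samples: list[str] | None = None) -> None:
    """Write the cluster table as TSV and (optionally) a BED6 track
    (name = gene:rank, score = pooled count)."""
    clusters.to_csv(tsv_path, sep="\t", index=False)
    if bed_path is None:
        return
    count_cols = [c for c in clusters.columns if c.startswith("count_")]
    with open(bed_path, "w") as fh:
        for r in clusters.itertuples():
            pooled = int(sum(getattr(r, c) for c in count_cols))
            fh.write(f"{r.chrom}\t{r.rep_pos}\t{r.rep_pos + 1}\t"
                     f"{r.gene_id}:{r.rank}\t{pooled}\t{r.strand}\n")
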