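"""Readers and writers for the formats the pipeline touches.

The in-memory model is deliberately small: a :class:`GeneModel` per gene
(strand, constitutive-UTR anchor, tandem-PAS territory) and a tidy tag table
(one row per uniquely mapped 3'-end tag, its 3'-most base being the putative
cleavage site).  All genomic coordinates are 0-based half-open (BED
convention) and all interval logic is strand-aware: "proximal" always means
nearer the stop codon, whichever strand the gene is on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GeneModel",
    "AnnotationError",
    "TagFileError",
    "read_annotation",
    "write_annotation",
    "read_tags",
    "read_fasta",
    "write_fasta",
    "write_tags_bed6",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class AnnotationError(ValueError):
    """Raised for malformed or empty annotation input."""


class TagFileError(ValueError):
    """Raised for malformed tag (BED6) input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene's tandem 3'UTR territory.

    Parameters
    ----------
    gene_id : unique identifier.
    chrom, strand : genomic location; strand in ``{'+', '-'}``.
    utr_start, utr_end : half-open genomic interval of the PAS territory
        (from the base after the stop codon to the annotated distal end).
    cds_start, cds_end : optional CDS interval, used only for genomic
        location classification of clusters.
    """

    gene_id: str
    chrom: str
    strand: str
    utr_start: int
    utr_end: int
    cds_start: int | None = None
    cds_end: int | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(f"{self.gene_id}: strand must be + or -")
        if self.utr_end <= self.utr_start:
            raise AnnotationError(f"{self.gene_id}: empty PAS territory")

    @property
    def cutr_anchor(self) -> int:
        """Genomic coordinate of the first 3'UTR base (after the stop codon)."""
        return self.utr_start if self.strand == "+" else self.utr_end - 1

    @property
    def distal_end(self) -> int:
        """Genomic coordinate of the annotated distal-most UTR base."""
        return self.utr_end - 1 if self.strand == "+" else self.utr_start

    def transcript_pos(self, genomic: int) -> int:
        """Transcript coordinate (0 = first UTR base) of a genomic position."""
        if self.strand == "+":
            return genomic - self.utr_start
        return (self.utr_end - 1) - genomic

    def genomic_pos(self, transcript: int) -> int:
        """Inverse of :meth:`transcript_pos`."""
        if self.strand == "+":
            return self.utr_start + transcript
        return (self.utr_end - 1) - transcript

    def isoform_length(self, cleavage_genomic: int) -> int:
        """3'UTR isoform length (nt) for a cleavage at the given genomic base."""
        return self.transcript_pos(cleavage_genomic) + 1


# ---------------------------------------------------------------------------
# annotation


def _models_from_bed12(df: pd.DataFrame, path: str) -> list[GeneModel]:
    genes = []
    for i, row in df.iterrows():
        chrom, start, end = row[0], int(row[1]), int(row[2])
        name, strand = str(row[3]), str(row[5])
        thick_start, thick_end = int(row[6]), int(row[7])
        if strand == "+":
            gm = GeneModel(name, chrom, strand, thick_end, end,
                           cds_start=start, cds_end=thick_end)
        elif strand == "-":
            gm = GeneModel(name, chrom, strand, start, thick_start,
                           cds_start=thick_start, cds_end=end)
        else:
            raise AnnotationError(f"{path}, line {i + 1}: bad strand {strand!r}")
        genes.append(gm)
    return genes


def _models_from_gff3(path: str) -> list[GeneModel]:
    utr: dict[str, tuple] = {}
    cds: dict[str, tuple] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 9:
                raise AnnotationError(f"{path}, line {lineno}: expected 9 columns")
            chrom, _, ftype, start, end, _, strand, _, attrs = parts
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = fields.get("ID") or fields.get("Parent")
            if gid is None:
                raise AnnotationError(f"{path}, line {lineno}: no ID/Parent attribute")
            gid = gid.split(":")[-1]
            iv = (chrom, int(start) - 1, int(end), strand)  # GFF3 is 1-based closed
            if ftype == "three_prime_UTR":
                utr[gid] = iv
            elif ftype == "CDS":
                cds[gid] = iv
    genes = []
    for gid, (chrom, s, e, strand) in utr.items():
        c = cds.get(gid)
        genes.append(GeneModel(gid, chrom, strand, s, e,
                               cds_start=c[1] if c else None,
                               cds_end=c[2] if c else None))
    return genes


def read_annotation(path: str | Path, dialect: str = "bed12",
                    on_overlap: str = "error") -> list[GeneModel]:
    """Read gene models from BED12 or a gene-level GFF3.

    BED12 semantics: the PAS territory runs from the end of the thick (CDS)
    interval to the transcript end, on the annotated strand.  Genes whose
    territories overlap another gene's on the same strand are rejected
    (``on_overlap='error'``) or dropped with a warning (``'drop'``).
    """
    path = str(path)
    if not Path(path).exists():
        raise AnnotationError(f"annotation file not found: {path}")
    if dialect == "bed12":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#")
        except pd.errors.EmptyDataError:
            raise AnnotationError(f"no genes in annotation: {path}") from None
        if df.shape[1] < 8:
            raise AnnotationError(f"{path}: BED12 needs >= 8 columns")
        genes = _models_from_bed12(df, path)
    elif dialect == "gff3":
        genes = _models_from_gff3(path)
    else:
        raise ValueError(f"unknown annotation dialect {dialect!r}")
    if not genes:
        raise AnnotationError(f"no genes in annotation: {path}")
    ids = [g.gene_id for g in genes]
    if len(set(ids)) != len(ids):
        raise AnnotationError(f"{path}: duplicate gene ids")
    bad = _overlapping_ids(genes)
    if bad:
        if on_overlap == "drop":
            warnings.warn(f"dropping {len(bad)} genes with overlapping territories")
            genes = [g for g in genes if g.gene_id not in bad]
        else:
            raise AnnotationError(
                f"{path}: overlapping same-strand territories: {sorted(bad)[:5]}...")
    if not genes:
        raise AnnotationError(f"no genes left after overlap filtering: {path}")
    return genes


def _overlapping_ids(genes: list[GeneModel]) -> set[str]:
    bad: set[str] = set()
    by_cs: dict[tuple, list[GeneModel]] = {}
    for g in genes:
        by_cs.setdefault((g.chrom, g.strand), []).append(g)
    for grp in by_cs.values():
        grp.sort(key=lambda g: g.utr_start)
        for a, b in zip(grp, grp[1:]):
            if b.utr_start < a.utr_end:
                bad.add(a.gene_id)
                bad.add(b.gene_id)
    return bad


def write_annotation(genes: Iterable[GeneModel], path: str | Path,
                     dialect: str = "bed12") -> None:
    """Write gene models as BED12 or gene-level GFF3 (inverse of read_annotation)."""
    genes = list(genes)
    with open(path, "w") as fh:
        if dialect == "bed12":
            for g in genes:
                if g.strand == "+":
                    start = g.cds_start if g.cds_start is not None else g.utr_start
                    end, thick_s, thick_e = g.utr_end, start, g.utr_start
                else:
                    end = g.cds_end if g.cds_end is not None else g.utr_end
                    start, thick_s, thick_e = g.utr_start, g.utr_end, end
                size = end - start
                fh.write("\t".join(map(str, [
                    g.chrom, start, end, g.gene_id, 0, g.strand,
                    thick_s, thick_e, "0,0,0", 1, size, 0])) + "\n")
        elif dialect == "gff3":
            fh.write("##gff-version 3\n")
            for g in genes:
                span = [g.utr_start, g.utr_end]
                if g.cds_start is not None:
                    span = [min(span[0], g.cds_start), max(span[1], g.cds_end)]
                fh.write(f"{g.chrom}\tapakit\tgene\t{span[0] + 1}\t{span[1]}\t.\t"
                         f"{g.strand}\t.\tID={g.gene_id}\n")
                if g.cds_start is not None:
                    fh.write(f"{g.chrom}\tapakit\tCDS\t{g.cds_start + 1}\t{g.cds_end}"
                             f"\t.\t{g.strand}\t0\tID={g.gene_id};Parent={g.gene_id}\n")
                fh.write(f"{g.chrom}\tapakit\tthree_prime_UTR\t{g.utr_start + 1}\t"
                         f"{g.utr_end}\t.\t{g.strand}\t.\t"
                         f"ID={g.gene_id};Parent={g.gene_id}\n")
        else:
            raise ValueError(f"unknown annotation dialect {dialect!r}")


# ---------------------------------------------------------------------------
# tags


def read_tags(paths: Mapping[str, str | Path] | str | Path) -> tuple[pd.DataFrame, int]:
    """Read 3'-end tags from BED6 file(s).

    ``paths`` maps sample id -> file, or is a single file (sample id = stem).
    The cleavage coordinate is the strand-resolved 3'-most base: ``end - 1``
    on the plus strand, ``start`` on the minus strand.  Duplicate-identical
    records are retained (distinct molecules).  Records with strand ``.`` are
    rejected and counted.

    Returns a tidy DataFrame with columns ``chrom, pos, strand, sample`` and
    the number of skipped strandless records.
    """
    if not isinstance(paths, Mapping):
        p = Path(paths)
        paths = {p.stem: p}
    frames = []
    skipped = 0
    for sample, path in paths.items():
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#",
                             usecols=[0, 1, 2, 5],
                             names=["chrom", "start", "end", "strand"])
        except pd.errors.EmptyDataError:
            warnings.warn(f"empty tag file for sample {sample}: {path}")
            continue
        bad = ~df["strand"].isin(["+", "-"])
        skipped += int(bad.sum())
        df = df[~bad]
        pos = df["end"].where(df["strand"] == "+", df["start"] + 1) - 1
        frames.append(pd.DataFrame({
            "chrom": df["chrom"].astype(str),
            "pos": pos.astype(int),
            "strand": df["strand"].astype(str),
            "sample": sample,
        }))
    if not frames:
        return (pd.DataFrame(columns=["chrom", "pos", "strand", "sample"]), skipped)
    return pd.concat(frames, ignore_index=True), skipped


def write_tags_bed6(tags: pd.DataFrame, path: str | Path, name: str = "tag") -> None:
    """Write a tag table (chrom, pos, strand) as single-base BED6 records."""
    out = pd.DataFrame({
        "chrom": tags["chrom"], "start": tags["pos"], "end": tags["pos"] + 1,
        "name": name, "score": 0, "strand": tags["strand"]})
    out.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# sequences


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA into a dict of uppercase sequences keyed by contig id."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(genome: Mapping[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.items()]
    SeqIO.write(records, str(path), "fasta")
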