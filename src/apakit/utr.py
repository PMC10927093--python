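"""cUTR/aUTR segmentation, miRNA seed-site discovery and the eUTR/cUTR ratio.

The segment of the 3'UTR upstream of the proximal PAS is the constitutive
UTR (cUTR); the segment between the proximal and the distal PAS, present
only in long isoforms, is the alternative/extended UTR (aUTR or eUTR).
Seed sites follow the canonical grading: 8mer > 7mer-m8 > 7mer-A1 > 6mer,
all anchored on complementarity to miRNA nucleotides 2-7/2-8.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .io import GeneModel, revcomp

__all__ = ["UtrSegmentation", "SeedSite", "segment_utr", "find_seed_sites",
           "localize_sites", "eutr_cutr_ratio", "utr_sequence"]


@dataclass(frozen=True)
class UtrSegmentation:
    """Transcript-coordinate cUTR/aUTR intervals for one gene."""

    gene_id: str
    strand: str
    #: half-open transcript interval [0, proximal cleavage + 1)
    cutr: tuple[int, int]
    #: half-open transcript interval (proximal, distal]; empty iff single PAS
    autr: tuple[int, int]

    @property
    def cutr_length(self) -> int:
        return self.cutr[1] - self.cutr[0]

    @property
    def autr_length(self) -> int:
        return self.autr[1] - self.autr[0]


@dataclass(frozen=True)
class SeedSite:
    mirna_id: str
    start: int  # 0-based on the UTR sequence
    end: int
    site_type: str  # 8mer | 7mer-m8 | 7mer-A1 | 6mer
    compartment: str = ""  # cUTR | aUTR (set by localize_sites)


def segment_utr(gene: GeneModel, proximal_pas: int, distal_pas: int,
                transcript_coords: bool = False) -> UtrSegmentation:
    """Split a gene's 3'UTR at its proximal PAS.

    ``proximal_pas``/``distal_pas`` are cleavage coordinates (genomic by
    default, transcript if ``transcript_coords``).  The cUTR runs from the
    cUTR start through the proximal cleavage base; the aUTR from there
    through the distal cleavage base.  A PAS upstream of the cUTR start is
    an annotation conflict and rejects the gene.
    """
    if transcript_coords:
        tp, td = proximal_pas, distal_pas
    else:
        tp = gene.transcript_pos(proximal_pas)
        td = gene.transcript_pos(distal_pas)
    if tp > td:
        tp, td = td, tp
    if tp < 0:
        raise ValueError(f"{gene.gene_id}: PAS upstream of the cUTR start")
    if tp == td:
        import warnings
        warnings.warn(f"{gene.gene_id}: proximal and distal PAS coincide; empty aUTR")
    return UtrSegmentation(gene.gene_id, gene.strand,
                           cutr=(0, tp + 1), autr=(tp + 1, td + 1))


def utr_sequence(gene: GeneModel, genome: dict[str, str], distal_pas: int) -> str:
    """Transcript-orientation 3'UTR sequence from the cUTR start through the
    distal cleavage base."""
    td = gene.transcript_pos(distal_pas)
    if gene.strand == "+":
        return genome[gene.chrom][gene.utr_start:gene.utr_start + td + 1].upper()
    return revcomp(genome[gene.chrom][gene.utr_end - 1 - td:gene.utr_end]).upper()


# ---------------------------------------------------------------------------
# seed matching


def _norm(seq: str) -> str:
    """Map RNA/DNA to one internal DNA alphabet, uppercase."""
    return seq.upper().replace("U", "T")


def find_seed_sites(mirna_id: str, mirna_seq: str, utr_seq: str) -> list[SeedSite]:
    """Canonical seed matches of a miRNA in a 3'UTR sequence.

    The 6mer core is the reverse complement of miRNA nucleotides 2-7; an
    additional match to nucleotide 8 at the site's 5' end upgrades to
    7mer-m8, an A across from nucleotide 1 at the 3' end upgrades to
    7mer-A1, and both together make an 8mer.  Overlapping matches are
    reported once, at the strongest type.  Ambiguous bases never match.
    """
    m = _norm(mirna_seq)
    if len(m) < 8:
        raise ValueError(f"{mirna_id}: miRNA must be >= 8 nt")
    utr = _norm(utr_seq)
    core6 = revcomp(m[1:7])      # matches miRNA nt 2-7
    m8_base = revcomp(m[7])      # base pairing miRNA nt 8
    if "N" in core6:
        return []
    sites = []
    start = utr.find(core6)
    while start != -1:
        has_m8 = start >= 1 and utr[start - 1] == m8_base
        has_a1 = start + 6 < len(utr) and utr[start + 6] == "A"
        if has_m8 and has_a1:
            sites.append(SeedSite(mirna_id, start - 1, start + 7, "8mer"))
        elif has_m8:
            sites.append(SeedSite(mirna_id, start - 1, start + 6, "7mer-m8"))
        elif has_a1:
            sites.append(SeedSite(mirna_id, start, start + 7, "7mer-A1"))
        else:
            sites.append(SeedSite(mirna_id, start, start + 6, "6mer"))
        start = utr.find(core6, start + 1)
    return sites


def localize_sites(sites: list[SeedSite], seg: UtrSegmentation) -> pd.DataFrame:
    """Assign each site to the cUTR or aUTR compartment by its start position.

    Returns one row per site with a ``spans_boundary`` flag; summarise with
    ``df.groupby(...)`` or :func:`autr_fraction`.
    """
    rows = []
    boundary = seg.cutr[1]
    for s in sites:
        comp = "cUTR" if s.start < boundary else "aUTR"
        rows.append({"mirna_id": s.mirna_id, "start": s.start, "end": s.end,
                     "site_type": s.site_type, "compartment": comp,
                     "spans_boundary": s.start < boundary <= s.end - 1})
    return pd.DataFrame(rows, columns=["mirna_id", "start", "end", "site_type",
                                       "compartment", "spans_boundary"])


def autr_fraction(localized: pd.DataFrame) -> float:
    """Fraction of seed sites falling in the aUTR."""
    if localized.empty:
        raise ValueError("no sites to summarise")
    return float((localized["compartment"] == "aUTR").mean())


# ---------------------------------------------------------------------------
# eUTR/cUTR ratio


def eutr_cutr_ratio(proximal_count: float | None = None,
                    distal_count: float | None = None,
                    ct_e_test: float | None = None, ct_c_test: float | None = None,
                    ct_e_ref: float | None = None, ct_c_ref: float | None = None,
                    ) -> float:
    """Long-isoform fraction of total transcripts.

    Count mode (``proximal_count`` + ``distal_count``): distal-inclusive
    tags over total gene tags, in [0, 1].  qPCR mode (four Ct values):
    ``2 ** -((Ct_e - Ct_c)_test - (Ct_e - Ct_c)_reference)`` — the eUTR
    amplicon signal normalized to the cUTR amplicon and to the reference
    sample.
    """
    count_mode = proximal_count is not None or distal_count is not None
    ct_vals = (ct_e_test, ct_c_test, ct_e_ref, ct_c_ref)
    if count_mode:
        if proximal_count is None or distal_count is None:
            raise ValueError("count mode needs both proximal and distal counts")
        total = proximal_count + distal_count
        if total <= 0:
            raise ValueError("no tags for this gene")
        return float(distal_count / total)
    if any(v is None for v in ct_vals):
        raise ValueError("qPCR mode needs all four Ct values")
    ddct = (ct_e_test - ct_c_test) - (ct_e_ref - ct_c_ref)
    return float(2.0 ** -ddct)
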