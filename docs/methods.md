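# Methods

## Scope and data model

`apakit` starts at aligned, uniquely mapped 3'-end tags: one BED6 record per
tag, whose strand-resolved 3'-most base (plus strand: `end − 1`; minus
strand: `start`) is the putative cleavage site.  Trimming and alignment are
upstream concerns.  Coordinates are 0-based half-open throughout; all
interval logic is strand-aware so that "proximal" always means nearer the
stop codon.  A gene is modelled as one tandem-3'UTR territory — the interval
from the base after the stop codon (the cUTR anchor) to the annotated distal
end — plus an optional CDS interval used only for location labelling.  Genes
with multiple annotated last exons are outside this model: the pipeline
restricts itself to tandem PASs within one territory, and same-strand genes
with overlapping territories are rejected (or dropped with a warning).

## Poly(A)-site calling

1. **Gene assignment.**  A tag belongs to a gene when it lies on the gene's
   strand inside the territory or at most `extension_bp` (default 4000 nt)
   downstream of the annotated end.
2. **Internal-priming filter.**  Oligo-d(T) priming on genomic A-tracts
   produces spurious 3' ends.  The 20 genomic bases 1–20 nt downstream of
   each cleavage site (reverse-complemented on the minus strand) are
   examined; the site is flagged when they contain ≥ 6 consecutive A or
   ≥ 7 A within any 10-nt sub-window.  The window length is standard in
   3'-end protocols; the two cut-offs are common 3'-end-seq practice and
   both are configurable (`ip_max_run`, `ip_max_in_10`).  A window truncated
   below 10 bases by a contig end makes the site unevaluable, which is
   treated conservatively as flagged.  Flagged tags never reach clustering.
3. **Clustering.**  Retained cleavage coordinates (pooled across samples,
   then counted per sample) are single-linkage clustered: consecutive sorted
   coordinates with gap ≤ `window` (default 24 nt) share a cluster.  The
   representative is the modal coordinate, ties broken toward the stop
   codon.  Clusters with pooled count < `min_count` (default 5) are dropped
   as singleton noise.  Per gene, input tags always reconcile exactly:
   clustered + flagged + dropped + unassigned.
4. **Annotation.**  The polyadenylation signal is scanned 10–40 nt upstream
   of the representative — a superset of the canonical 10–30 nt placement,
   widened downstream-side to tolerate representative shift under cleavage
   microheterogeneity — with priority AATAAA > ATTAAA > ten common
   single-base variants, the occurrence nearest the site breaking ties
   within a class.  Location classes follow the precedence 3'UTR >
   extended/downstream (≤ 4 kb) > intron > CDS > other; the bundled
   simulator has no introns, so the intron class never fires on synthetic
   data.
5. **Normalization.**  Per-sample CPM over retained cluster counts; a
   zero library total is a hard error naming the sample.

## Length metrics and switching test

Isoform length is the transcript distance from the cUTR anchor through the
cluster representative.  The isoform-weighted 3'UTR length is the count-
weighted mean of isoform lengths; the normalized length expresses it as a
percentage of the gene's longest isoform, with the denominator pooled
across all samples of the analysis so samples are comparable.  The
switching index is the signed change in normalized length between the last
and first design point, on a 0–1 scale:

    TSI = (norm_last − norm_first) / 100,   TSI ∈ [−1, 1],  shortening < 0.

With ≥ 3 ordered samples, p comes from the OLS slope t-test of normalized
length on the ordinal design index; with exactly two samples a two-point
regression has no residual degrees of freedom, so p comes from a two-sided
Fisher exact test of proximal-versus-(summed) distal counts between the two
samples.  BH adjustment runs across genes; `|TSI| ≥ tsi_threshold`
(default 0.1) at `q < apa_fdr` (default 0.01) calls shortened/lengthened.
Genes with one retained PAS, or unquantified in an endpoint sample, are
excluded with a reason.  Labels are symmetric: swapping the two samples
negates TSI and swaps shortened↔lengthened with p unchanged.

The Fisher p itself is computed in-package from the hypergeometric log-pmf
(`scipy.special.gammaln`), summing the probabilities of all tables with the
observed margins whose probability does not exceed the observed one, with
the standard 1e-7 relative tie tolerance.  The `gammaln` route is orders of
magnitude faster than per-table pmf calls at sequencing-scale margins and
agrees with exact integer enumeration to < 1e-13 relative error (checked
exhaustively in the tests for all tables with margins ≤ 30, and against
`scipy.stats.fisher_exact`).  BH adjustment delegates to
`statsmodels.stats.multitest.multipletests`; NaN p-values propagate without
entering the ranking.

## Differential expression and target genes

Gene expression is the summed retained 3'UTR cluster count.  Fold change is
computed on the CPM scale with a pseudocount (default 0.5 CPM) for finite
ratios; significance is the two-sided Fisher exact test of the gene's count
against the remainder of the library in each sample, BH-adjusted.  The
default call is > 3-fold at q < 0.01.  Note that per-million normalization
is compositional: when a sizeable fraction of the library genuinely moves,
CPM folds shrink toward the ratio of library totals, so hard fold cut-offs
undercount true movers (the demo analysis shows a 4-fold simulation reading
as ~2.9-fold in CPM).  Target genes are the exact intersection of the
shortened set in a loss-of-function contrast with the lengthened set in a
restoration contrast, optionally further intersected with the DE-up set.

## UTR features and assay calculators

The UTR is segmented at the proximal representative: cUTR = [anchor,
pPAS], aUTR = (pPAS, dPAS], which partition the distal isoform exactly.
Seed sites use the canonical grading — 6mer = reverse complement of miRNA
nt 2–7; 7mer-m8 adds the nt-8 match at the site's 5' end; 7mer-A1 adds an A
across from nt 1; 8mer has both — reported once per core match at the
strongest type, with U/T mapped to one alphabet and N never matching.
Sites are assigned to a compartment by their start position (boundary-
spanning sites flagged).  The eUTR/cUTR ratio estimates the long-isoform
fraction: distal-inclusive over total counts in count mode, and
`2^−[(Ct_e−Ct_c)_test − (Ct_e−Ct_c)_ref]` in qPCR mode — the standard
ΔΔCt construction, stated here explicitly because assay write-ups usually
leave it implicit.  The assay calculators assume exact doubling per cycle
(2^−ΔΔCt), fit first-order decay by OLS on the log scale after normalizing
to the first usable time point (k = −slope, half-life = ln 2 / k, R²
clipped to [0, 1]; rising series report a signed k with a warning), and the
plaque titer is count / (D × V).

## The simulator

The generator defines the study conditions the tests and the reproduction
script run under.  Per gene: 2–4 cleavage sites placed approximately evenly
along a 0.8–2.4 kb UTR (uniform jitter, minimum gap 100 nt; distal site at
the annotated end), each with a canonical hexamer written into the genome
at a uniform 10–30 nt upstream offset (80% AATAAA / 20% ATTAAA by default;
a configurable fraction of non-canonical variants is off by default so
recall is unambiguous).  Genes sit on both strands, 50 per chromosome,
6 kb apart, in otherwise uniform-random (50% GC) sequence.  Tag totals per
gene per sample are negative binomial (Gamma–Poisson; Poisson at
dispersion 0) with mean `depth_per_gene × libsize_factor × fold`,
allocated multinomially by the sample's usage vector; each tag's 3' end is
jittered by rounded Normal(0, sd 3 nt by default — small enough that the
24-nt clustering window comfortably captures one site).  Usage shifts move
`shift_delta` of probability onto (shortened) or off (lengthened) the
proximal site along a per-sample profile, rescaling the remaining sites
proportionally; with uniform baselines and even spacing this makes the
true TSI −delta/2 = −0.15 at the default delta 0.3 regardless of the
number of sites, because even spacing fixes the normalized-length
geometry.  Internal-
priming artifacts write an A-tract (≥ 15 nt) into the UTR at least 60 nt
from any true site and divert a fraction of the gene's tags to end at the
tract's 5' edge, exactly where a mispriming event would.

Two idealisations make filter guarantees exact rather than statistical:
the 20-nt window downstream of every *true* site is re-drawn until it
fails both A-richness criteria (real poly(A) sites lack such tracts — that
is the filter's premise), and chance AATAAA/ATTAAA occurrences are removed
from the upstream scan windows so the planted signal is the only one.
Consequently "0% true sites flagged" and "100% hexamer recall" are
construction-backed contracts on synthetic data.  What passing therefore
shows: the pipeline's logic is correct and calibrated under its own model.
What it does not show: performance on real libraries with non-canonical
signals, closely spaced or alternative-last-exon PASs, A-rich but genuine
3' ends, alignment artifacts, or compositional depth differences beyond
scalar library-size factors.

Depth, replicate and dispersion defaults (500 tags/gene, 2 samples,
dispersion 0.1) are stated choices of this package, typical of a
well-covered 3'-end library, not values taken from any particular dataset.
Hexamer recall is measured on jitter-0 simulations, where representatives
provably coincide with true sites; representative recovery (±2 nt) is
measured at jitter sd 3 and depth 1000.

## Determinism and numerics

One integer seed drives every random draw through
`numpy.random.default_rng`; fixed seed means byte-identical FASTA,
annotation, tag files and result tables.  Benchmark problem sizes (150–500
genes, depth 500–1000, 20 all-null replicates) are chosen so the whole
validation suite completes in about a minute on one core while keeping
binomial standard errors well inside the tolerances they are compared to.
Degenerate inputs are handled explicitly: empty annotation and zero library
totals are hard errors; zero-tag genes are reported unquantified;
single-PAS genes are excluded from switching with a reason; constant
normalized lengths give p = 1; equal proximal and distal PASs give an empty
aUTR with a warning.

## Known limitations

- One territory per gene: no alternative last exons, no intronic-PAS
  truncation analysis (intronic sites are only location-labelled).
- The two-sample switching test collapses > 2 PASs to proximal vs rest; a
  multinomial trend test would use more information.
- CPM is the only normalization; no TMM-style compositional correction.
- Seed matching is positional only — no conservation weighting, pairing
  thermodynamics or context scoring.
- The simulator does not model sequencing error, strand-switching
  artifacts, or non-uniform background tags.
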