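#!/usr/bin/env python
"""Call poly(A)-site clusters from the demo tags.

Reads the simulated genome, annotation and per-sample BED6 tags back
through the package's format readers, runs the internal-priming filter and
single-linkage clustering, and writes the annotated cluster table.  Prints
the tag accounting and the hexamer/location composition — on clean 3'-end
data nearly all retained clusters sit in annotated 3'UTRs with a canonical
signal 10-30 nt upstream.
"""

from pathlib import Path

from apakit.io import read_annotation, read_fasta, read_tags
from apakit.pas import call_pas, write_clusters

BASE = Path(__file__).resolve().parent.parent / "results" / "demo"
SAMPLES = ["s1", "s2", "s3"]


def main():
    sim = BASE / "sim"
    genome = read_fasta(sim / "genome.fa")
    genes = read_annotation(sim / "annotation.bed12", "bed12")
    tags, skipped = read_tags({s: sim / "tags" / f"{s}.bed" for s in SAMPLES})
    clusters, audit = call_pas(tags, genes, genome, SAMPLES)
    write_clusters(clusters, BASE / "pas_clusters.tsv", BASE / "pas_clusters.bed",
                   SAMPLES)
    print(f"tags in: {audit.tags_in} (skipped strandless: {skipped})")
    print(f"  flagged internal priming: {audit.flagged} "
          f"({100 * audit.flagged / audit.tags_in:.1f}%)")
    print(f"  dropped below min count:  {audit.dropped_min_count}")
    print(f"  retained in clusters:     {audit.retained}")
    print(f"accounting reconciles: {audit.reconciles()}")
    print(f"clusters called: {len(clusters)}")
    print("hexamer classes:", clusters["hexamer_class"].value_counts().to_dict())
    print("locations:      ", clusters["location"].value_counts().to_dict())


if __name__ == "__main__":
    main()
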