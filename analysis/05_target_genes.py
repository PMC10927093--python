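#!/usr/bin/env python
"""Define the factor's target-gene set from the knockout/rescue design.

Targets = genes shortened upon knockout (s1 -> s2) AND lengthened upon
rescue (s2 -> s3); the intersection with the DE-up set mirrors the "target
genes among upregulated genes" analysis.  Both sets are scored against the
simulation truth.
"""

from pathlib import Path

import pandas as pd

from apakit.io import read_annotation
from apakit.stats import call_apa_switching, define_target_genes, fisher_de

BASE = Path(__file__).resolve().parent.parent / "results" / "demo"


def main():
    clusters = pd.read_csv(BASE / "pas_clusters.tsv", sep="\t")
    genes = read_annotation(BASE / "sim" / "annotation.bed12", "bed12")
    apa_ko = call_apa_switching(clusters, genes, ["s1", "s2"])
    apa_rescue = call_apa_switching(clusters, genes, ["s2", "s3"])
    shortened = set(apa_ko.loc[apa_ko["switch_class"] == "shortened", "gene_id"])
    lengthened = set(apa_rescue.loc[apa_rescue["switch_class"] == "lengthened",
                                    "gene_id"])
    targets = define_target_genes(shortened, lengthened)
    (BASE / "target_genes.txt").write_text("".join(f"{g}\n" for g in sorted(targets)))

    de = fisher_de(clusters, control="s1", treatment="s2")
    de_up = set(de.loc[de["direction"] == "up", "gene_id"])
    up_targets = define_target_genes(shortened, lengthened, de_up=de_up)

    truth = pd.read_csv(BASE / "sim" / "truth.tsv", sep="\t")
    true_set = set(truth.loc[truth["switch_class"] == "shortened", "gene_id"])
    print(f"shortened on knockout: {len(shortened)}  "
          f"lengthened on rescue: {len(lengthened)}")
    print(f"target genes: {len(targets)} (truth: {len(true_set)}; "
          f"exact match: {targets == true_set})")
    print(f"targets among upregulated genes: {len(up_targets)}")


if __name__ == "__main__":
    main()
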