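#!/usr/bin/env python
"""3'-end differential expression, knockout vs wild type (s2 vs s1).

Gene expression is the summed retained 3'UTR cluster count; the call is
"up" above 3-fold (CPM scale, 0.5-CPM pseudocount) at BH q < 0.01 by a
two-sided Fisher exact test.  Scored against the simulated 4-fold set.
"""

from pathlib import Path

import pandas as pd

from apakit.stats import fisher_de

BASE = Path(__file__).resolve().parent.parent / "results" / "demo"


def main():
    clusters = pd.read_csv(BASE / "pas_clusters.tsv", sep="\t")
    de = fisher_de(clusters, control="s1", treatment="s2")
    de.to_csv(BASE / "de_results.tsv", sep="\t", index=False)
    truth = pd.read_csv(BASE / "sim" / "truth.tsv", sep="\t")
    true_up = set(truth.loc[truth["fold"] > 1, "gene_id"])
    called_up = set(de.loc[de["direction"] == "up", "gene_id"])
    print(f"genes tested: {len(de)}")
    print(f"called up: {len(called_up)}  truly 4-fold: {len(true_up)}")
    print(f"  sensitivity: {len(called_up & true_up) / len(true_up):.2%}")
    print(f"  false calls: {len(called_up - true_up)}")
    med = de.loc[de["gene_id"].isin(true_up), "fold"].median()
    print(f"median observed fold among true 4-fold genes: {med:.2f}")
    print("note: per-million normalization is compositional — with 13% of "
          "genes truly 4-fold up,\nCPM folds shrink toward ~4/1.4 = 2.9, so "
          "a hard 3-fold cut misses genuine movers.")


if __name__ == "__main__":
    main()
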