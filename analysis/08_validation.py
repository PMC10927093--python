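#!/usr/bin/env python
"""Parameter-recovery and error-control experiments.

Runs the package's benchmark suite (internal-priming separation, cluster
representative recovery, hexamer recall, switching sensitivity/FDR,
all-null call rate, target-set recovery) and writes one summary table.
These are the same experiments scripts/acceptance.py reports.
"""

import json
from pathlib import Path

import pandas as pd

from apakit import benchmarks

OUT = Path(__file__).resolve().parent.parent / "results" / "demo"
SEED = 20240923


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    results = {
        "internal_priming": benchmarks.ip_filter_benchmark(SEED),
        "pas_recovery": benchmarks.pas_recovery_benchmark(SEED + 1),
        "hexamer_recall": benchmarks.hexamer_recall_benchmark(SEED + 2),
        "switching_recovery": benchmarks.switching_recovery_benchmark(SEED + 3),
        "null_call_rate": benchmarks.null_call_rate_benchmark(SEED + 4, n_seeds=5),
        "target_recovery": benchmarks.target_recovery_benchmark(SEED + 5),
    }
    rows = [{"experiment": name, **vals} for name, vals in results.items()]
    df = pd.DataFrame([{k: (v if not isinstance(v, dict) else json.dumps(v))
                        for k, v in r.items()} for r in rows])
    df.to_csv(OUT / "validation.tsv", sep="\t", index=False)
    for name, vals in results.items():
        print(f"{name}: {vals}")


if __name__ == "__main__":
    main()
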