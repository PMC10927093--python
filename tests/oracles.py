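"""Independent brute-force oracles used only by the test suite.

Each oracle recomputes a quantity by direct enumeration, staying clear of
the implementation path it checks.
"""

from __future__ import annotations

from math import comb

import numpy as np

#: same relative tie tolerance the implementation documents, applied here in
#: exact integer arithmetic: include a table iff
#: weight * 10^7 <= observed_weight * (10^7 + 1)
_EPS_NUM = 10**7
_EPS_DEN = 10**7 + 1


def fisher_two_sided_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration with
    exact integer weights."""
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    weights = [comb(r1, k) * comb(n - r1, c1 - k) for k in range(lo, hi + 1)]
    w_obs = weights[a - lo]
    total = comb(n, c1)
    acc = sum(w for w in weights if w * _EPS_NUM <= w_obs * _EPS_DEN)
    return acc / total


def bh_stepup_naive(p: np.ndarray) -> np.ndarray:
    """O(m^2) Benjamini-Hochberg step-up: q_(i) = min_{j >= i} m p_(j) / j."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    stepped = m * p[order] / ranks
    q_sorted = np.empty(m)
    for i in range(m):  # suffix minimum taken afresh for every rank
        q_sorted[i] = min(stepped[i:].min(), 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def connected_components_clusters(positions: np.ndarray, window: int) -> list[set]:
    """All-pairs single-linkage clustering: positions are linked when within
    `window` of each other; clusters are connected components."""
    n = len(positions)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if abs(int(positions[i]) - int(positions[j])) <= window:
                parent[find(i)] = find(j)
    comps: dict[int, set] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(i)
    return list(comps.values())


def a_rich_window_oracle(seq: str, max_run: int = 6, max_in_10: int = 7) -> bool:
    """Direct window scan for the internal-priming criteria."""
    seq = seq.upper()
    if any(seq[i:i + max_run] == "A" * max_run for i in range(len(seq) - max_run + 1)):
        return True
    return any(seq[i:i + 10].count("A") >= max_in_10
               for i in range(max(1, len(seq) - 9)))


_RC = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _rc(s: str) -> str:
    return "".join(_RC[b] for b in reversed(s))


def seed_sites_oracle(mirna: str, utr: str) -> list[tuple[int, int, str]]:
    """Sliding-window seed matching: compare every UTR window against the
    explicit site sequences for each type, strongest type per core match."""
    m = mirna.upper().replace("U", "T")
    utr = utr.upper()
    core6 = _rc(m[1:7])
    site_8mer = _rc(m[1:8]) + "A"
    site_7m8 = _rc(m[1:8])
    site_7a1 = core6 + "A"
    out = []
    for i in range(len(utr) - 5):
        if utr[i:i + 6] != core6:
            continue
        if i >= 1 and utr[i - 1:i + 7] == site_8mer:
            out.append((i - 1, i + 7, "8mer"))
        elif i >= 1 and utr[i - 1:i + 6] == site_7m8:
            out.append((i - 1, i + 6, "7mer-m8"))
        elif utr[i:i + 7] == site_7a1:
            out.append((i, i + 7, "7mer-A1"))
        else:
            out.append((i, i + 6, "6mer"))
    return out
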