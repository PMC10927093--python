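"""Tandem-3'UTR length metrics, APA-switching calls and 3'-end differential
expression.

Per gene and sample the pipeline computes the isoform-weighted 3'UTR length
(mean isoform length weighted by isoform tag counts) and the normalized
length (percentage of the longest isoform, the denominator pooled over all
samples of the gene).  The tandem 3'UTR switching index

    TSI = (normalized length at the last design point
           - normalized length at the first) / 100

is signed so that shortening is negative.  Significance comes from an OLS
slope t-test of normalized length on the ordinal design index when >= 3
samples are available, and from a two-sided Fisher exact test on proximal
vs distal-sum counts for exactly two samples (a two-point regression has no
residual degrees of freedom).  Benjamini-Hochberg adjustment is applied
across genes, separately for the APA and the DE test families.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import ApaConfig, DeConfig
from .io import GeneModel

__all__ = ["weighted_utr_length", "normalized_utr_length", "fisher_exact_two_sided",
           "bh_adjust", "call_apa_switching", "fisher_de", "define_target_genes"]

#: relative tie tolerance for two-sided Fisher (the convention R and scipy use)
_FISHER_EPS = 1e-7


def _log_comb(n, k):
    from scipy.special import gammaln
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


# ---------------------------------------------------------------------------
# closed-form length metrics


def weighted_utr_length(lengths, counts) -> float:
    """Isoform-weighted 3'UTR length: sum(l_i c_i) / sum(c_i)."""
    lengths = np.asarray(lengths, dtype=float)
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("all-zero isoform counts: gene unquantified in this sample")
    return float((lengths * counts).sum() / total)


def normalized_utr_length(weighted: float, longest: float) -> float:
    """Weighted length as a percentage of the longest isoform (pooled)."""
    if longest <= 0:
        raise ValueError("longest isoform length must be positive")
    return 100.0 * weighted / longest


# ---------------------------------------------------------------------------
# primitive tests


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric probabilities of all tables (same margins) whose
    probability does not exceed the observed table's, with the standard
    1e-7 relative tie tolerance.
    """
    (a, b), (c, d) = np.asarray(table, dtype=int)
    if min(a, b, c, d) < 0:
        raise ValueError("negative cell in 2x2 table")
    n = a + b + c + d
    r1, c1 = a + b, a + c
    if n == 0:
        return 1.0
    k = np.arange(max(0, c1 - (n - r1)), min(r1, c1) + 1)
    # log-pmf via gammaln: orders of magnitude faster than scipy's pmf for
    # large margins, accurate to ~1e-14 relative
    logpmf = (_log_comb(r1, k) + _log_comb(n - r1, c1 - k) - _log_comb(n, c1))
    pmf = np.exp(logpmf)
    p_obs = float(pmf[k == a][0])
    p = float(pmf[pmf <= p_obs * (1 + _FISHER_EPS)].sum())
    return min(p, 1.0)


def bh_adjust(p: np.ndarray | list) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values (NaNs propagate)."""
    p = np.asarray(p, dtype=float)
    q = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.sum():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# APA switching


def _gene_blocks(clusters: pd.DataFrame, samples: list[str]):
    """Retained, territory-ordered cluster blocks per gene."""
    usable = clusters[clusters["location"].isin(["3UTR", "extended"])]
    for gene_id, block in usable.groupby("gene_id", sort=True):
        yield gene_id, block.sort_values("tpos")


def call_apa_switching(clusters: pd.DataFrame, genes: list[GeneModel],
                       samples: list[str],
                       config: ApaConfig | None = None) -> pd.DataFrame:
    """Per-gene TSI, p, BH q and switching class over an ordered design.

    ``samples`` is the ordered design (first = reference condition, last =
    treatment); TSI < 0 means shortening toward the last sample.  Genes with
    a single retained PAS are excluded with a reason; genes unquantified in
    the first or last sample likewise.
    """
    cfg = config or ApaConfig()
    if len(samples) < 2:
        raise ValueError("need >= 2 samples for a switching test")
    gene_map = {g.gene_id: g for g in genes}
    rows = []
    for gene_id, block in _gene_blocks(clusters, samples):
        g = gene_map[gene_id]
        if len(block) < 2:
            rows.append({"gene_id": gene_id, "n_pas": len(block),
                         "excluded": "single_pas"})
            continue
        lengths = np.array([g.isoform_length(int(p)) for p in block["rep_pos"]],
                           dtype=float)
        counts = block[[f"count_{s}" for s in samples]].to_numpy(dtype=float)
        totals = counts.sum(axis=0)
        if totals[0] <= 0 or totals[-1] <= 0:
            rows.append({"gene_id": gene_id, "n_pas": len(block),
                         "excluded": "unquantified_endpoint"})
            continue
        longest = lengths.max()
        norm = np.full(len(samples), np.nan)
        for j in range(len(samples)):
            if totals[j] > 0:
                norm[j] = normalized_utr_length(
                    weighted_utr_length(lengths, counts[:, j]), longest)
        tsi = (norm[-1] - norm[0]) / 100.0
        if len(samples) == 2:
            table = [[counts[0, 0], counts[1:, 0].sum()],
                     [counts[0, 1], counts[1:, 1].sum()]]
            p = fisher_exact_two_sided(np.asarray(table, dtype=int))
        else:
            ok = ~np.isnan(norm)
            if np.nanstd(norm[ok]) == 0:
                p = 1.0
            else:
                p = float(sps.linregress(np.nonzero(ok)[0], norm[ok]).pvalue)
        row = {"gene_id": gene_id, "n_pas": len(block), "excluded": "",
               "isoform_lengths": ",".join(str(int(l)) for l in lengths),
               "tsi": tsi, "p": p}
        for j, s in enumerate(samples):
            row[f"weighted_len_{s}"] = (weighted_utr_length(lengths, counts[:, j])
                                        if totals[j] > 0 else np.nan)
            row[f"norm_len_{s}"] = norm[j]
        rows.append(row)
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    if "p" not in res.columns:
        res["p"] = np.nan
        res["tsi"] = np.nan
    res["q"] = bh_adjust(res["p"].to_numpy())
    cls = np.full(len(res), "none", dtype=object)
    called = (res["q"].to_numpy() < cfg.fdr) & ~res["q"].isna().to_numpy()
    tsi = res["tsi"].to_numpy(dtype=float)
    cls[called & (tsi <= -cfg.tsi_threshold)] = "shortened"
    cls[called & (tsi >= cfg.tsi_threshold)] = "lengthened"
    res["switch_class"] = cls
    return res


# ---------------------------------------------------------------------------
# differential expression


def fisher_de(clusters: pd.DataFrame, control: str, treatment: str,
              config: DeConfig | None = None) -> pd.DataFrame:
    """Per-gene 3'-end differential expression between two samples.

    Gene counts are the summed retained 3'UTR cluster counts; fold change is
    on the CPM scale with a pseudocount for finite ratios; p is a two-sided
    Fisher exact test of the gene's count against the rest of the library in
    each sample; q is BH across genes.
    """
    cfg = config or DeConfig()
    for s in (control, treatment):
        if f"count_{s}" not in clusters.columns:
            raise ValueError(f"no counts for sample {s!r} in the cluster table")
    usable = clusters[clusters["location"].isin(["3UTR", "extended"])]
    gc = usable.groupby("gene_id")[[f"count_{control}", f"count_{treatment}"]].sum()
    tot_c = int(gc[f"count_{control}"].sum())
    tot_t = int(gc[f"count_{treatment}"].sum())
    if tot_c <= 0 or tot_t <= 0:
        raise ValueError("zero library total in a DE sample")
    rows = []
    for gene_id, (n_c, n_t) in gc.iterrows():
        n_c, n_t = int(n_c), int(n_t)
        if n_c > tot_c or n_t > tot_t:
            raise ValueError(f"{gene_id}: gene count exceeds library total")
        cpm_c = n_c * 1e6 / tot_c
        cpm_t = n_t * 1e6 / tot_t
        fold = (cpm_t + cfg.pseudocount_cpm) / (cpm_c + cfg.pseudocount_cpm)
        p = fisher_exact_two_sided([[n_t, tot_t - n_t], [n_c, tot_c - n_c]])
        rows.append({"gene_id": gene_id, f"count_{control}": n_c,
                     f"count_{treatment}": n_t, f"cpm_{control}": cpm_c,
                     f"cpm_{treatment}": cpm_t, "fold": fold, "p": p})
    res = pd.DataFrame(rows)
    res["q"] = bh_adjust(res["p"].to_numpy())
    direction = np.full(len(res), "none", dtype=object)
    sig = res["q"].to_numpy() < cfg.fdr
    direction[sig & (res["fold"].to_numpy() > cfg.fold)] = "up"
    direction[sig & (res["fold"].to_numpy() < 1.0 / cfg.fold)] = "down"
    res["direction"] = direction
    return res


# ---------------------------------------------------------------------------
# target-gene logic


def define_target_genes(shortened: set[str], lengthened: set[str],
                        de_up: set[str] | None = None) -> set[str]:
    """Genes shortened in one contrast and lengthened (rescued) in the other,
    optionally intersected with a DE-up set."""
    targets = set(shortened) & set(lengthened)
    if de_up is not None:
        targets &= set(de_up)
    return targets
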