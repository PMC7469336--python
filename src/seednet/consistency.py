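"""Concordance of seeded rankings across networks.

With few donors, the stability of the guilt-by-association ranking is
checked by building one network per brain and correlating the per-brain
rankings of all non-seed genes (Kendall tau-b over every pair of brains).
Seed-set clustering in two region subsets is compared through the seeds'
CR distributions.
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import kendalltau, mannwhitneyu, wilcoxon

from .network import build_network, nonseed_scores
from .prep import per_brain_region_means


def per_brain_rankings(matrix: pd.DataFrame,
                       ann: pd.DataFrame,
                       seeds: Sequence[str],
                       granularity: str = "low",
                       structure_high: str | None = "cerebrum") -> pd.DataFrame:
    """Non-seed CRs from one network per donor (genes x donors).

    Each donor's samples are averaged into region-level expression, a
    network is built over that donor's regions (optionally restricted to one
    high-level structure), and every non-seed gene receives a CR. Only genes
    scored in every donor's network are returned.
    """
    cols = {}
    for brain in sorted(ann["brain_id"].unique()):
        re = per_brain_region_means(matrix, ann, brain, granularity)
        subset = (re.subset_regions(structure_high) if structure_high
                  else list(re.values.columns))
        net = build_network(re, subset)
        cols[brain] = nonseed_scores(net, seeds)["cr"]
    out = pd.DataFrame(cols).dropna()
    if out.shape[1] < 2:
        raise ValueError("need at least 2 donors for a concordance matrix")
    return out


def kendall_matrix(rankings: pd.DataFrame) -> pd.DataFrame:
    """Kendall tau-b between every pair of ranking columns (unit diagonal)."""
    if rankings.shape[1] < 2:
        raise ValueError("need at least 2 rankings")
    if rankings.isna().any().any():
        raise ValueError("rankings must cover the same gene universe (no NaN)")
    labels = list(rankings.columns)
    k = len(labels)
    tau = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            t = kendalltau(rankings.iloc[:, i], rankings.iloc[:, j]).statistic
            tau[i, j] = tau[j, i] = t
    return pd.DataFrame(tau, index=labels, columns=labels)


class CRComparison(NamedTuple):
    median_a: float
    median_b: float
    pvalue: float
    method: str


def compare_cr(cr_a: Sequence[float], cr_b: Sequence[float],
               method: str = "signed_rank",
               alternative: str = "two-sided") -> CRComparison:
    """Compare two CR distributions for the same seed genes.

    ``method="signed_rank"`` runs the paired Wilcoxon signed-rank test
    (exact distribution for n <= 25 without ties, normal approximation with
    continuity correction above); it requires equal-length paired vectors.
    ``method="rank_sum"`` runs the two-sample Wilcoxon rank-sum
    (Mann-Whitney) test, the convention that reproduces the published
    early-vs-late comparison.
    """
    a = np.asarray(cr_a, dtype=float)
    b = np.asarray(cr_b, dtype=float)
    if method == "signed_rank":
        if a.shape != b.shape:
            raise ValueError("signed-rank test needs equal-length paired vectors")
        d = a - b
        if np.all(d == 0):
            raise ValueError("all paired differences are zero")
        mode = "exact" if (a.size <= 25 and not _has_rank_ties(d)) else "approx"
        res = wilcoxon(a, b, alternative=alternative, method=mode,
                       correction=(mode == "approx"))
    elif method == "rank_sum":
        res = mannwhitneyu(a, b, alternative=alternative)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CRComparison(median_a=float(np.median(a)), median_b=float(np.median(b)),
                        pvalue=float(res.pvalue), method=method)


def _has_rank_ties(d: np.ndarray) -> bool:
    nz = np.abs(d[d != 0])
    return (d == 0).any() or nz.size != np.unique(nz).size
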