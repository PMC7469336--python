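"""Seeded co-expression networks and rank-based clustering scores.

A network is the complete graph over genes whose edge weights are absolute
Pearson correlations of region-level expression across a stated region
subset. Given a seed set of established disease genes, every other gene is
scored by its summed edge weight to the seeds (guilt by association) and the
sums are normalized to percentile ranks, rank/(N+1), which are uniform on
(0, 1) and hence comparable across networks built on different region
subsets.

Two orientations of the percentile are kept explicitly:

* ``percentile_top`` — rank 1 is the *largest* sum, so strongly
  seed-correlated genes get small values; this is the orientation fed to the
  upper-tail normal quantile when converting to network Z-scores.
* ``cr`` ("correlation ranking") = 1 - percentile_top — large for strongly
  seed-correlated genes; the orientation reported in result tables.

Seed genes themselves are scored leave-one-out: each seed is removed from
the seed set, summed correlations to the reduced set are recomputed for it
and for every non-seed gene, and the held-out seed is ranked within that
pool. The median of the seeds' leave-one-out CRs is the MRC
(median ranking by correlation), the per-network summary of how tightly the
seed set clusters.
"""

from __future__ import annotations

import logging
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .types import CorrelationNetwork, RegionExpression

log = logging.getLogger(__name__)


def build_network(region_expr: RegionExpression,
                  subset: Sequence[str] | None = None) -> CorrelationNetwork:
    """Absolute-Pearson network over the given region subset.

    ``subset`` defaults to every region in ``region_expr``. Genes with zero
    variance across the subset get all their edge weights set to 0 (logged)
    so that downstream rankings stay total.
    """
    if subset is None:
        subset = list(region_expr.values.columns)
    subset = list(subset)
    missing = [r for r in subset if r not in region_expr.values.columns]
    if missing:
        raise ValueError(f"regions not in region expression: {missing[:5]}")
    if len(subset) < 3:
        raise ValueError("need at least 3 regions to build a network")
    x = region_expr.values[subset].to_numpy()
    sd = x.std(axis=1)
    flat = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.abs(np.corrcoef(x))
    if flat.any():
        log.warning("build_network: %d zero-variance genes; their edges set to 0",
                    int(flat.sum()))
        w[flat, :] = 0.0
        w[:, flat] = 0.0
    np.fill_diagonal(w, 1.0)
    w = np.clip(w, 0.0, 1.0)
    return CorrelationNetwork(genes=list(region_expr.values.index), weights=w,
                              region_subset=subset, n_obs=len(subset))


def _seed_indices(network: CorrelationNetwork, seeds: Iterable[str]) -> np.ndarray:
    present, absent = [], []
    for s in seeds:
        (present if s in network._index else absent).append(s)
    if absent:
        log.warning("seeds absent from network (dropped): %s", absent[:5])
    if not present:
        raise ValueError("no seed gene present in the network")
    return np.array([network.index_of(s) for s in present], dtype=int)


def seed_sum(network: CorrelationNetwork, seeds: Sequence[str], gene: str) -> float:
    """Summed absolute correlation of one non-seed gene to all seeds."""
    if gene in set(seeds):
        raise ValueError(f"{gene!r} is a seed; use seed_cr_loo for seeds")
    idx = _seed_indices(network, seeds)
    return float(network.weights[network.index_of(gene), idx].sum())


def seed_sums(network: CorrelationNetwork,
              seeds: Sequence[str]) -> pd.Series:
    """Summed absolute correlation to the full seed set for every non-seed gene."""
    idx = _seed_indices(network, seeds)
    seed_set = set(seeds)
    nonseed = np.array([i for i, g in enumerate(network.genes)
                        if g not in seed_set], dtype=int)
    sums = network.weights[np.ix_(nonseed, idx)].sum(axis=1)
    return pd.Series(sums, index=[network.genes[i] for i in nonseed],
                     name="sum_abs_corr")


class PercentileRanks(NamedTuple):
    percentile_top: np.ndarray  # rank/(N+1) with rank 1 = largest score
    cr: np.ndarray              # 1 - percentile_top


def percentile_ranks(scores: Sequence[float]) -> PercentileRanks:
    """Normalize scores to rank/(N+1) percentiles; ties get average rank."""
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size == 0:
        raise ValueError("scores must be a non-empty 1-D sequence")
    rank_desc = rankdata(-scores, method="average")
    p_top = rank_desc / (scores.size + 1)
    return PercentileRanks(percentile_top=p_top, cr=1.0 - p_top)


def nonseed_scores(network: CorrelationNetwork,
                   seeds: Sequence[str]) -> pd.DataFrame:
    """Score every non-seed gene: summed seed correlation and both percentiles."""
    sums = seed_sums(network, seeds)
    pr = percentile_ranks(sums.to_numpy())
    return pd.DataFrame({"sum_abs_corr": sums,
                         "percentile_top": pr.percentile_top,
                         "cr": pr.cr})


def seed_cr_loo(network: CorrelationNetwork,
                seeds: Sequence[str]) -> pd.DataFrame:
    """Leave-one-out correlation ranking for each seed gene.

    For seed g: sums to the reduced seed set S\\{g} are recomputed for g and
    for every non-seed gene; g is ranked (average ranks on ties) within the
    pool {non-seeds} + {g}, and cr(g) = 1 - rank/(N+1) with N the pool size.
    """
    idx = _seed_indices(network, seeds)
    if idx.size < 3:
        raise ValueError("leave-one-out CR needs at least 3 seeds in the network")
    seed_set = {network.genes[i] for i in idx}
    nonseed = np.array([i for i, g in enumerate(network.genes)
                        if g not in seed_set], dtype=int)
    if nonseed.size == 0:
        raise ValueError("network has no non-seed genes to rank against")
    w_ns = network.weights[np.ix_(nonseed, idx)]       # non-seed x seed
    ns_full = w_ns.sum(axis=1)
    w_ss = network.weights[np.ix_(idx, idx)]           # seed x seed, diag 1
    seed_full = w_ss.sum(axis=1) - 1.0                 # exclude self edge

    rows = []
    n_pool = nonseed.size + 1
    for k, gi in enumerate(idx):
        s_g = seed_full[k]
        pool_ns = ns_full - w_ns[:, k]                 # sums to S \ {g}
        greater = int(np.sum(pool_ns > s_g))
        equal = int(np.sum(pool_ns == s_g))
        rank = greater + (equal + 2) / 2.0             # average rank incl. self
        cr = 1.0 - rank / (n_pool + 1)
        rows.append((network.genes[gi], s_g, cr))
    out = pd.DataFrame(rows, columns=["gene", "sum_abs_corr", "cr"])
    return out.set_index("gene")


def mrc(seed_crs: Sequence[float] | pd.Series) -> float:
    """Median ranking by correlation: the median of the seeds' CRs."""
    crs = np.asarray(seed_crs, dtype=float)
    if crs.size == 0:
        raise ValueError("mrc needs at least one seed CR")
    return float(np.median(crs))
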