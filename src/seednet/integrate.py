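"""Combine network and GWAS evidence; filter, test and FDR-rank candidates.

Network percentiles become Z-scores through the upper-tail normal quantile,
then each gene's network and GWAS Z are combined with an equal-weight
Stouffer sum, z = (z_gwas + z_network) / sqrt(2). Candidates are restricted
to genes whose model-organism knockout produces an AD-related phenotype,
one-tailed normal p-values are attached, and Benjamini-Hochberg adjustment
is applied *within the phenotype-filtered set* (the FDR universe m is the
number of genes surviving the filter).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .gwas import p_to_z
from .types import AD_PHENOTYPES

log = logging.getLogger(__name__)

_STOUFFER_WEIGHTS = (0.5, 0.5)


def network_z(percentile_top):
    """Convert top-oriented percentiles (small = strongly seed-correlated)
    to Z-scores; the top-ranked gene gets the largest positive Z."""
    p = np.asarray(percentile_top, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("percentile_top must lie strictly in (0, 1)")
    return p_to_z(p)


def stouffer_combine(z_gwas, z_network):
    """Equal-weight Stouffer combination of two Z-scores (vectorized)."""
    w1, w2 = _STOUFFER_WEIGHTS
    z1 = np.asarray(z_gwas, dtype=float)
    z2 = np.asarray(z_network, dtype=float)
    if not (np.isfinite(z1).all() and np.isfinite(z2).all()):
        raise ValueError("Z-scores must be finite")
    out = (w1 * z1 + w2 * z2) / np.sqrt(w1 ** 2 + w2 ** 2)
    return out if out.ndim else float(out)


def one_tailed_p(z):
    """Upper-tail standard-normal probability of a Z-score (vectorized)."""
    z = np.asarray(z, dtype=float)
    out = norm.sf(z)
    return out if out.ndim else float(out)


def bh_fdr(p_values: Sequence[float], m: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values.

    ``m`` is the size of the testing universe; it defaults to ``len(p)`` but
    may be larger when only the smallest ``len(p)`` p-values of a bigger
    family are supplied (the supplied values are then assumed to occupy
    ranks 1..len(p), which holds for the top of a ranked table).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr needs at least one p-value")
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in (0, 1]")
    if m is None:
        m = p.size
    elif m < p.size:
        raise ValueError("universe size m cannot be smaller than len(p)")
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, p.size + 1)
    q_sorted = p[order] * m / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty_like(q_sorted)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def phenotype_filter(genes: Sequence[str],
                     phenotype_table: pd.DataFrame) -> pd.DataFrame:
    """Keep genes whose knockout phenotypes intersect the AD-related codes.

    Returns a frame (gene, phenotypes) with the matching codes attached;
    genes absent from the table or with no AD-related code are dropped
    (counts logged).
    """
    pheno = phenotype_table.set_index("gene")["phenotypes"]
    ad = set(AD_PHENOTYPES)
    kept, n_absent, n_no_pheno = [], 0, 0
    for g in genes:
        if g not in pheno.index:
            n_absent += 1
            continue
        codes = tuple(sorted(set(pheno[g]) & ad))
        if codes:
            kept.append((g, codes))
        else:
            n_no_pheno += 1
    log.info("phenotype_filter: kept %d / %d genes (%d unannotated, %d without "
             "AD-related phenotype)", len(kept), len(list(genes)), n_absent,
             n_no_pheno)
    return pd.DataFrame(kept, columns=["gene", "phenotypes"])


def rank_candidates(network_scores: pd.DataFrame,
                    gene_association: pd.DataFrame,
                    phenotype_table: pd.DataFrame) -> pd.DataFrame:
    """Full candidate ranking for non-seed genes.

    Parameters
    ----------
    network_scores:
        indexed by gene, with a ``percentile_top`` column (from
        :func:`seednet.network.nonseed_scores`).
    gene_association:
        columns gene, z_gwas (and optionally p_gene), one row per gene.
    phenotype_table:
        columns gene, phenotypes.

    Returns the ranked table (z_combined descending, ties alphabetical) with
    one-tailed p and BH-FDR q computed within the phenotype-filtered set.
    Only genes present in all three inputs are ranked.
    """
    zn = pd.Series(network_z(network_scores["percentile_top"].to_numpy()),
                   index=network_scores.index, name="z_network")
    zg = gene_association.set_index("gene")["z_gwas"]
    filt = phenotype_filter(
        [g for g in network_scores.index if g in zg.index], phenotype_table)
    if filt.empty:
        raise ValueError("no gene survives the phenotype filter")
    df = filt.set_index("gene")
    df["z_gwas"] = zg.reindex(df.index)
    df["z_network"] = zn.reindex(df.index)
    df["z_combined"] = stouffer_combine(df["z_gwas"].to_numpy(),
                                        df["z_network"].to_numpy())
    df["p_unadjusted"] = one_tailed_p(df["z_combined"].to_numpy())
    df["q_fdr"] = bh_fdr(df["p_unadjusted"].to_numpy())
    df = df.reset_index().sort_values(["z_combined", "gene"],
                                      ascending=[False, True],
                                      kind="stable").reset_index(drop=True)
    return df[["gene", "phenotypes", "z_gwas", "z_network", "z_combined",
               "p_unadjusted", "q_fdr"]]
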