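"""Gene-level GWAS scoring from SNP-level association p-values.

A gene's evidence is its best (smallest) SNP p-value, corrected for the
number of SNPs it contains with the closed-form adjustment

    p_gene = 1 - (1 - p_best) ** ((N + 1) / 2)

which treats (N + 1)/2 as the effective number of independent tests — a
conservative count under the linkage disequilibrium typical within a gene
(it is *not* conservative for fully independent SNPs). Corrected p-values
are converted to one-tailed Z-scores; association direction is not tracked.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import norm

log = logging.getLogger(__name__)

# smallest/largest p accepted by the quantile conversion before clamping
_P_FLOOR = 1e-300
_P_CEIL = 1.0 - 1e-16


def best_snp_reduce(snp_rows: pd.DataFrame) -> pd.DataFrame:
    """Reduce SNP-level rows (columns gene, p) to per-gene best-SNP records."""
    if "gene" not in snp_rows.columns or "p" not in snp_rows.columns:
        raise ValueError("SNP table needs 'gene' and 'p' columns")
    if snp_rows.empty:
        raise ValueError("no SNP rows to reduce")
    p = snp_rows["p"].to_numpy(dtype=float)
    if np.any((p <= 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("SNP p-values must lie in (0, 1]")
    grouped = snp_rows.groupby("gene", sort=True)["p"]
    out = pd.DataFrame({"gene": grouped.min().index,
                        "p_best": grouped.min().to_numpy(),
                        "n_snps": grouped.size().to_numpy()})
    return out.reset_index(drop=True)


def hotspot_correct(p_best, n_snps):
    """SNP-count correction of a best-SNP p-value (vectorized).

    Monotone increasing in both arguments; the identity at N = 1.
    """
    p_best = np.asarray(p_best, dtype=float)
    n_snps = np.asarray(n_snps)
    if np.any((p_best <= 0) | (p_best > 1)):
        raise ValueError("p_best must lie in (0, 1]")
    if np.any(n_snps < 1):
        raise ValueError("n_snps must be >= 1")
    # -expm1(k*log1p(-p)) keeps precision for tiny p; p_best = 1 gives 1
    with np.errstate(divide="ignore"):
        out = -np.expm1((n_snps + 1) / 2.0 * np.log1p(-p_best))
    return out if out.ndim else float(out)


def p_to_z(p):
    """Upper-tail standard-normal quantile of a p-value (vectorized).

    Values at or beyond the open interval (0, 1) are clamped to the nearest
    machine-representable bound with a warning.
    """
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0) or np.any(p == 1):
        log.warning("p_to_z: clamping p-values at 0 or 1 to machine bounds")
        p = np.clip(p, _P_FLOOR, _P_CEIL)
    out = norm.isf(p)
    return out if out.ndim else float(out)


def gene_association(records: pd.DataFrame) -> pd.DataFrame:
    """Corrected gene p-values and one-tailed Z from best-SNP records.

    ``records`` has columns gene, p_best, n_snps (one row per gene).
    """
    for col in ("gene", "p_best", "n_snps"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    if records["gene"].duplicated().any():
        raise ValueError("duplicate genes in best-SNP records")
    p_gene = hotspot_correct(records["p_best"].to_numpy(),
                             records["n_snps"].to_numpy())
    return pd.DataFrame({"gene": records["gene"].to_numpy(),
                         "p_gene": p_gene,
                         "z_gwas": p_to_z(p_gene)})
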