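"""Vectorized REML for the per-gene random-intercept region model.

Model, per gene g, over tissue samples s:

    y_s = beta_{region(s)} + u_{brain(s)} + e_s,
    u_b ~ N(0, sigma_u^2),   e_s ~ N(0, sigma_e^2)

with region cell means as the fixed effects (``beta_r`` is the region-level
expression, donor effect marginalized out). All genes share the same design
(region and donor labels), which makes a dedicated solver worthwhile: the
design-dependent linear algebra is factored once, after which each gene costs
a one-dimensional profile-REML optimization over the variance ratio
``theta = sigma_u^2 / sigma_e^2``.

Sketch: let ``P`` project onto the orthogonal complement of the region
design. REML is the Gaussian likelihood of the data in that residual space,
where the covariance is ``sigma_e^2 (I + theta * P Z Z' P)`` and ``Z`` is the
donor indicator matrix. The non-zero eigenvalues ``d_j`` of ``Z' P Z`` (at
most one per donor; one is lost to the region/donor confounded grand mean)
reduce the restricted log-likelihood to

    -2 l(theta) = sum_j log(1 + theta d_j) + (n - p) log sigma_hat^2(theta),
    sigma_hat^2 = [ sum_j c_j^2 / (1 + theta d_j) + t ] / (n - p),

with ``c_j`` the projections of the region-centered data onto the donor
eigendirections and ``t`` the leftover squared norm. Fixed effects are then
the GLS solution at ``theta_hat``, computed through the Woodbury identity
(the donor block is tiny). Estimates agree with gene-by-gene
``statsmodels`` MixedLM fits (see the test suite) at a fraction of the cost.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

_EIG_TOL = 1e-9
_LOG_THETA_BOUNDS = (-14.0, 14.0)


@dataclass
class RandomInterceptFit:
    """REML estimates for every gene sharing one design."""

    region_effects: np.ndarray  # genes x regions (cell means, GLS at theta_hat)
    sigma_u2: np.ndarray        # donor (random-intercept) variance, per gene
    sigma_e2: np.ndarray        # residual variance, per gene
    theta: np.ndarray           # sigma_u2 / sigma_e2, per gene


def _one_hot_counts(codes: np.ndarray, k: int) -> np.ndarray:
    return np.bincount(codes, minlength=k).astype(float)


def fit_random_intercept(y: np.ndarray,
                         region_codes: np.ndarray,
                         donor_codes: np.ndarray,
                         n_regions: int,
                         n_donors: int) -> RandomInterceptFit:
    """Fit the region + donor random-intercept model to every row of ``y``.

    Parameters
    ----------
    y:
        genes x samples data matrix.
    region_codes, donor_codes:
        integer labels per sample, ``0..n_regions-1`` / ``0..n_donors-1``;
        every region and donor must appear at least once.
    """
    y = np.atleast_2d(np.asarray(y, dtype=float))
    region_codes = np.asarray(region_codes)
    donor_codes = np.asarray(donor_codes)
    n_genes, n = y.shape
    p, q = n_regions, n_donors
    if n <= p:
        raise ValueError("need more samples than regions to fit the model")
    n_r = _one_hot_counts(region_codes, p)
    n_b = _one_hot_counts(donor_codes, q)
    if (n_r == 0).any() or (n_b == 0).any():
        raise ValueError("every region and donor must be observed")

    # region x donor count matrix N = X'Z
    N = np.zeros((p, q))
    np.add.at(N, (region_codes, donor_codes), 1.0)

    # Z'PZ = Z'Z - N' diag(1/n_r) N  (donor structure in region-residual space)
    ZtPZ = np.diag(n_b) - N.T @ (N / n_r[:, None])
    d, W = np.linalg.eigh(ZtPZ)
    keep = d > _EIG_TOL * max(1.0, d.max())
    d, W = d[keep], W[:, keep]

    # per-gene sufficient statistics
    region_sums = np.zeros((n_genes, p))
    np.add.at(region_sums.T, region_codes, y.T)
    donor_sums = np.zeros((n_genes, q))
    np.add.at(donor_sums.T, donor_codes, y.T)
    region_means = region_sums / n_r

    # Z'Py = Z'y - N' (region means);   c = W' Z'Py / sqrt(d)
    ZtPy = donor_sums - region_means @ N
    c = (ZtPy @ W) / np.sqrt(d)                       # genes x n_eig
    ss_total = np.einsum("ij,ij->i", y, y)
    ss_region = np.einsum("ij,ij->i", region_sums, region_means)
    ss_resid = np.maximum(ss_total - ss_region, 0.0)  # ||Py||^2
    t = np.maximum(ss_resid - np.einsum("ij,ij->i", c, c), 0.0)

    dof = n - p
    theta = np.zeros(n_genes)
    sigma_e2 = np.empty(n_genes)
    for g in range(n_genes):
        c2 = c[g] ** 2
        if ss_resid[g] <= 1e-300:   # flat gene: nothing to fit
            sigma_e2[g] = 0.0
            continue

        def neg2_reml(log_th: float) -> float:
            th = np.exp(log_th)
            denom = 1.0 + th * d
            s2 = (np.sum(c2 / denom) + t[g]) / dof
            return float(np.sum(np.log(denom)) + dof * np.log(s2))

        res = minimize_scalar(neg2_reml, bounds=_LOG_THETA_BOUNDS,
                              method="bounded",
                              options={"xatol": 1e-8})
        at_zero = dof * np.log(ss_resid[g] / dof)  # boundary theta = 0
        if res.fun < at_zero - 1e-12:
            theta[g] = np.exp(res.x)
        sigma_e2[g] = (np.sum(c2 / (1.0 + theta[g] * d)) + t[g]) / dof

    sigma_u2 = theta * sigma_e2

    # GLS fixed effects via Woodbury: V^-1 = I - Z diag(w) Z', w_b = th/(1+th n_b)
    beta = region_means.copy()
    XtX = np.diag(n_r)
    nontrivial = np.nonzero(theta > 0)[0]
    for g in nontrivial:
        w = theta[g] / (1.0 + theta[g] * n_b)
        A = XtX - (N * w) @ N.T
        rhs = region_sums[g] - N @ (w * donor_sums[g])
        beta[g] = np.linalg.solve(A, rhs)

    return RandomInterceptFit(region_effects=beta, sigma_u2=sigma_u2,
                              sigma_e2=sigma_e2, theta=theta)
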