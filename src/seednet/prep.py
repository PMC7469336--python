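"""Expression preparation: probe collapsing, region-level expression, PCA QC.

The pipeline order is fixed: probes are averaged into genes first, then the
gene x sample matrix is reduced to a gene x region matrix, either by a
mixed-effect adjustment that accounts for repeated sampling of donors and
regions (``fit_region_expression``) or by plain within-donor means
(``per_brain_region_means``) when building one network per brain.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .lmm import fit_random_intercept
from .types import RegionExpression, validate_annotations, validate_expression

log = logging.getLogger(__name__)

_GRANULARITY_COLUMN = {"low": "region_low", "mid": "structure_mid"}


def collapse_probes(matrix: pd.DataFrame,
                    probe2gene: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Average all probes mapping to each gene, per sample.

    Probes absent from the mapping are dropped (count logged). Column order
    is preserved. Raises if no probe maps to any gene.
    """
    validate_expression(matrix)
    mapping = pd.Series(dict(probe2gene)) if not isinstance(probe2gene, pd.Series) \
        else probe2gene
    genes = matrix.index.map(mapping)
    unmapped = genes.isna()
    if unmapped.any():
        log.info("collapse_probes: dropping %d unmapped probes", int(unmapped.sum()))
    kept = matrix.loc[~unmapped]
    if kept.empty:
        raise ValueError("no probe maps to a gene; nothing to collapse")
    collapsed = kept.groupby(genes[~unmapped]).mean()
    collapsed.index.name = matrix.index.name
    return collapsed[matrix.columns]


def _region_table(ann: pd.DataFrame, granularity: str) -> pd.DataFrame:
    col = _GRANULARITY_COLUMN[granularity]
    tbl = (ann.groupby(col, observed=True)[["structure_high", "structure_mid"]]
              .first())
    tbl.index.name = "region"
    return tbl


def fit_region_expression(matrix: pd.DataFrame,
                          ann: pd.DataFrame,
                          granularity: str = "low") -> RegionExpression:
    """Donor-adjusted region-level expression via a mixed-effect model.

    Per gene: expression ~ region (fixed, one level per region at the chosen
    granularity) + donor (random intercept), fitted by REML; the reported
    region value is the estimated region cell mean with the donor effect
    marginalized out. With a balanced design or zero estimated donor
    variance this collapses to plain per-region means.
    """
    if granularity not in _GRANULARITY_COLUMN:
        raise ValueError(f"granularity must be one of {sorted(_GRANULARITY_COLUMN)}")
    validate_expression(matrix)
    validate_annotations(ann)
    missing = [s for s in matrix.columns if s not in ann.index]
    if missing:
        raise ValueError(f"samples without annotations: {missing[:5]}")
    sub = ann.loc[list(matrix.columns)]
    if sub["brain_id"].nunique() < 2:
        raise ValueError("mixed-model adjustment needs at least 2 donors")
    col = _GRANULARITY_COLUMN[granularity]
    region_cat = pd.Categorical(sub[col])
    donor_cat = pd.Categorical(sub["brain_id"])
    regions = list(region_cat.categories)

    singles = pd.Series(region_cat).value_counts()
    lonely = singles[singles == 1]
    if len(lonely):
        log.warning("regions observed in a single sample (value = that sample): %s",
                    lonely.index.tolist()[:5])

    fit = fit_random_intercept(matrix.to_numpy(), region_cat.codes,
                               donor_cat.codes, len(regions),
                               len(donor_cat.categories))
    values = pd.DataFrame(fit.region_effects, index=matrix.index, columns=regions)
    vc = pd.DataFrame({"sigma_u2": fit.sigma_u2, "sigma_e2": fit.sigma_e2},
                      index=matrix.index)
    return RegionExpression(values=values, regions=_region_table(sub, granularity),
                            provenance="mixed_model", variance_components=vc)


def per_brain_region_means(matrix: pd.DataFrame,
                           ann: pd.DataFrame,
                           brain_id: str,
                           granularity: str = "low") -> RegionExpression:
    """Region-level expression from a single donor's samples (plain means).

    Regions the donor never sampled are dropped.
    """
    if granularity not in _GRANULARITY_COLUMN:
        raise ValueError(f"granularity must be one of {sorted(_GRANULARITY_COLUMN)}")
    validate_expression(matrix)
    validate_annotations(ann)
    sub = ann.loc[[s for s in matrix.columns if s in ann.index]]
    samples = sub.index[sub["brain_id"] == brain_id]
    if len(samples) == 0:
        raise ValueError(f"donor {brain_id!r} has no annotated samples")
    col = _GRANULARITY_COLUMN[granularity]
    values = matrix[list(samples)].T.groupby(sub.loc[samples, col]).mean().T
    values.columns.name = None
    return RegionExpression(values=values,
                            regions=_region_table(sub.loc[samples], granularity),
                            provenance="per_brain_mean", brain_id=brain_id)


def pca_qc(matrix: pd.DataFrame,
           ann: pd.DataFrame | None = None,
           n_components: int = 2) -> pd.DataFrame:
    """Centered (unscaled) PCA of sample expression vectors.

    Returns one row per sample with PC coordinates, joined with the
    high-level structure label when annotations are supplied — the table
    behind the batch-effect scatterplot.
    """
    from sklearn.decomposition import PCA

    validate_expression(matrix)
    if matrix.shape[1] < 3:
        raise ValueError("PCA QC needs at least 3 samples")
    if n_components > matrix.shape[1]:
        raise ValueError("fewer samples than requested components")
    coords = PCA(n_components=n_components).fit_transform(matrix.T.to_numpy())
    out = pd.DataFrame(coords, index=matrix.columns,
                       columns=[f"PC{i + 1}" for i in range(n_components)])
    out.index.name = "sample_id"
    if ann is not None:
        out = out.join(ann["structure_high"], how="left")
    return out
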