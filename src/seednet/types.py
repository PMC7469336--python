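"""Shared domain containers and controlled vocabularies.

Tabular data travel as :class:`pandas.DataFrame` throughout the package;
the dataclasses here bundle a frame with the metadata that gives it meaning
(provenance, region hierarchy, planted truth).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: The three top-level brain structures used for network stratification.
HIGH_STRUCTURES = ("cerebrum", "cerebellum", "brain_stem")

#: Knockout phenotype codes counted as AD-related in the fly-ortholog filter.
AD_PHENOTYPES = ("DM", "DA", "OS", "PA")

PHENOTYPE_NAMES = {
    "DM": "defective_memory",
    "DA": "defective_aging",
    "OS": "oxidative_stress",
    "PA": "premature_aging",
}

ANNOTATION_COLUMNS = ("brain_id", "structure_high", "structure_mid", "region_low")


def validate_annotations(ann: pd.DataFrame) -> pd.DataFrame:
    """Check a sample-annotation table (indexed by sample id).

    Requires the donor and three-level region hierarchy columns, unique sample
    ids, known high-level structures, and proper nesting (each fine region
    belongs to exactly one mid structure, each mid to one high structure).
    """
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in annotations: {dups[:5]}")
    bad = set(ann["structure_high"]) - set(HIGH_STRUCTURES)
    if bad:
        raise ValueError(f"unknown high-level structures: {sorted(bad)}")
    if ann[list(ANNOTATION_COLUMNS)].isna().any().any():
        raise ValueError("annotations contain missing values")
    for child, parent in (("region_low", "structure_mid"),
                          ("structure_mid", "structure_high")):
        n_parents = ann.groupby(child, observed=True)[parent].nunique()
        broken = n_parents[n_parents > 1]
        if len(broken):
            raise ValueError(
                f"{child} labels map to multiple {parent} values: "
                f"{broken.index.tolist()[:5]}")
    return ann


def validate_expression(values: pd.DataFrame) -> pd.DataFrame:
    """Check a genes/probes x samples expression frame: unique ids, finite."""
    if values.index.has_duplicates:
        dups = values.index[values.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate row ids in expression matrix: {dups[:5]}")
    if values.columns.has_duplicates:
        dups = values.columns[values.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in expression matrix: {dups[:5]}")
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("expression matrix contains non-numeric cells")
    if not np.isfinite(arr).all():
        raise ValueError("expression matrix contains missing or non-finite values")
    return values


@dataclass
class RegionExpression:
    """Gene x region expression after within-region aggregation.

    ``values`` has one row per gene and one column per region at the chosen
    granularity. ``regions`` (indexed by region label) records the structure
    hierarchy for each column. ``provenance`` is ``"mixed_model"`` when the
    values are donor-adjusted fixed-effect estimates, or ``"per_brain_mean"``
    when they are plain means from a single donor (``brain_id`` then set).
    """

    values: pd.DataFrame
    regions: pd.DataFrame
    provenance: str
    brain_id: str | None = None
    variance_components: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("mixed_model", "per_brain_mean"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        unknown = [r for r in self.values.columns if r not in self.regions.index]
        if unknown:
            raise ValueError(f"regions without structure lookup: {unknown[:5]}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("region expression contains non-finite values")

    def subset_regions(self, structure_high: str) -> list[str]:
        """Region labels belonging to one high-level structure."""
        keep = self.regions.index[self.regions["structure_high"] == structure_high]
        return [r for r in self.values.columns if r in set(keep)]


@dataclass
class CorrelationNetwork:
    """Fully connected co-expression network over a stated region subset.

    ``weights[i, j]`` is the absolute Pearson correlation of genes i and j
    across the subset's region-level expression values. The diagonal is
    stored as 1 but excluded from every score that consumes the network.
    """

    genes: list[str]
    weights: np.ndarray
    region_subset: list[str]
    n_obs: int

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.genes), len(self.genes)):
            raise ValueError("weight matrix shape does not match gene list")
        if self.n_obs < 3:
            raise ValueError("a correlation network needs at least 3 observations")
        if not np.allclose(w, w.T, atol=1e-12):
            raise ValueError("weight matrix is not symmetric")
        if w.min() < -1e-12 or w.max() > 1 + 1e-12:
            raise ValueError("absolute correlations must lie in [0, 1]")
        self.weights = w
        self._index = {g: i for i, g in enumerate(self.genes)}

    def index_of(self, gene: str) -> int:
        return self._index[gene]


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic study, recorded exactly as drawn."""

    seed_genes: list[str]
    signal_genes: list[str]
    loadings: dict[str, float]
    region_effects: pd.DataFrame
    region_factor: pd.Series
    gwas_z: pd.Series
    rng_seed: int


@dataclass
class SyntheticStudy:
    """One fully generated dataset: every input the pipeline consumes."""

    expression: pd.DataFrame
    annotations: pd.DataFrame
    gwas: pd.DataFrame
    phenotypes: pd.DataFrame
    truth: SyntheticTruth
    region_groups: dict[str, list[str]] = field(default_factory=dict)
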