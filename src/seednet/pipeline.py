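"""End-to-end conveniences tying the stages together."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .gwas import gene_association
from .integrate import rank_candidates
from .network import build_network, mrc, nonseed_scores, seed_cr_loo
from .types import CorrelationNetwork, RegionExpression


@dataclass
class SeededScores:
    """All seeded scores of one network: seeds (leave-one-out) and non-seeds."""

    network: CorrelationNetwork
    seed_scores: pd.DataFrame     # index gene; sum_abs_corr, cr (leave-one-out)
    nonseed: pd.DataFrame         # index gene; sum_abs_corr, percentile_top, cr

    @property
    def mrc(self) -> float:
        return mrc(self.seed_scores["cr"])


def score_network(region_expr: RegionExpression,
                  seeds: Sequence[str],
                  subset: Sequence[str] | None = None) -> SeededScores:
    """Build one network and compute every seeded score on it."""
    net = build_network(region_expr, subset)
    return SeededScores(network=net,
                        seed_scores=seed_cr_loo(net, seeds),
                        nonseed=nonseed_scores(net, seeds))


def prioritize(region_expr: RegionExpression,
               seeds: Sequence[str],
               gwas_records: pd.DataFrame,
               phenotype_table: pd.DataFrame,
               subset: Sequence[str] | None = None) -> pd.DataFrame:
    """Rank novel candidates: network scores + GWAS Z + phenotype filter + FDR."""
    scores = score_network(region_expr, seeds, subset)
    assoc = gene_association(gwas_records)
    return rank_candidates(scores.nonseed, assoc, phenotype_table)
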