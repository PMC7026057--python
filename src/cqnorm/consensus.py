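"""Consensus ranking of the four stability methods and optimal gene count.

Each stability algorithm scores the same candidate set; its scores are
turned into ranks (average ranks on ties) and the per-gene geometric mean
of the four ranks gives the comprehensive weighted order.  The optimal
number of reference genes is then read off the pairwise-variation series
computed along that consensus order: the first V_n/n+1 below the cutoff
(default 0.15) means adding the (n+1)-th gene is unnecessary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .stability import PairwiseVariationSeries, genorm_pairwise_variation
from .transform import QuantityMatrix

logger = logging.getLogger("cqnorm")

DEFAULT_V_CUTOFF = 0.15


@dataclass
class ConsensusRanking:
    ranks: pd.DataFrame  # methods x genes, tie-averaged ranks
    geomean: pd.Series  # per-gene geometric mean of the method ranks
    order: list[str]  # genes, most stable first

    def to_tsv(self, path) -> None:
        tab = self.ranks.T.copy()
        tab["geomean_rank"] = self.geomean
        tab["consensus_rank"] = range(1, len(self.order) + 1)
        tab.loc[self.order].rename_axis("gene").to_csv(
            path, sep="\t", float_format="%.4g"
        )


def method_ranks(scores: dict[str, pd.Series]) -> pd.DataFrame:
    """Turn per-method stability scores into ranks (ascending = stable).

    Exact score ties receive the average of the tied positions.  All
    methods must have scored the same gene set.
    """
    if not scores:
        raise ValueError("no method scores supplied")
    gene_sets = {m: frozenset(s.index) for m, s in scores.items()}
    ref = next(iter(gene_sets.values()))
    mismatched = [m for m, gs in gene_sets.items() if gs != ref]
    if mismatched:
        raise ValueError(f"methods scored different gene sets: {mismatched}")
    ranks = pd.DataFrame(
        {m: s.rank(method="average") for m, s in scores.items()}
    ).T
    return ranks


def reffinder_consensus(ranks: pd.DataFrame) -> ConsensusRanking:
    """Geometric-mean aggregation of per-method ranks.

    The consensus order is ascending in the geometric mean rank; ties are
    broken by arithmetic mean rank, then lexicographically.
    """
    geomean = pd.Series(
        stats.gmean(ranks, axis=0), index=ranks.columns, name="geomean_rank"
    )
    arith = ranks.mean(axis=0)
    order = sorted(ranks.columns, key=lambda g: (geomean[g], arith[g], g))
    return ConsensusRanking(ranks=ranks, geomean=geomean, order=order)


def optimal_rg_count(
    q: QuantityMatrix | pd.DataFrame,
    consensus: ConsensusRanking | list[str],
    cutoff: float = DEFAULT_V_CUTOFF,
    n_max: int | None = None,
) -> PairwiseVariationSeries:
    """Recommended number of reference genes from the V_n/n+1 series.

    The normalization factors follow the consensus order; the optimal n
    is the first with V_n/n+1 < cutoff (adding gene n+1 is unnecessary).
    When no V falls below the cutoff the optimal count is left undefined
    and using the full candidate set is recommended.
    """
    order = consensus.order if isinstance(consensus, ConsensusRanking) else consensus
    series = genorm_pairwise_variation(q, order, n_max=n_max)
    series.cutoff = cutoff
    below = series.v.index[series.v < cutoff]
    if len(below):
        series.optimal_n = int(below[0])
    else:
        series.optimal_n = None
        logger.warning(
            "no pairwise variation below the %.3g cutoff; consider using "
            "the full set of %d candidate genes",
            cutoff,
            len(order),
        )
    return series
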