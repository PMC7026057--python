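"""High-level pipeline: dataset -> stability ranking -> quantification.

These helpers wire the module-level operations together in the standard
order (collapse technical replicates, efficiency-correct, convert to
relative quantities, score with all four algorithms, aggregate, read the
pairwise-variation series) and are what the CLI, the examples and most
interactive users call.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .consensus import (
    DEFAULT_V_CUTOFF,
    ConsensusRanking,
    method_ranks,
    optimal_rg_count,
    reffinder_consensus,
)
from .evaluation import GroupTestReport, ReductionReport, group_tests, reduction_study
from .io import CollapsedCqTable, CqDataset, collapse_technical_replicates, validate_complete_matrix
from .normalization import NormalizedExpression, quantify
from .stability import (
    BestKeeperResult,
    DeltaCtResult,
    GeNormResult,
    NormFinderResult,
    PairwiseVariationSeries,
    bestkeeper,
    delta_ct,
    genorm,
    normfinder,
)
from .transform import QuantityMatrix, efficiency_correct_table, to_relative_quantity

METHODS = ("genorm", "normfinder", "bestkeeper", "delta_ct")


@dataclass
class StabilityReport:
    """Everything the ranking stage produces."""

    raw: CollapsedCqTable  # complete raw Cq matrix (candidates only)
    cqe: CollapsedCqTable
    quantities: QuantityMatrix
    genorm: GeNormResult | None
    normfinder: NormFinderResult | None
    bestkeeper: BestKeeperResult | None
    delta_ct: DeltaCtResult | None
    consensus: ConsensusRanking | None
    v_series: PairwiseVariationSeries | None

    @property
    def recommended(self) -> list[str] | None:
        """Top consensus genes up to the optimal count (None if unresolved)."""
        if self.consensus is None or self.v_series is None:
            return None
        if self.v_series.optimal_n is None:
            return None
        return self.consensus.order[: self.v_series.optimal_n]


def prepare_quantities(
    ds: CqDataset,
    genes: list[str] | None = None,
    missing_policy: str = "strict",
) -> tuple[CollapsedCqTable, CollapsedCqTable, QuantityMatrix]:
    """Collapse, filter to completeness, efficiency-correct, convert.

    Returns (raw collapsed table, CqE table, quantity matrix), all over
    the same complete gene x sample grid.
    """
    collapsed = collapse_technical_replicates(ds)
    complete = validate_complete_matrix(collapsed, genes=genes, policy=missing_policy)
    cqe = efficiency_correct_table(complete, ds.efficiency)
    qm = to_relative_quantity(cqe)
    return complete, cqe, qm


def rank_genes(
    ds: CqDataset,
    candidates: list[str] | None = None,
    methods: tuple[str, ...] = METHODS,
    cutoff: float = DEFAULT_V_CUTOFF,
    missing_policy: str = "strict",
    delta_ct_on_cqe: bool = True,
    bestkeeper_on_cqe: bool = False,
) -> StabilityReport:
    """Run the stability algorithms and, with all four, the consensus.

    ``candidates`` defaults to every gene in the dataset; pass a subset
    to keep genes of interest out of the candidate pool.  BestKeeper
    works on raw Cq and the comparative delta-Ct on CqE by default, both
    switchable.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    raw, cqe, qm = prepare_quantities(ds, genes=candidates, missing_policy=missing_policy)
    groups = ds.meta.loc[raw.samples, "group"]

    gn = genorm(qm) if "genorm" in methods else None
    nf = normfinder(-cqe.cq, groups) if "normfinder" in methods else None
    bk = (
        bestkeeper(cqe if bestkeeper_on_cqe else raw)
        if "bestkeeper" in methods
        else None
    )
    dc = (
        delta_ct(cqe if delta_ct_on_cqe else raw)
        if "delta_ct" in methods
        else None
    )

    cons = v_series = None
    if all(m in methods for m in METHODS):
        ranks = method_ranks(
            {
                "genorm": gn.ranking,  # iterative-elimination rank
                "normfinder": nf.rho,
                "bestkeeper": bk.sd_cq,
                "delta_ct": dc.score,
            }
        )
        cons = reffinder_consensus(ranks)
        if len(cons.order) >= 3:
            v_series = optimal_rg_count(qm, cons, cutoff=cutoff)
    return StabilityReport(
        raw=raw,
        cqe=cqe,
        quantities=qm,
        genorm=gn,
        normfinder=nf,
        bestkeeper=bk,
        delta_ct=dc,
        consensus=cons,
        v_series=v_series,
    )


@dataclass
class QuantificationReport:
    expression: NormalizedExpression
    tests: GroupTestReport
    reduction: ReductionReport | None = None


def quantify_goi(
    ds: CqDataset,
    goi: str,
    rgs: list[str],
    calibrator_group: str,
    reduction_order: list[str] | None = None,
    missing_policy: str = "strict",
) -> QuantificationReport:
    """Normalize a gene of interest and run the group statistics.

    When ``reduction_order`` is given (usually the consensus order), a
    stepwise reduction study from len(rgs) down to 2 genes is added.
    """
    genes = sorted(set(rgs) | {goi} | set(reduction_order or []))
    _, _, qm = prepare_quantities(ds, genes=genes, missing_policy=missing_policy)
    groups = ds.meta.loc[qm.samples, "group"]
    ne = quantify(qm, goi, rgs, groups, calibrator_group)
    tests = group_tests(ne.fold, groups, calibrator_group)
    red = None
    if reduction_order is not None:
        red = reduction_study(
            qm, goi, reduction_order, len(rgs), groups, calibrator_group
        )
    return QuantificationReport(expression=ne, tests=tests, reduction=red)


def stability_scores_table(report: StabilityReport) -> pd.DataFrame:
    """Per-gene score and rank of every method that ran, one table."""
    cols = {}
    if report.genorm is not None:
        cols["genorm_M"] = report.genorm.m
        cols["genorm_rank"] = report.genorm.ranking
    if report.normfinder is not None:
        cols["normfinder_rho"] = report.normfinder.rho
        cols["normfinder_rank"] = report.normfinder.rho.rank(method="average")
    if report.bestkeeper is not None:
        cols["bestkeeper_sd"] = report.bestkeeper.sd_cq
        cols["bestkeeper_rank"] = report.bestkeeper.sd_cq.rank(method="average")
    if report.delta_ct is not None:
        cols["delta_ct_sd"] = report.delta_ct.score
        cols["delta_ct_rank"] = report.delta_ct.score.rank(method="average")
    tab = pd.DataFrame(cols).rename_axis("gene")
    if report.consensus is not None:
        tab["consensus_geomean"] = report.consensus.geomean
        tab["consensus_rank"] = [
            report.consensus.order.index(g) + 1 for g in tab.index
        ]
        tab = tab.sort_values("consensus_rank")
    return tab
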