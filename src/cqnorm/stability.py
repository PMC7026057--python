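"""The four reference-gene stability algorithms.

* geNorm: a gene's stability M is the mean standard deviation of its
  pairwise log2 expression ratios with every other candidate; genes are
  ranked by iterative elimination of the worst M.  The companion pairwise
  variation V_n/n+1 measures how much the normalization factor changes
  when an (n+1)-th gene is added.
* NormFinder: a model-based estimator separating intra-group variance
  from (shrunken) inter-group expression differences.
* BestKeeper: descriptive dispersion of raw Cq values plus Pearson
  correlation of each gene against the per-sample geometric-mean index.
* Comparative delta-Ct: mean standard deviation of pairwise Cq
  differences across samples.

All standard deviations use the n-1 (sample) denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CollapsedCqTable
from .transform import QuantityMatrix


# ---------------------------------------------------------------------------
# geNorm


@dataclass
class GeNormResult:
    m: pd.Series  # full-set stability value M per gene (log2-ratio SD units)
    pairwise_sd: pd.DataFrame  # V_jk = SD_s log2(q_j/q_k)
    removal_order: list[str]  # least stable first; ends with the final pair
    ranking: pd.Series  # 1 = most stable (elimination rank)


def _pairwise_log_ratio_sd(log2q: np.ndarray) -> np.ndarray:
    """SD over samples of log2 q_j - log2 q_k for every gene pair (j, k)."""
    k = log2q.shape[0]
    out = np.zeros((k, k))
    for j in range(k):
        diffs = log2q[j] - log2q  # (k, n)
        out[j] = diffs.std(axis=1, ddof=1)
    return out


def genorm(q: QuantityMatrix | pd.DataFrame) -> GeNormResult:
    """geNorm stability values and iterative elimination ranking.

    The final surviving pair cannot be resolved by elimination; its ranks
    1 and 2 are assigned by the full-set M (ties broken lexicographically)
    so that the output is deterministic.
    """
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    genes = list(qdf.index)
    if len(genes) < 3:
        raise ValueError("geNorm requires at least 3 candidate genes")
    if qdf.shape[1] < 2:
        raise ValueError("geNorm requires at least 2 samples")
    vals = qdf.to_numpy(dtype=float)
    if not np.all(vals > 0):
        raise ValueError("quantities must be strictly positive")
    log2q = np.log2(vals)

    vjk = _pairwise_log_ratio_sd(log2q)
    pairwise_sd = pd.DataFrame(vjk, index=genes, columns=genes)
    k = len(genes)
    m_full = pd.Series(vjk.sum(axis=1) / (k - 1), index=genes, name="M")

    # iterative elimination: recompute M on the surviving set each round
    surviving = list(genes)
    removal_order: list[str] = []
    while len(surviving) > 2:
        sub = pairwise_sd.loc[surviving, surviving]
        m_cur = sub.sum(axis=1) / (len(surviving) - 1)
        # worst M; lexicographic tie-break for determinism
        worst = max(sorted(surviving), key=lambda g: (m_cur[g], g))
        removal_order.append(worst)
        surviving.remove(worst)
    final_pair = sorted(surviving, key=lambda g: (m_full[g], g))
    removal_order.extend(final_pair[::-1])

    ranking = pd.Series(
        {g: k - i for i, g in enumerate(removal_order)}, name="rank", dtype=float
    ).loc[genes]
    return GeNormResult(
        m=m_full,
        pairwise_sd=pairwise_sd,
        removal_order=removal_order,
        ranking=ranking,
    )


@dataclass
class PairwiseVariationSeries:
    """NF_n series and the pairwise variation V_n/n+1 between them."""

    v: pd.Series  # indexed by n (2..n_max-1): V_{n/n+1}
    nf: pd.DataFrame  # rows n, columns samples: NF_n
    order: list[str]  # ranked gene list the NFs were built from
    cutoff: float | None = None
    optimal_n: int | None = None

    def to_tsv(self, path) -> None:
        tab = self.v.rename("V").rename_axis("n").reset_index()
        tab["transition"] = [f"V{n}/{n + 1}" for n in tab["n"]]
        if self.cutoff is not None:
            tab["below_cutoff"] = tab["V"] < self.cutoff
            tab["optimal"] = tab["n"] == self.optimal_n
        tab.to_csv(path, sep="\t", index=False)


def genorm_pairwise_variation(
    q: QuantityMatrix | pd.DataFrame,
    order: list[str],
    n_max: int | None = None,
) -> PairwiseVariationSeries:
    """Pairwise variation V_n/n+1 of sequential normalization factors.

    NF_n is the per-sample geometric mean of the quantities of the n
    top-ranked genes in ``order``; V_n/n+1 is the sample SD over samples
    of log2(NF_n / NF_n+1), for n = 2 .. n_max-1.  A small V means the
    (n+1)-th gene barely changes the normalization factor.
    """
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    unknown = set(order) - set(qdf.index)
    if unknown:
        raise KeyError(f"ranked genes not in matrix: {sorted(unknown)}")
    if n_max is None:
        n_max = len(order)
    if n_max < 3:
        raise ValueError("pairwise variation needs n_max >= 3 genes")
    if n_max > len(order):
        raise ValueError(f"n_max={n_max} exceeds ranked list ({len(order)})")

    log2q = np.log2(qdf.loc[list(order[:n_max])].to_numpy(dtype=float))
    # log2 NF_n = mean of the first n rows
    cum = np.cumsum(log2q, axis=0)
    ns = np.arange(1, n_max + 1)[:, None]
    log2nf = cum / ns
    v = {
        n: float(np.std(log2nf[n - 1] - log2nf[n], ddof=1))
        for n in range(2, n_max)
    }
    nf = pd.DataFrame(
        np.power(2.0, log2nf[1:]),
        index=pd.Index(range(2, n_max + 1), name="n"),
        columns=qdf.columns,
    )
    return PairwiseVariationSeries(
        v=pd.Series(v, name="V").rename_axis("n"),
        nf=nf,
        order=list(order[:n_max]),
    )


# ---------------------------------------------------------------------------
# NormFinder


@dataclass
class NormFinderResult:
    rho: pd.Series  # stability value, lower = more stable
    d_bar: pd.DataFrame  # gene x group mean of sample-centered values
    s2: pd.DataFrame  # gene x group sample variance of centered values
    sigma2_hat: pd.DataFrame  # corrected intra-group variance, >= 0
    gamma2_hat: float  # inter-group variance of group differences
    d_shrunk: pd.DataFrame  # shrunken inter-group differences
    n_per_group: pd.Series = field(repr=False, default=None)


def normfinder(
    y: pd.DataFrame, groups: pd.Series | None = None
) -> NormFinderResult:
    """Model-based stability value from intra- and inter-group variation.

    Parameters
    ----------
    y
        genes x samples matrix of log2-scale expression (e.g. -CqE or
        log2 relative quantity; the result is invariant to per-gene
        additive offsets, hence to that choice).
    groups
        sample -> group label.  With a single group the stability value
        reduces to the corrected intra-group SD.

    The per-sample gene-average is removed first (absorbing loading
    differences), then each gene's intra-group variance is corrected for
    the centering, and with several groups the gene x group differences
    are shrunk toward zero in proportion to their estimation noise.
    """
    genes = list(y.index)
    k = len(genes)
    if k < 3:
        raise ValueError("NormFinder needs >= 3 genes (variance correction)")
    if groups is None:
        groups = pd.Series("all", index=y.columns)
    groups = groups.loc[y.columns]
    labels = list(dict.fromkeys(groups))
    G = len(labels)

    d_bar = pd.DataFrame(index=genes, columns=labels, dtype=float)
    s2 = pd.DataFrame(index=genes, columns=labels, dtype=float)
    sigma2 = pd.DataFrame(index=genes, columns=labels, dtype=float)
    n_per_group = pd.Series(0, index=labels, dtype=int)

    for g in labels:
        cols = groups.index[groups == g]
        n_g = len(cols)
        if n_g < 2:
            raise ValueError(f"group {g!r} has {n_g} sample(s); need >= 2")
        n_per_group[g] = n_g
        z = y[cols].to_numpy(dtype=float)
        z = z - z.mean(axis=0, keepdims=True)  # center per sample over genes
        d_bar[g] = z.mean(axis=1)
        s2[g] = z.var(axis=1, ddof=1)
        s_g = s2[g].sum()
        sigma2[g] = np.maximum(
            0.0, (k / (k - 2)) * (s2[g] - s_g / (k * (k - 1)))
        )

    if G == 1:
        rho = np.sqrt(sigma2[labels[0]])
        return NormFinderResult(
            rho=pd.Series(rho, index=genes, name="rho"),
            d_bar=d_bar,
            s2=s2,
            sigma2_hat=sigma2,
            gamma2_hat=0.0,
            d_shrunk=pd.DataFrame(0.0, index=genes, columns=labels),
            n_per_group=n_per_group,
        )

    d = d_bar.sub(d_bar.mean(axis=1), axis=0)
    var_noise = sigma2.div(n_per_group, axis=1)
    # variance of the true gene x group differences; d carries (k-1)(G-1)
    # free dimensions after the two centerings
    gamma2 = float(
        max(
            0.0,
            (d.to_numpy() ** 2).sum() / ((k - 1) * (G - 1))
            - var_noise.to_numpy().mean(),
        )
    )
    shrink = gamma2 / (gamma2 + var_noise)
    d_shrunk = d * shrink
    post_sd = np.sqrt(gamma2 * var_noise / (gamma2 + var_noise))
    rho = (d_shrunk.abs() + post_sd).mean(axis=1)
    return NormFinderResult(
        rho=pd.Series(rho, index=genes, name="rho"),
        d_bar=d_bar,
        s2=s2,
        sigma2_hat=sigma2,
        gamma2_hat=gamma2,
        d_shrunk=d_shrunk,
        n_per_group=n_per_group,
    )


# ---------------------------------------------------------------------------
# BestKeeper


@dataclass
class BestKeeperResult:
    stats: pd.DataFrame  # per gene: arith_mean, geo_mean, min, max, sd_cq,
    #                      cv_pct, r, p, inconsistent
    index: pd.Series  # per-sample BestKeeper index (geometric mean of Cq)
    qc_warnings: list[str] = field(default_factory=list)

    @property
    def sd_cq(self) -> pd.Series:
        return self.stats["sd_cq"]


def bestkeeper(
    table: CollapsedCqTable | pd.DataFrame, sd_flag: float = 1.0
) -> BestKeeperResult:
    """BestKeeper descriptive statistics on raw Cq values.

    Dispersion (``sd_cq``) is the mean absolute deviation from each
    gene's arithmetic mean Cq, in cycles; genes with sd_cq beyond
    ``sd_flag`` cycles are flagged inconsistent.  Each gene is also
    correlated (Pearson) against the BestKeeper index, the per-sample
    geometric mean of all candidates' Cq values.
    """
    cq = table.cq if isinstance(table, CollapsedCqTable) else table
    if cq.shape[0] < 2 or cq.shape[1] < 3:
        raise ValueError("BestKeeper needs >= 2 genes and >= 3 samples")
    if cq.isna().values.any():
        raise ValueError("BestKeeper requires a complete Cq matrix")
    vals = cq.to_numpy(dtype=float)
    warnings: list[str] = []

    arith = vals.mean(axis=1)
    geo = np.exp(np.log(vals).mean(axis=1))
    sd_cq = np.abs(vals - arith[:, None]).mean(axis=1)
    cv = 100.0 * sd_cq / arith
    index = np.exp(np.log(vals).mean(axis=0))

    r = np.full(len(cq.index), np.nan)
    p = np.full(len(cq.index), np.nan)
    for i, gene in enumerate(cq.index):
        if np.ptp(vals[i]) == 0 or np.ptp(index) == 0:
            warnings.append(
                f"gene {gene}: zero variance, correlation vs index undefined"
            )
            continue
        r[i], p[i] = stats.pearsonr(vals[i], index)

    res = pd.DataFrame(
        {
            "arith_mean": arith,
            "geo_mean": geo,
            "min": vals.min(axis=1),
            "max": vals.max(axis=1),
            "sd_cq": sd_cq,
            "cv_pct": cv,
            "r": r,
            "p": p,
            "inconsistent": sd_cq > sd_flag,
        },
        index=cq.index,
    )
    return BestKeeperResult(
        stats=res,
        index=pd.Series(index, index=cq.columns, name="bestkeeper_index"),
        qc_warnings=warnings,
    )


# ---------------------------------------------------------------------------
# comparative delta-Ct


@dataclass
class DeltaCtResult:
    score: pd.Series  # mean over partners of SD of pairwise Cq differences
    pair_sd: pd.DataFrame


def delta_ct(table: CollapsedCqTable | pd.DataFrame) -> DeltaCtResult:
    """Comparative delta-Ct stability: mean SD of pairwise Cq differences.

    For each gene pair the SD over samples of Cq_j - Cq_k is computed
    (n-1 denominator); a gene's score is the mean over its partners.
    Works on raw Cq or CqE (shift-invariant per gene either way).
    """
    cq = table.cq if isinstance(table, CollapsedCqTable) else table
    if cq.shape[0] < 2 or cq.shape[1] < 2:
        raise ValueError("delta-Ct needs >= 2 genes and >= 2 samples")
    if cq.isna().values.any():
        raise ValueError("delta-Ct requires a complete matrix")
    vals = cq.to_numpy(dtype=float)
    sd = _pairwise_log_ratio_sd(vals)  # same algebra: SD of row differences
    pair_sd = pd.DataFrame(sd, index=cq.index, columns=cq.index)
    score = pd.Series(
        sd.sum(axis=1) / (len(cq.index) - 1), index=cq.index, name="delta_ct"
    )
    return DeltaCtResult(score=score, pair_sd=pair_sd)
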