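"""Normalization-factor computation and fold-change quantification.

The normalization factor (NF) of a sample is the geometric mean of the
selected reference genes' relative quantities; a gene of interest (GOI)
is normalized by dividing its quantity by the NF, and fold changes are
expressed relative to the mean normalized quantity of a calibrator group
(e.g. premeiosis).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .transform import QuantityMatrix


@dataclass
class NormalizedExpression:
    nf: pd.Series  # per-sample normalization factor
    rel: pd.Series  # normalized GOI quantity per sample
    fold: pd.Series  # expression ratio vs calibrator-group mean
    calibrator_group: str
    rg_set: list[str]
    groups: pd.Series  # sample -> group
    group_summary: pd.DataFrame  # per group: n, mean fold, standard error

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {
                "group": self.groups,
                "nf": self.nf,
                "rel": self.rel,
                "fold": self.fold,
            }
        ).rename_axis("sample").to_csv(path, sep="\t")


def normalization_factor(
    q: QuantityMatrix | pd.DataFrame, rgs: list[str]
) -> pd.Series:
    """Per-sample geometric mean of the selected reference genes' quantities."""
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    if not rgs:
        raise ValueError("reference gene set is empty")
    missing = set(rgs) - set(qdf.index)
    if missing:
        raise KeyError(f"reference genes not in matrix: {sorted(missing)}")
    nf = np.exp(np.log(qdf.loc[list(rgs)].to_numpy(dtype=float)).mean(axis=0))
    return pd.Series(nf, index=qdf.columns, name="nf")


def normalize_goi(goi_q: pd.Series, nf: pd.Series) -> pd.Series:
    """Divide the gene of interest's quantities by the per-sample NF."""
    if set(goi_q.index) != set(nf.index):
        raise ValueError("GOI quantities and NF cover different samples")
    return (goi_q / nf.loc[goi_q.index]).rename("rel")


def fold_change_vs_group(
    rel: pd.Series, groups: pd.Series, calibrator_group: str
) -> tuple[pd.Series, pd.DataFrame]:
    """Fold change of each sample vs the calibrator group's mean.

    fold[s] = rel[s] / mean(rel over calibrator samples); by construction
    the calibrator group's folds average exactly 1.  Returns the
    per-sample folds and a per-group summary (n, mean, standard error).
    """
    groups = groups.loc[rel.index]
    cal = rel[groups == calibrator_group]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no samples")
    fold = (rel / cal.mean()).rename("fold")
    summary = (
        fold.groupby(groups)
        .agg(n="size", mean="mean", se=lambda x: stats.sem(x) if len(x) > 1 else np.nan)
        .rename_axis("group")
    )
    return fold, summary


def quantify(
    q: QuantityMatrix | pd.DataFrame,
    goi: str,
    rgs: list[str],
    groups: pd.Series,
    calibrator_group: str,
) -> NormalizedExpression:
    """Full quantification of one gene of interest against a RG set."""
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    if goi in rgs:
        raise ValueError(f"gene of interest {goi!r} is in the reference set")
    if goi not in qdf.index:
        raise KeyError(f"gene of interest {goi!r} not in matrix")
    nf = normalization_factor(qdf, rgs)
    rel = normalize_goi(qdf.loc[goi], nf)
    fold, summary = fold_change_vs_group(rel, groups, calibrator_group)
    return NormalizedExpression(
        nf=nf,
        rel=rel,
        fold=fold,
        calibrator_group=calibrator_group,
        rg_set=list(rgs),
        groups=groups.loc[rel.index],
        group_summary=summary,
    )
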