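"""Statistical evaluation of normalized expression and the RG-reduction study.

Group comparisons follow the conventional qPCR reporting battery:
Shapiro-Wilk normality per group, one-way ANOVA across groups, Tukey HSD
all-pairs comparisons rendered as a compact letter display (groups
sharing a letter are not significantly different), and Dunnett's
two-tailed test against a control group rendered as asterisks
(* p < 0.05, ** p < 0.01).

The reduction study asks whether normalizing with fewer reference genes
than recommended changes the quantification or the statistical
interpretation of a gene of interest: normalization factors NF_n are
built for n = n_rec .. 2 along the consensus order, fold changes are
recomputed under each, and within every sample group the NF variants are
compared by ANOVA + Tukey on log2 folds while each variant's Dunnett
significance pattern is checked against the recommended one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .normalization import quantify
from .transform import QuantityMatrix

ALPHA_DEFAULT = 0.05


def significance_stars(p: float) -> str:
    """Figure-style marker: ** p<0.01, * p<0.05, empty otherwise."""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


# ---------------------------------------------------------------------------
# compact letter display


def compact_letter_display(
    pmatrix: pd.DataFrame, alpha: float = ALPHA_DEFAULT
) -> dict[str, str]:
    """Letters such that two groups share one iff they do not differ.

    Groups are nodes of a graph with an edge where the pairwise p-value
    is >= alpha; every maximal clique of that graph receives a letter.
    Any edge lies in some maximal clique and non-adjacent nodes never
    share one, so the display is exact, not merely heuristic.
    """
    groups = list(pmatrix.index)
    adj = {
        g: {
            h
            for h in groups
            if h != g and pmatrix.at[g, h] >= alpha
        }
        for g in groups
    }
    cliques = _maximal_cliques(groups, adj)
    # stable letter order: by first member in the given group order
    pos = {g: i for i, g in enumerate(groups)}
    cliques.sort(key=lambda c: (min(pos[g] for g in c), sorted(pos[g] for g in c)))
    letters = {g: "" for g in groups}
    for i, clique in enumerate(cliques):
        letter = chr(ord("a") + i) if i < 26 else f"z{i}"
        for g in sorted(clique, key=pos.get):
            letters[g] += letter
    return letters


def _maximal_cliques(nodes: list, adj: dict) -> list[set]:
    """Bron-Kerbosch without pivoting; group counts are tiny."""
    out: list[set] = []

    def bk(r: set, p: set, x: set) -> None:
        if not p and not x:
            out.append(r)
            return
        for v in list(p):
            bk(r | {v}, p & adj[v], x & adj[v])
            p = p - {v}
            x = x | {v}

    bk(set(), set(nodes), set())
    return out


# ---------------------------------------------------------------------------
# group testing battery


@dataclass
class GroupTestReport:
    shapiro: pd.DataFrame  # per group: w, p
    anova_f: float
    anova_p: float
    tukey_p: pd.DataFrame  # all-pairs adjusted p-values
    letters: dict[str, str]
    dunnett: pd.DataFrame  # per non-control group: statistic, p, stars
    control_group: str
    alpha: float = ALPHA_DEFAULT

    @property
    def dunnett_pattern(self) -> tuple[str, ...]:
        """Asterisk pattern vs control, in group order."""
        return tuple(self.dunnett["stars"])


def group_tests(
    values: pd.Series,
    groups: pd.Series,
    control_group: str,
    log2_transform: bool = True,
    alpha: float = ALPHA_DEFAULT,
) -> GroupTestReport:
    """Normality, ANOVA, Tukey HSD letters and Dunnett stars per group.

    ``values`` are per-sample normalized quantities (or folds); with
    ``log2_transform`` they are analysed on the log2 scale, on which
    ratio data are closer to normal.  The control group anchors the
    Dunnett comparisons.
    """
    groups = groups.loc[values.index]
    labels = list(dict.fromkeys(groups))
    if control_group not in labels:
        raise ValueError(f"control group {control_group!r} absent from data")
    x = np.log2(values.astype(float)) if log2_transform else values.astype(float)
    arrays = {g: x[groups == g].to_numpy() for g in labels}
    for g, arr in arrays.items():
        if len(arr) < 2:
            raise ValueError(f"group {g!r} has a single replicate")

    shapiro = pd.DataFrame(
        {
            g: dict(zip(("w", "p"), _safe_shapiro(arr)))
            for g, arr in arrays.items()
        }
    ).T.rename_axis("group")

    anova = stats.f_oneway(*arrays.values())

    tukey = stats.tukey_hsd(*arrays.values())
    tukey_p = pd.DataFrame(tukey.pvalue, index=labels, columns=labels)
    letters = compact_letter_display(tukey_p, alpha=alpha)

    treat = [g for g in labels if g != control_group]
    with np.errstate(divide="ignore", invalid="ignore"):
        # zero within-group variance (noise-free data) is legitimate input;
        # the resulting inf/nan statistics map to p=0 / "no call" downstream
        dres = stats.dunnett(
            *(arrays[g] for g in treat), control=arrays[control_group]
        )
    dunnett = pd.DataFrame(
        {
            "statistic": dres.statistic,
            "p": dres.pvalue,
            "stars": [significance_stars(p) for p in dres.pvalue],
        },
        index=pd.Index(treat, name="group"),
    )
    return GroupTestReport(
        shapiro=shapiro,
        anova_f=float(anova.statistic),
        anova_p=float(anova.pvalue),
        tukey_p=tukey_p,
        letters=letters,
        dunnett=dunnett,
        control_group=control_group,
        alpha=alpha,
    )


def _safe_shapiro(arr: np.ndarray) -> tuple[float, float]:
    if len(arr) < 3 or np.ptp(arr) == 0:
        return (np.nan, np.nan)
    w, p = stats.shapiro(arr)
    return (float(w), float(p))


# ---------------------------------------------------------------------------
# stepwise reduction study


@dataclass
class ReductionReport:
    levels: list[int]  # n values, n_rec first
    fold: pd.DataFrame  # levels x samples: fold change under NF_n
    quant_shift: pd.DataFrame  # group x level: Tukey p of level vs reference
    dunnett_pattern: dict[int, tuple[str, ...]]
    reports: dict[int, GroupTestReport] = field(repr=False, default=None)
    minimal_safe_n: int = 2
    n_rec: int = 2
    alpha: float = ALPHA_DEFAULT

    def level_safe(self, n: int) -> bool:
        return (
            bool((self.quant_shift[n] >= self.alpha).all())
            and self.dunnett_pattern[n] == self.dunnett_pattern[self.n_rec]
        )


def reduction_study(
    q: QuantityMatrix | pd.DataFrame,
    goi: str,
    consensus_order: list[str],
    n_rec: int,
    groups: pd.Series,
    control_group: str,
    alpha: float = ALPHA_DEFAULT,
) -> ReductionReport:
    """Stepwise reduction of the reference-gene set from n_rec down to 2.

    For each n the top-n consensus genes form NF_n and the GOI's fold
    changes vs the control group are recomputed.  Per sample group, log2
    folds are compared across NF variants (one-way ANOVA + Tukey); each
    variant's Dunnett star pattern is compared with the recommended one.
    ``minimal_safe_n`` is the smallest n reachable from n_rec by steps
    that neither shift quantification in any group nor alter the
    significance pattern.
    """
    qdf = q.q if isinstance(q, QuantityMatrix) else q
    if n_rec < 2:
        raise ValueError("n_rec must be >= 2")
    if len(consensus_order) < n_rec:
        raise ValueError("consensus order shorter than n_rec")
    if goi in consensus_order[:n_rec]:
        raise ValueError(f"gene of interest {goi!r} inside the RG set")

    levels = list(range(n_rec, 1, -1))
    folds = {}
    reports = {}
    for n in levels:
        rgs = consensus_order[:n]
        if goi in rgs:
            raise ValueError(f"gene of interest {goi!r} inside the RG set")
        ne = quantify(qdf, goi, rgs, groups, control_group)
        folds[n] = ne.fold
        reports[n] = group_tests(
            ne.fold, groups, control_group, log2_transform=True, alpha=alpha
        )
    fold = pd.DataFrame(folds).T.rename_axis("n")

    groups = groups.loc[fold.columns]
    labels = list(dict.fromkeys(groups))
    quant_shift = pd.DataFrame(1.0, index=pd.Index(labels, name="group"), columns=levels)
    if len(levels) > 1:
        log2fold = np.log2(fold)
        for g in labels:
            cols = groups.index[groups == g]
            arrays = [log2fold.loc[n, cols].to_numpy() for n in levels]
            if max(np.ptp(a) for a in arrays) < 1e-9:
                # within-variant spread at floating-point noise level (far
                # below any real qPCR signal): compare the level means
                # directly instead of feeding rounding error to Tukey
                ref = arrays[0].mean()
                for j, n in enumerate(levels):
                    same = np.isclose(arrays[j].mean(), ref, rtol=1e-9, atol=1e-9)
                    quant_shift.at[g, n] = 1.0 if same else 0.0
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                tk = stats.tukey_hsd(*arrays)
            for j, n in enumerate(levels):
                quant_shift.at[g, n] = float(tk.pvalue[0, j])  # vs reference n_rec

    patterns = {n: reports[n].dunnett_pattern for n in levels}
    report = ReductionReport(
        levels=levels,
        fold=fold,
        quant_shift=quant_shift,
        dunnett_pattern=patterns,
        reports=reports,
        n_rec=n_rec,
        alpha=alpha,
    )
    minimal = n_rec
    for n in levels[1:]:
        if report.level_safe(n):
            minimal = n
        else:
            break
    report.minimal_safe_n = minimal
    return report
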