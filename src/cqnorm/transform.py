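"""Efficiency correction and conversion of Cq values to relative quantities.

A reaction with per-cycle amplification efficiency E reaches threshold at
cycle Cq; the efficiency-corrected cycle CqE = Cq * log(E)/log(2) is the
equivalent cycle count under perfect doubling, so all downstream algebra
can work in exact log2 units.  Relative quantities are then
q = 2^(calibrator_cq - CqE), i.e. expression relative to a per-gene
calibrator (by default the most expressed sample of that gene, the geNorm
convention, so max q = 1 per gene).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EFFICIENCY_RANGE, CollapsedCqTable


@dataclass
class QuantityMatrix:
    """Relative quantities and the corrected Cq values they came from."""

    q: pd.DataFrame  # genes x samples, > 0
    cqe: pd.DataFrame  # genes x samples, efficiency-corrected Cq
    calibrator_cq: pd.Series  # per-gene reference CqE

    @property
    def genes(self) -> list[str]:
        return list(self.q.index)

    @property
    def samples(self) -> list[str]:
        return list(self.q.columns)

    def to_wide_tsv(self, path) -> None:
        self.q.rename_axis("gene").to_csv(path, sep="\t")


def efficiency_correct(cq, e):
    """Rescale Cq to perfect-doubling units: CqE = Cq * log2(E).

    Accepts scalars or arrays; ``e`` must lie in (1, 2.2].  At E = 2 this
    is the identity.
    """
    e = np.asarray(e, dtype=float)
    if np.any(e <= EFFICIENCY_RANGE[0]) or np.any(e > EFFICIENCY_RANGE[1]):
        raise ValueError(
            f"efficiency must be in ({EFFICIENCY_RANGE[0]}, "
            f"{EFFICIENCY_RANGE[1]}], got {e}"
        )
    return np.asarray(cq, dtype=float) * np.log2(e)


def efficiency_correct_table(
    table: CollapsedCqTable, efficiency: pd.Series
) -> CollapsedCqTable:
    """Apply per-gene efficiency correction to a collapsed Cq matrix."""
    missing = set(table.genes) - set(efficiency.index)
    if missing:
        raise KeyError(f"no efficiency for genes: {sorted(missing)}")
    eff = efficiency.loc[table.genes].astype(float)
    cqe = table.cq.mul(np.log2(eff.values), axis=0)
    if (eff <= EFFICIENCY_RANGE[0]).any() or (eff > EFFICIENCY_RANGE[1]).any():
        raise ValueError("efficiency outside admissible range")
    return CollapsedCqTable(
        cq=cqe,
        provenance=table.provenance + "; efficiency-corrected (CqE)",
        qc_warnings=list(table.qc_warnings),
    )


def to_relative_quantity(
    corrected: CollapsedCqTable,
    calibrator: pd.Series | dict | None = None,
) -> QuantityMatrix:
    """Convert a complete CqE matrix to relative quantities.

    q[g, s] = 2^(calibrator_cq[g] - CqE[g, s]).  The default calibrator is
    each gene's minimum CqE (its most expressed sample), so quantities are
    in (0, 1] with max 1.  A per-gene mapping of fixed calibrator CqE
    values may be supplied instead; all stability statistics downstream
    are invariant to this choice.
    """
    if not corrected.is_complete():
        raise ValueError(
            "matrix has missing cells; run validate_complete_matrix first"
        )
    cqe = corrected.cq.astype(float)
    if calibrator is None:
        cal = cqe.min(axis=1)
    else:
        cal = pd.Series(calibrator, dtype=float)
        missing = set(cqe.index) - set(cal.index)
        if missing:
            raise KeyError(f"no calibrator CqE for genes: {sorted(missing)}")
        cal = cal.loc[cqe.index]
    q = np.power(2.0, cal.values[:, None] - cqe.values)
    return QuantityMatrix(
        q=pd.DataFrame(q, index=cqe.index, columns=cqe.columns),
        cqe=cqe,
        calibrator_cq=cal,
    )
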