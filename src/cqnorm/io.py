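"""Data model and tabular I/O for Cq (quantitation cycle) experiments.

A qPCR experiment is represented as a long table of Cq measurements
(gene x sample x technical replicate), per-amplicon amplification
efficiencies, and per-sample metadata (group/stage, genotype, tissue,
biological replicate).  Readers accept the common TSV/CSV dialects and
the usual missing-value tokens emitted by thermocycler exports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("cqnorm")

#: Missing-value tokens accepted in Cq cells (case-insensitive).
MISSING_TOKENS = {"na", "nan", "n/a", "", "undetermined", "undet"}

#: Cq values outside this range trigger a QC warning (instrument ceilings vary).
CQ_RANGE = (0.0, 45.0)

#: Admissible per-cycle amplification efficiency; 2 = perfect doubling.
EFFICIENCY_RANGE = (1.0, 2.2)

LONG_COLUMNS = ["sample", "gene", "tech_rep", "cq"]
META_COLUMNS = ["sample", "group", "genotype", "tissue", "bio_rep"]


class CqParseError(ValueError):
    """Malformed input table (bad cell, duplicate key, missing column...)."""


@dataclass
class CqDataset:
    """Raw Cq measurements with replicate structure and annotations.

    Parameters
    ----------
    data
        Long table with columns ``sample, gene, tech_rep, cq``; ``cq`` may
        be NaN for explicitly missing reactions.
    efficiency
        Per-gene amplification efficiency ``E`` (1 < E <= 2.2), indexed by
        gene symbol.
    meta
        Per-sample metadata indexed by sample ID, with columns
        ``group, genotype, tissue, bio_rep``.
    """

    data: pd.DataFrame
    efficiency: pd.Series
    meta: pd.DataFrame
    qc_warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._validate()

    # -- structure ---------------------------------------------------------
    @property
    def genes(self) -> list[str]:
        return sorted(self.data["gene"].unique())

    @property
    def samples(self) -> list[str]:
        # preserve metadata order
        return [s for s in self.meta.index if s in set(self.data["sample"])]

    @property
    def groups(self) -> pd.Series:
        """sample -> group label, restricted to samples with measurements."""
        return self.meta.loc[self.samples, "group"]

    def _validate(self) -> None:
        missing_cols = set(LONG_COLUMNS) - set(self.data.columns)
        if missing_cols:
            raise CqParseError(f"Cq table lacks columns: {sorted(missing_cols)}")
        dup = self.data.duplicated(subset=["gene", "sample", "tech_rep"])
        if dup.any():
            key = self.data.loc[dup.idxmax(), ["gene", "sample", "tech_rep"]]
            raise CqParseError(
                f"duplicate measurement for (gene={key['gene']}, "
                f"sample={key['sample']}, tech_rep={key['tech_rep']})"
            )
        no_meta = set(self.data["sample"]) - set(self.meta.index)
        if no_meta:
            raise CqParseError(f"samples without metadata: {sorted(no_meta)}")
        no_eff = set(self.data["gene"]) - set(self.efficiency.index)
        if no_eff:
            raise CqParseError(f"genes without efficiency: {sorted(no_eff)}")
        eff = self.efficiency.astype(float)
        if (eff <= EFFICIENCY_RANGE[0]).any() or (eff > EFFICIENCY_RANGE[1]).any():
            bad = eff[(eff <= EFFICIENCY_RANGE[0]) | (eff > EFFICIENCY_RANGE[1])]
            raise CqParseError(
                f"efficiencies outside ({EFFICIENCY_RANGE[0]}, "
                f"{EFFICIENCY_RANGE[1]}]: {bad.to_dict()}"
            )
        over = eff[eff > 2.0]
        for g, e in over.items():
            self._warn(f"gene {g}: efficiency {e:.3f} > 2 (over-efficiency artifact?)")
        cq = self.data["cq"].dropna()
        if np.isinf(cq).any():
            raise CqParseError("non-finite Cq value")
        out = cq[(cq <= CQ_RANGE[0]) | (cq > CQ_RANGE[1])]
        for idx, v in out.items():
            row = self.data.loc[idx]
            self._warn(
                f"Cq {v} outside ({CQ_RANGE[0]}, {CQ_RANGE[1]}] for "
                f"(gene={row['gene']}, sample={row['sample']})"
            )

    def _warn(self, msg: str) -> None:
        self.qc_warnings.append(msg)
        logger.warning(msg)

    # -- export ------------------------------------------------------------
    def to_long_tsv(self, path) -> None:
        """Write the canonical long TSV (sample, gene, tech_rep, cq)."""
        self.data[LONG_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")

    def write_metadata_tsv(self, path) -> None:
        self.meta.reset_index(names="sample")[META_COLUMNS].to_csv(
            path, sep="\t", index=False
        )

    def write_efficiency_tsv(self, path) -> None:
        self.efficiency.rename("efficiency").rename_axis("gene").reset_index().to_csv(
            path, sep="\t", index=False
        )

    def to_json(self) -> str:
        """JSON dump of the dataset plus accumulated QC warnings."""
        payload = {
            "genes": self.genes,
            "samples": self.samples,
            "measurements": self.data[LONG_COLUMNS]
            .replace({np.nan: None})
            .to_dict(orient="records"),
            "efficiency": self.efficiency.to_dict(),
            "meta": self.meta.to_dict(orient="index"),
            "qc_warnings": list(self.qc_warnings),
        }
        return json.dumps(payload, indent=2)


@dataclass
class CollapsedCqTable:
    """Technical-replicate-averaged Cq matrix (genes x samples).

    Missing cells are NaN; ``mask`` reports presence.  ``provenance``
    records the collapse rule applied.
    """

    cq: pd.DataFrame
    provenance: str = "mean of technical replicates"
    qc_warnings: list[str] = field(default_factory=list)

    @property
    def mask(self) -> pd.DataFrame:
        return self.cq.notna()

    @property
    def genes(self) -> list[str]:
        return list(self.cq.index)

    @property
    def samples(self) -> list[str]:
        return list(self.cq.columns)

    def is_complete(self) -> bool:
        return bool(self.mask.values.all())


# ---------------------------------------------------------------------------
# parsing


def _read_table(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        # sniff delimiter (TSV vs CSV)
        return pd.read_csv(path, sep=None, engine="python", dtype=str)
    return pd.read_csv(path, sep=sep, dtype=str)


def _parse_cq_cell(raw, where: str) -> float:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return np.nan
    s = str(raw).strip()
    if s.lower() in MISSING_TOKENS:
        return np.nan
    try:
        return float(s)
    except ValueError:
        raise CqParseError(f"malformed Cq value {raw!r} at {where}") from None


def parse_cq_table(
    path,
    layout: str = "long",
    meta_path=None,
    efficiency_path=None,
    sep: str | None = None,
    default_efficiency: float | None = None,
) -> CqDataset:
    """Read a Cq table plus metadata and efficiencies into a :class:`CqDataset`.

    Parameters
    ----------
    path
        Cq table.  ``layout='long'`` expects columns
        ``sample, gene, tech_rep, cq``; ``layout='wide'`` expects genes as
        rows (first column ``gene``) and samples as columns, one value per
        cell (tech_rep is set to 1).
    meta_path
        Sample metadata TSV/CSV with columns
        ``sample, group, genotype, tissue, bio_rep``.  Required.
    efficiency_path
        Gene efficiency table with columns ``gene, efficiency``.  Genes
        absent from it fall back to ``default_efficiency`` if given,
        otherwise parsing fails.
    sep
        Field delimiter; sniffed when None.
    """
    if layout not in {"long", "wide"}:
        raise ValueError(f"unknown layout {layout!r}")
    if meta_path is None:
        raise CqParseError("sample metadata file is required")

    raw = _read_table(path, sep)
    if layout == "wide":
        if raw.columns[0] != "gene":
            raise CqParseError("wide layout requires first column 'gene'")
        raw = raw.melt(id_vars="gene", var_name="sample", value_name="cq")
        raw["tech_rep"] = 1
    missing_cols = set(LONG_COLUMNS) - set(raw.columns)
    if missing_cols:
        raise CqParseError(f"Cq table lacks columns: {sorted(missing_cols)}")

    cq = [
        _parse_cq_cell(v, f"row {i + 2}, column 'cq'")
        for i, v in enumerate(raw["cq"])
    ]
    data = pd.DataFrame(
        {
            "sample": raw["sample"].astype(str).str.strip(),
            "gene": raw["gene"].astype(str).str.strip(),
            "tech_rep": pd.to_numeric(raw["tech_rep"]).astype(int),
            "cq": cq,
        }
    )

    meta = _read_table(meta_path, sep)
    missing_cols = set(META_COLUMNS) - set(meta.columns)
    if missing_cols:
        raise CqParseError(f"metadata lacks columns: {sorted(missing_cols)}")
    meta = meta.set_index(meta["sample"].astype(str).str.strip())[META_COLUMNS[1:]]
    warnings: list[str] = []
    unknown = set(meta.index) - set(data["sample"])
    if unknown:
        msg = f"metadata for samples not in Cq table ignored: {sorted(unknown)}"
        warnings.append(msg)
        logger.warning(msg)

    genes = sorted(data["gene"].unique())
    if efficiency_path is not None:
        eff_tab = _read_table(efficiency_path, sep)
        if not {"gene", "efficiency"} <= set(eff_tab.columns):
            raise CqParseError("efficiency table needs columns gene, efficiency")
        eff = pd.Series(
            pd.to_numeric(eff_tab["efficiency"]).values,
            index=eff_tab["gene"].astype(str).str.strip(),
            name="efficiency",
            dtype=float,
        )
    else:
        eff = pd.Series(dtype=float, name="efficiency")
    absent = [g for g in genes if g not in eff.index]
    if absent:
        if default_efficiency is None:
            raise CqParseError(f"missing efficiency for genes: {absent}")
        eff = pd.concat([eff, pd.Series(default_efficiency, index=absent)])

    ds = CqDataset(
        data=data, efficiency=eff.loc[genes].astype(float), meta=meta,
        qc_warnings=warnings,
    )
    return ds


# ---------------------------------------------------------------------------
# replicate collapsing and completeness


def collapse_technical_replicates(
    ds: CqDataset, discordance_threshold: float = 0.5
) -> CollapsedCqTable:
    """Average technical replicates to one Cq per (gene, sample).

    Cells whose replicates are all missing stay missing.  Replicate
    disagreement beyond ``discordance_threshold`` cycles, and cells left
    with a single usable replicate, are logged as QC warnings — never
    errors, matching bench practice of inspecting rather than discarding.
    """
    warnings: list[str] = []
    grouped = ds.data.groupby(["gene", "sample"])["cq"]
    for (gene, sample), vals in grouped:
        present = vals.dropna()
        if len(vals) > 1 and len(present) == 1:
            warnings.append(f"({gene}, {sample}): single usable technical replicate")
        if len(present) >= 2:
            spread = present.max() - present.min()
            if spread > discordance_threshold:
                warnings.append(
                    f"({gene}, {sample}): technical replicates discordant "
                    f"(range {spread:.3g} > {discordance_threshold:g} cycles)"
                )
    wide = grouped.mean().unstack("sample")
    wide = wide.loc[ds.genes, ds.samples]
    for msg in warnings:
        logger.warning(msg)
    return CollapsedCqTable(cq=wide, qc_warnings=warnings)


def validate_complete_matrix(
    table: CollapsedCqTable,
    genes: list[str] | None = None,
    policy: str = "strict",
) -> CollapsedCqTable:
    """Restrict to ``genes`` and guarantee a complete matrix.

    ``policy='strict'`` raises on any missing cell, naming it;
    ``policy='drop-gene'`` silently drops genes with missing cells (the
    situation of a candidate gene not expressed in some genotypes).
    """
    if genes is None:
        genes = table.genes
    unknown = set(genes) - set(table.genes)
    if unknown:
        raise KeyError(f"genes not in table: {sorted(unknown)}")
    sub = table.cq.loc[list(genes)]
    if policy == "drop-gene":
        incomplete = sub.index[sub.isna().any(axis=1)]
        if len(incomplete):
            logger.warning(
                "dropping genes with missing cells: %s", list(incomplete)
            )
        sub = sub.drop(index=incomplete)
    elif policy == "strict":
        if sub.isna().values.any():
            cells = [
                (g, s)
                for g in sub.index
                for s in sub.columns
                if pd.isna(sub.at[g, s])
            ]
            raise ValueError(f"missing Cq cells: {cells}")
    else:
        raise ValueError(f"unknown policy {policy!r}")
    if sub.empty:
        raise ValueError("no genes left after completeness filtering")
    return CollapsedCqTable(
        cq=sub,
        provenance=table.provenance + f"; completeness policy={policy}",
        qc_warnings=list(table.qc_warnings),
    )
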