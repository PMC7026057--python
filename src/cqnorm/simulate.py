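"""Synthetic Cq data with known ground-truth stability structure.

The generator emulates a candidate reference-gene screen across staged
anther samples: latent log2 abundance per gene and sample is a gene
baseline plus a shared per-sample loading factor (RNA input / RT yield),
plus optional group-specific regulation and per-gene biological noise.
The efficiency model is the exact inverse of the CqE correction, so raw
Cq values correct back to the latent CqE to machine precision.

Unstable genes come in two flavors deliberately: high biological noise
(caught by every method) and a coordinated group-specific shift (the
co-regulation failure mode that pairwise methods are partially blind to
but a model-based method is not).

Defaults mirror the emulated study design: 12 candidates, Cq in the
20-30 cycle range, efficiencies 1.900-1.946, four meiotic stage groups
(PM, PRO, TT, IP) with 3 biological x 2 technical replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import CqDataset, CqParseError


def default_groups() -> dict[str, int]:
    return {"PM": 3, "PRO": 3, "TT": 3, "IP": 3}


@dataclass
class SimConfig:
    """Study-design parameters of the generator.

    All noise SDs are in cycles on the CqE (perfect-doubling) scale, so
    they are also log2-expression SDs.
    """

    k_stable: int = 9
    k_noise: int = 2  # unstable flavor 1: inflated biological noise
    k_shift: int = 1  # unstable flavor 2: group-specific regulation
    groups: dict[str, int] = field(default_factory=default_groups)
    tech_reps: int = 2
    mu_range: tuple[float, float] = (20.0, 30.0)  # baseline Cq, U(20, 30)
    tau: float = 0.5  # SD of the shared per-sample loading factor
    sigma_stable: float = 0.15
    sigma_unstable: float = 1.0
    shift_cycles: float = 1.5  # regulation amplitude of shifted genes
    shift_group: str = "TT"
    sigma_tech: float = 0.1  # technical replicate SD
    efficiency_range: tuple[float, float] = (1.900, 1.946)
    goi_profile: dict[str, float] | None = None  # group -> log2 fold vs baseline
    goi_sigma: float = 0.15
    seed: int = 0

    def validate(self) -> None:
        if min(self.tau, self.sigma_stable, self.sigma_unstable,
               self.sigma_tech, self.goi_sigma) < 0:
            raise ValueError("noise SDs must be non-negative")
        lo, hi = self.efficiency_range
        if not (1.0 < lo <= hi <= 2.2):
            raise ValueError("efficiency range must lie in (1, 2.2]")
        if self.k_shift and self.shift_group not in self.groups:
            raise ValueError(f"shift group {self.shift_group!r} not a group")
        if self.tech_reps < 1 or any(n < 1 for n in self.groups.values()):
            raise ValueError("need >= 1 replicate everywhere")

    @property
    def gene_names(self) -> list[str]:
        k = self.k_stable + self.k_noise + self.k_shift
        return [f"RG{i + 1:02d}" for i in range(k)]


@dataclass
class GroundTruth:
    """Generator parameters as drawn, for checking recovery."""

    mu: pd.Series  # baseline Cq per gene
    sigma: pd.Series  # biological noise SD per gene
    shift: pd.DataFrame  # gene x group regulation, cycles on the CqE scale
    lam: pd.Series  # per-sample loading factor
    efficiency: pd.Series
    true_stability_order: list[str]  # stable genes first
    cqe: pd.DataFrame  # realized latent CqE (before technical noise)

    @property
    def stable_genes(self) -> list[str]:
        instab = self.instability()
        return [g for g in self.mu.index if instab[g] == instab.min()]

    def instability(self) -> pd.Series:
        return self.shift.abs().sum(axis=1) + self.sigma

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "mu": self.mu.to_dict(),
                "sigma": self.sigma.to_dict(),
                "shift": self.shift.to_dict(orient="index"),
                "lambda": self.lam.to_dict(),
                "efficiency": self.efficiency.to_dict(),
                "true_stability_order": self.true_stability_order,
            },
            indent=2,
        )


def _sample_frame(cfg: SimConfig) -> pd.DataFrame:
    rows = []
    for group, n_bio in cfg.groups.items():
        for b in range(1, n_bio + 1):
            rows.append(
                {
                    "sample": f"{group}_{b}",
                    "group": group,
                    "genotype": "CS",
                    "tissue": "anther" if group not in {"L", "R"} else group,
                    "bio_rep": b,
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_cq_dataset(cfg: SimConfig) -> tuple[CqDataset, GroundTruth]:
    """Draw a full candidate-gene Cq dataset plus its ground truth.

    Latent CqE[g, s] = mu_g + lambda_s + shift[g, group(s)] + b[g, s]
    with b ~ N(0, sigma_g^2) and lambda ~ N(0, tau^2) shared by all
    genes of a sample; raw Cq = CqE * log(2)/log(E_g); each technical
    replicate adds N(0, sigma_tech^2).  Deterministic given cfg.seed
    (draw order: mu, efficiency, lambda, biological noise, technical
    noise, gene by gene).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.gene_names
    meta = _sample_frame(cfg)
    samples = list(meta.index)
    group_of = meta["group"]

    mu = pd.Series(rng.uniform(*cfg.mu_range, size=len(genes)), index=genes)
    eff = pd.Series(
        rng.uniform(*cfg.efficiency_range, size=len(genes)), index=genes,
        name="efficiency",
    )
    lam = pd.Series(rng.normal(0.0, cfg.tau, size=len(samples)), index=samples)

    sigma = pd.Series(cfg.sigma_stable, index=genes)
    shift = pd.DataFrame(0.0, index=genes, columns=list(cfg.groups))
    noisy = genes[cfg.k_stable : cfg.k_stable + cfg.k_noise]
    shifted = genes[cfg.k_stable + cfg.k_noise :]
    sigma[noisy] = cfg.sigma_unstable
    for g in shifted:
        shift.at[g, cfg.shift_group] = cfg.shift_cycles

    b = rng.normal(0.0, 1.0, size=(len(genes), len(samples))) * sigma.values[:, None]
    cqe = (
        mu.values[:, None]
        + lam.values[None, :]
        + shift.loc[:, group_of].to_numpy()
        + b
    )
    cqe_df = pd.DataFrame(cqe, index=genes, columns=samples)

    raw = cqe / np.log2(eff.values)[:, None]
    tech = rng.normal(
        0.0, cfg.sigma_tech, size=(len(genes), len(samples), cfg.tech_reps)
    )
    records = []
    for i, g in enumerate(genes):
        for j, s in enumerate(samples):
            for r in range(cfg.tech_reps):
                records.append(
                    {
                        "sample": s,
                        "gene": g,
                        "tech_rep": r + 1,
                        "cq": raw[i, j] + tech[i, j, r],
                    }
                )
    data = pd.DataFrame(records)

    instab = shift.abs().sum(axis=1) + sigma
    order = sorted(genes, key=lambda g: (instab[g], g))
    truth = GroundTruth(
        mu=mu,
        sigma=sigma,
        shift=shift,
        lam=lam,
        efficiency=eff,
        true_stability_order=order,
        cqe=cqe_df,
    )
    ds = CqDataset(data=data, efficiency=eff, meta=meta)
    return ds, truth


GOI_NAME = "GOI"


def simulate_goi(
    cfg: SimConfig, truth: GroundTruth
) -> tuple[pd.DataFrame, float]:
    """Draw a gene of interest sharing the dataset's loading factors.

    The GOI's latent CqE is its own baseline plus the same per-sample
    lambda, minus the per-group log2 fold profile (a fold of 0.5 raises
    CqE by one cycle).  Returns long-format rows (sample, gene, tech_rep,
    cq) and the GOI's amplicon efficiency.  Deterministic given cfg.seed
    (independent stream, so adding the GOI never perturbs the RG draw).
    """
    if cfg.goi_profile is None:
        raise CqParseError("cfg.goi_profile is not set")
    missing = set(g for g in cfg.groups) - set(cfg.goi_profile)
    if missing:
        raise ValueError(f"goi_profile lacks groups: {sorted(missing)}")
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 7]))
    samples = list(truth.lam.index)
    group_of = pd.Series(
        {s: s.rsplit("_", 1)[0] for s in samples}
    )

    mu = rng.uniform(*cfg.mu_range)
    eff = rng.uniform(*cfg.efficiency_range)
    profile = pd.Series(cfg.goi_profile)
    b = rng.normal(0.0, cfg.goi_sigma, size=len(samples))
    cqe = (
        mu
        + truth.lam.values
        - profile.loc[group_of.loc[samples]].values
        + b
    )
    raw = cqe / np.log2(eff)
    tech = rng.normal(0.0, cfg.sigma_tech, size=(len(samples), cfg.tech_reps))
    records = [
        {
            "sample": s,
            "gene": GOI_NAME,
            "tech_rep": r + 1,
            "cq": raw[j] + tech[j, r],
        }
        for j, s in enumerate(samples)
        for r in range(cfg.tech_reps)
    ]
    return pd.DataFrame(records), float(eff)


def simulate_experiment(cfg: SimConfig) -> tuple[CqDataset, GroundTruth]:
    """Candidate RGs plus the GOI (if a profile is configured) in one dataset."""
    ds, truth = simulate_cq_dataset(cfg)
    if cfg.goi_profile is None:
        return ds, truth
    goi_rows, goi_eff = simulate_goi(cfg, truth)
    data = pd.concat([ds.data, goi_rows], ignore_index=True)
    eff = pd.concat([ds.efficiency, pd.Series({GOI_NAME: goi_eff})])
    merged = CqDataset(data=data, efficiency=eff, meta=ds.meta)
    return merged, truth
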