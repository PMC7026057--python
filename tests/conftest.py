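import numpy as np
import pandas as pd
import pytest

from cqnorm.io import CqDataset


@pytest.fixture
def micro_cq() -> pd.DataFrame:
    """3-gene x 4-sample Cq matrix with G1/G2 perfectly co-varying and G3 jittered."""
    return pd.DataFrame(
        {
            "S1": [20.0, 25.0, 20.0],
            "S2": [21.0, 26.0, 22.0],
            "S3": [22.0, 27.0, 21.0],
            "S4": [23.0, 28.0, 23.0],
        },
        index=["G1", "G2", "G3"],
    )


def make_dataset(
    cq_wide: pd.DataFrame,
    groups: dict[str, str] | None = None,
    efficiency: float | pd.Series = 2.0,
) -> CqDataset:
    """Wrap a genes x samples Cq matrix into a CqDataset (1 tech rep)."""
    records = [
        {"sample": s, "gene": g, "tech_rep": 1, "cq": cq_wide.at[g, s]}
        for g in cq_wide.index
        for s in cq_wide.columns
    ]
    samples = list(cq_wide.columns)
    if groups is None:
        groups = {s: "all" for s in samples}
    meta = pd.DataFrame(
        {
            "group": [groups[s] for s in samples],
            "genotype": "CS",
            "tissue": "anther",
            "bio_rep": range(1, len(samples) + 1),
        },
        index=pd.Index(samples, name="sample"),
    )
    if np.isscalar(efficiency):
        efficiency = pd.Series(float(efficiency), index=cq_wide.index)
    return CqDataset(
        data=pd.DataFrame(records), efficiency=efficiency, meta=meta
    )


def rand_cqe(n_genes=5, n_samples=8, seed=0) -> pd.DataFrame:
    """Random complete CqE matrix (plain helper, usable inside hypothesis)."""
    rng = np.random.default_rng(seed)
    vals = rng.uniform(18, 32, size=(n_genes, n_samples))
    return pd.DataFrame(
        vals,
        index=[f"G{i}" for i in range(n_genes)],
        columns=[f"S{j}" for j in range(n_samples)],
    )


@pytest.fixture
def random_cqe():
    """Factory for random complete CqE matrices."""
    return rand_cqe
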