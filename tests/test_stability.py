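"""The four stability algorithms: frozen examples, oracles and invariances."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cqnorm.io import CollapsedCqTable
from cqnorm.stability import (
    bestkeeper,
    delta_ct,
    genorm,
    genorm_pairwise_variation,
    normfinder,
)
from cqnorm.transform import to_relative_quantity


def quantities(cqe: pd.DataFrame):
    return to_relative_quantity(CollapsedCqTable(cq=cqe))


# ---------------------------------------------------------------------------
# geNorm


class TestGeNorm:
    def test_micro_example_m_values(self, micro_cq):
        res = genorm(quantities(micro_cq))
        # sample SD of delta-Cq (0,-1,1,0) = sqrt(2/3); M1 = M2 = half of it
        assert res.m["G1"] == pytest.approx(0.408248, abs=1e-4)
        assert res.m["G2"] == pytest.approx(0.408248, abs=1e-4)
        assert res.m["G3"] == pytest.approx(0.816497, abs=1e-4)
        assert res.removal_order[0] == "G3"
        assert res.ranking["G3"] == 3

    def test_covarying_pair_has_zero_pairwise_sd(self, micro_cq):
        res = genorm(quantities(micro_cq))
        assert res.pairwise_sd.at["G1", "G2"] == pytest.approx(0.0, abs=1e-12)

    def test_identical_genes_all_zero_m(self):
        cqe = pd.DataFrame(
            [[20.0, 21.0, 23.0]] * 4, index=["G4", "G3", "G2", "G1"],
            columns=["S1", "S2", "S3"],
        )
        res = genorm(quantities(cqe))
        assert np.allclose(res.m, 0.0)
        # deterministic lexicographic tie-break: worst-sorted gene removed first
        assert res.removal_order == ["G4", "G3", "G2", "G1"]

    def test_needs_three_genes(self, micro_cq):
        with pytest.raises(ValueError, match="3 candidate genes"):
            genorm(quantities(micro_cq.iloc[:2]))

    def test_positive_quantities_required(self, micro_cq):
        q = quantities(micro_cq).q.copy()
        q.iloc[0, 0] = -1.0
        with pytest.raises(ValueError, match="positive"):
            genorm(q)

    def test_scale_invariance(self, random_cqe):
        """Multiplying one gene's quantities by a constant leaves M unchanged."""
        q = quantities(random_cqe(5, 8, seed=11)).q
        scaled = q.copy()
        scaled.loc["G2"] *= 37.5
        a, b = genorm(q), genorm(scaled)
        assert np.allclose(a.m, b.m, atol=1e-9)
        assert a.removal_order == b.removal_order

    def test_sample_order_invariance(self, random_cqe):
        q = quantities(random_cqe(5, 8, seed=12)).q
        shuffled = q[list(q.columns[::-1])]
        assert np.allclose(genorm(q).m, genorm(shuffled).m, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_elimination_matches_brute_force(self, random_cqe, seed):
        """Independent two-loop re-implementation agrees on removal order."""
        q = quantities(random_cqe(6, 9, seed=seed)).q
        res = genorm(q)
        assert res.removal_order[:-2] == brute_force_removal(q)[: len(q) - 2]


def brute_force_removal(q: pd.DataFrame) -> list[str]:
    """Oracle: recompute every pairwise SD from scratch at each elimination."""
    removed = []
    genes = list(q.index)
    while len(genes) > 2:
        m = {}
        for g in genes:
            sds = []
            for h in genes:
                if h == g:
                    continue
                ratios = [
                    np.log2(q.at[g, s] / q.at[h, s]) for s in q.columns
                ]
                sds.append(np.std(ratios, ddof=1))
            m[g] = np.mean(sds)
        worst = max(sorted(genes), key=lambda g: (m[g], g))
        removed.append(worst)
        genes.remove(worst)
    return removed


# ---------------------------------------------------------------------------
# pairwise variation


class TestPairwiseVariation:
    def test_identical_genes_give_zero_v(self):
        cqe = pd.DataFrame(
            [[20.0, 21.0, 23.0, 24.0]] * 4,
            index=list("ABCD"), columns=["S1", "S2", "S3", "S4"],
        )
        series = genorm_pairwise_variation(quantities(cqe), list("ABCD"))
        assert np.allclose(series.v, 0.0, atol=1e-12)

    def test_duplicated_top_gene_value(self, micro_cq):
        """With gene3 a duplicate of gene1, V_2/3 = SD(log2 q1/q2)/6."""
        cqe = pd.DataFrame(
            {
                "A": micro_cq.loc["G1"],
                "B": micro_cq.loc["G3"],
                "C": micro_cq.loc["G1"],
            }
        ).T
        series = genorm_pairwise_variation(quantities(cqe), ["A", "B", "C"])
        assert series.v[2] == pytest.approx(0.816497 / 6, abs=1e-4)

    def test_order_permutation_within_top_n_keeps_nf(self, random_cqe):
        qm = quantities(random_cqe(5, 8, seed=4))
        genes = list(qm.q.index)
        a = genorm_pairwise_variation(qm, genes)
        b = genorm_pairwise_variation(qm, genes[2::-1] + genes[3:])
        pd.testing.assert_series_equal(
            a.nf.loc[3], b.nf.loc[3], atol=1e-12, check_names=False
        )

    def test_requires_three_genes(self, random_cqe):
        qm = quantities(random_cqe(5, 8, seed=5))
        with pytest.raises(ValueError, match="n_max >= 3"):
            genorm_pairwise_variation(qm, list(qm.q.index), n_max=2)


# ---------------------------------------------------------------------------
# NormFinder


class TestNormFinder:
    def test_noise_free_data_has_zero_rho(self):
        # per-gene offsets plus a shared per-sample effect: centering removes all
        mu = np.array([20.0, 24.0, 28.0, 22.0])[:, None]
        lam = np.array([0.3, -0.2, 0.5, 0.0, -0.6])[None, :]
        y = pd.DataFrame(-(mu + lam), index=list("ABCD"), columns=[f"S{i}" for i in range(5)])
        res = normfinder(y)
        assert np.allclose(res.rho, 0.0, atol=1e-12)
        assert np.allclose(res.s2, 0.0, atol=1e-12)

    def test_gene_centering_sums_to_zero(self, random_cqe):
        y = -random_cqe(6, 10, seed=21)
        groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=y.columns)
        res = normfinder(y, groups)
        assert np.allclose(res.d_bar.sum(axis=0), 0.0, atol=1e-9)

    def test_single_group_noisy_gene_ranks_worst(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            k, n = 6, 50
            y = rng.normal(0, 0.1, size=(k, n))
            y[0] = rng.normal(0, 1.0, size=n)
            res = normfinder(pd.DataFrame(y, index=[f"G{i}" for i in range(k)]))
            hits += res.rho.idxmax() == "G0"
        assert hits >= 57  # >= 95%

    def test_group_shifted_gene_ranks_last(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            k, n_g = 5, 20
            y = rng.normal(0, 0.1, size=(k, 2 * n_g))
            y[2, n_g:] += 2.0  # regulated in group 2 only
            cols = [f"S{i}" for i in range(2 * n_g)]
            groups = pd.Series(["a"] * n_g + ["b"] * n_g, index=cols)
            res = normfinder(pd.DataFrame(y, index=[f"G{i}" for i in range(k)], columns=cols), groups)
            hits += res.rho.idxmax() == "G2"
        assert hits >= 57

    def test_invariant_to_per_gene_offsets(self, random_cqe):
        """rho is identical for y = -CqE and y = log2 q with any calibrator."""
        cqe = random_cqe(5, 12, seed=33)
        groups = pd.Series(["a"] * 6 + ["b"] * 6, index=cqe.columns)
        rng = np.random.default_rng(0)
        cal = cqe.min(axis=1) + rng.uniform(-3, 3, size=5)
        qm = to_relative_quantity(CollapsedCqTable(cq=cqe), calibrator=cal.to_dict())
        a = normfinder(-cqe, groups)
        b = normfinder(np.log2(qm.q), groups)
        assert np.allclose(a.rho, b.rho, atol=1e-9)
        assert a.gamma2_hat == pytest.approx(b.gamma2_hat, abs=1e-9)

    def test_too_few_genes_or_singleton_group(self, random_cqe):
        y = -random_cqe(2, 6, seed=1)
        with pytest.raises(ValueError, match=">= 3 genes"):
            normfinder(y)
        y = -random_cqe(4, 3, seed=1)
        groups = pd.Series(["a", "a", "b"], index=y.columns)
        with pytest.raises(ValueError, match="need >= 2"):
            normfinder(y, groups)


# ---------------------------------------------------------------------------
# BestKeeper


class TestBestKeeper:
    def test_micro_example(self, micro_cq):
        res = bestkeeper(CollapsedCqTable(cq=micro_cq))
        assert res.stats.at["G1", "sd_cq"] == pytest.approx(1.0, abs=1e-4)
        assert res.stats.at["G1", "cv_pct"] == pytest.approx(4.651, abs=1e-3)
        assert res.index["S1"] == pytest.approx(21.544, abs=1e-3)

    def test_descriptives_bracket(self, random_cqe):
        res = bestkeeper(CollapsedCqTable(cq=random_cqe(6, 10, seed=8)))
        s = res.stats
        assert (s["min"] <= s["geo_mean"]).all() and (s["geo_mean"] <= s["max"]).all()
        assert (s["min"] <= s["arith_mean"]).all() and (s["arith_mean"] <= s["max"]).all()
        assert (s["sd_cq"] >= 0).all()
        assert (s["r"].abs() <= 1).all()

    def test_affine_gene_correlates_perfectly(self, random_cqe):
        cq = random_cqe(4, 8, seed=9)
        # replace one gene by an affine image of the index of the others;
        # Pearson r vs the final index stays 1 only if the gene tracks it,
        # so build the gene directly from the other genes' geometric mean
        idx = np.exp(np.log(cq.iloc[1:]).mean(axis=0))
        cq.iloc[0] = 2.0 + idx  # additive constant on a monotone image
        res = bestkeeper(CollapsedCqTable(cq=cq))
        assert res.stats.iloc[0]["r"] > 0.99

    def test_constant_gene_flagged_not_error(self, micro_cq):
        cq = micro_cq.copy()
        cq.loc["G1"] = 24.0
        res = bestkeeper(CollapsedCqTable(cq=cq))
        assert np.isnan(res.stats.at["G1", "r"])
        assert any("zero variance" in w for w in res.qc_warnings)
        assert res.stats.at["G1", "sd_cq"] == 0.0

    def test_high_dispersion_flagged_inconsistent(self, micro_cq):
        cq = micro_cq.copy()
        cq.loc["G1"] = [18.0, 30.0, 18.0, 30.0]
        res = bestkeeper(CollapsedCqTable(cq=cq))
        assert bool(res.stats.at["G1", "inconsistent"])

    def test_needs_three_samples(self, micro_cq):
        with pytest.raises(ValueError, match=">= 2 genes and >= 3 samples"):
            bestkeeper(CollapsedCqTable(cq=micro_cq.iloc[:, :2]))


# ---------------------------------------------------------------------------
# comparative delta-Ct


class TestDeltaCt:
    def test_micro_example(self, micro_cq):
        res = delta_ct(CollapsedCqTable(cq=micro_cq))
        assert res.score["G1"] == pytest.approx(0.408248, abs=1e-4)
        assert res.score["G2"] == pytest.approx(0.408248, abs=1e-4)
        assert res.score["G3"] == pytest.approx(0.816497, abs=1e-4)

    def test_shift_invariance(self, random_cqe):
        cq = random_cqe(5, 8, seed=10)
        shifted = cq.copy()
        shifted.loc["G1"] += 7.5
        assert np.allclose(delta_ct(cq).score, delta_ct(shifted).score, atol=1e-9)

    def test_identical_pair_scores_zero(self):
        cq = pd.DataFrame(
            [[20.0, 22.0, 21.0]] * 2, index=["G1", "G2"], columns=["S1", "S2", "S3"]
        )
        res = delta_ct(cq)
        assert np.allclose(res.score, 0.0, atol=1e-12)

    def test_pair_sd_symmetric_zero_diagonal(self, random_cqe):
        res = delta_ct(random_cqe(5, 8, seed=13))
        assert np.allclose(res.pair_sd, res.pair_sd.T, atol=1e-12)
        assert np.allclose(np.diag(res.pair_sd), 0.0)


# ---------------------------------------------------------------------------
# cross-method oracle


@settings(deadline=None, max_examples=30)
@given(seed=st.integers(0, 10_000))
def test_delta_ct_equals_full_set_genorm_m(seed):
    """SD algebra oracle: delta-Ct on CqE == full-set geNorm M from quantities."""
    from conftest import rand_cqe

    cqe = rand_cqe(5, 8, seed=seed)
    m = genorm(quantities(cqe)).m
    score = delta_ct(cqe).score
    assert np.allclose(m, score, atol=1e-9)
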