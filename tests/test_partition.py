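"""PCA, nested AMOVA with Phi statistics, Weir's theta."""

import numpy as np
import pytest

from clonepop import (
    allele_frequencies,
    amova,
    amova_table,
    population_pca,
    theta_weir,
)
from clonepop.simulate import SimConfig, simulate_structured

from conftest import make_matrix


class TestPca:
    def test_identical_populations_share_coordinates(self):
        rows = ([[0, 1]] * 4 + [[0, 1]] * 4 + [[1, 0]] * 4)
        pops = ["pa"] * 4 + ["pb"] * 4 + ["pc"] * 4
        res = population_pca(allele_frequencies(make_matrix(rows, pops)))
        np.testing.assert_allclose(res.coordinates[0], res.coordinates[1],
                                   atol=1e-12)

    def test_collinear_gradient_loads_on_pc1(self):
        # 4 populations on a 1-D frequency gradient at every locus
        rows, pops = [], []
        grads = [0, 1, 2, 3]
        for k, gshift in enumerate(grads):
            pop = f"p{k}"
            ones = gshift  # 0..3 of 4 isolates carry allele 1
            for i in range(4):
                rows.append([1 if i < ones else 0] * 3)
                pops.append(pop)
        res = population_pca(allele_frequencies(make_matrix(rows, pops)))
        assert res.percent_variance[0] == pytest.approx(100.0, abs=1e-8)

    def test_variances_match_eigensolver_oracle(self, rng):
        alleles = rng.integers(0, 2, size=(60, 10))
        pops = [f"p{i // 10}" for i in range(60)]
        freqs = allele_frequencies(make_matrix(alleles.tolist(), pops))
        res = population_pca(freqs)
        # independent oracle: sklearn PCA on the same feature matrix
        from sklearn.decomposition import PCA

        X = np.array([[freqs.freqs[g][j][1] for j in range(10)]
                      for g in freqs.groups])
        sk = PCA().fit(X)
        np.testing.assert_allclose(
            res.percent_variance,
            100 * sk.explained_variance_ratio_[: len(res.percent_variance)],
            atol=1e-8,
        )

    def test_rank_zero_rejected(self):
        g = make_matrix([[0]] * 9, [f"p{i // 3}" for i in range(9)])
        with pytest.raises(ValueError):
            population_pca(allele_frequencies(g))


class TestAmovaTable:
    def test_ms_and_percent_from_published_columns(self):
        # nested AMOVA summary: df (5, 4, 133), SS (47.325, 51.975, 326.588),
        # Est.Var (0.000, 0.770, 2.456) must reproduce the printed MS / %var
        tab = amova_table(
            df=[5, 4, 133],
            ss=[47.325, 51.975, 326.588],
            est_var=[0.000, 0.770, 2.456],
        )
        np.testing.assert_allclose(tab.MS.round(3), [9.465, 12.994, 2.456])
        np.testing.assert_allclose(tab.percent.round(0), [0, 24, 76])
        assert tab.percent.sum() == pytest.approx(100.0)


def _balanced_amova_oracle(alleles, pops, regions):
    """Direct nested-ANOVA algebra on one-hot embeddings (balanced only)."""
    pops = np.asarray(pops)
    regions = np.asarray(regions)
    # embed so squared Euclidean distance equals mismatch count
    cols = []
    for j in range(alleles.shape[1]):
        codes = np.unique(alleles[:, j])
        onehot = (alleles[:, j][:, None] == codes[None, :]) / np.sqrt(2)
        cols.append(onehot)
    X = np.hstack(cols)
    grand = X.mean(axis=0)
    pop_labels = list(dict.fromkeys(pops))
    reg_labels = list(dict.fromkeys(regions))
    n_pop = {p: np.sum(pops == p) for p in pop_labels}
    reg_of_pop = {p: regions[pops == p][0] for p in pop_labels}
    ss_wp = sum(
        np.sum((X[pops == p] - X[pops == p].mean(axis=0)) ** 2)
        for p in pop_labels
    )
    ss_ap = sum(
        n_pop[p] * np.sum(
            (X[pops == p].mean(axis=0) - X[regions == reg_of_pop[p]].mean(axis=0))
            ** 2)
        for p in pop_labels
    )
    ss_ar = sum(
        np.sum(regions == r) * np.sum((X[regions == r].mean(axis=0) - grand) ** 2)
        for r in reg_labels
    )
    n = len(pops)
    R, P = len(reg_labels), len(pop_labels)
    df = np.array([R - 1, P - R, n - P], float)
    ms = np.array([ss_ar, ss_ap, ss_wp]) / df
    n_per_pop = n // P  # balanced
    pops_per_reg = P // R
    sigma_c = ms[2]
    sigma_b = (ms[1] - sigma_c) / n_per_pop
    sigma_a = (ms[0] - sigma_c - n_per_pop * sigma_b) / (n_per_pop * pops_per_reg)
    return np.array([ss_ar, ss_ap, ss_wp]), np.array([sigma_a, sigma_b, sigma_c])


class TestAmova:
    def test_identical_individuals_all_zero(self):
        g = make_matrix([[0, 1]] * 12,
                        [f"p{i // 3}" for i in range(12)],
                        ["r0"] * 6 + ["r1"] * 6)
        res = amova(g, n_perm=19, seed=0)
        np.testing.assert_allclose(res.table.SS, 0.0)
        np.testing.assert_allclose(res.table.est_var, 0.0)

    def test_balanced_toy_matches_algebraic_oracle(self, rng):
        # 2 regions x 2 populations x 4 individuals, 5 loci
        alleles = rng.integers(0, 2, size=(16, 5))
        pops = [f"p{i // 4}" for i in range(16)]
        regions = ["r0"] * 8 + ["r1"] * 8
        g = make_matrix(alleles.tolist(), pops, regions)
        res = amova(g, n_perm=19, seed=1)
        ss_o, comp_o = _balanced_amova_oracle(alleles, pops, regions)
        np.testing.assert_allclose(res.table.SS, ss_o, atol=1e-9)
        np.testing.assert_allclose(res.table.est_var, comp_o, atol=1e-9)

    def test_df_ss_consistency_invariants(self, rng):
        g = simulate_structured(SimConfig(
            n_regions=3, pops_per_region=(2, 2, 1), n_per_pop=(8, 6, 9, 5, 7),
            seed=5))
        res = amova(g, n_perm=19, seed=2)
        assert res.table.df.sum() == g.n_samples - 1
        np.testing.assert_allclose(res.table.MS, res.table.SS / res.table.df)
        assert res.table.percent.sum() == pytest.approx(100.0)

    def test_strong_structure_detected(self):
        rows = [[0] * 6] * 8 + [[1] * 6] * 8
        pops = ["p0"] * 4 + ["p1"] * 4 + ["p2"] * 4 + ["p3"] * 4
        regions = ["r0"] * 8 + ["r1"] * 8
        g = make_matrix(rows, pops, regions)
        res = amova(g, n_perm=99, seed=3)
        assert res.phi["PhiRT"] > 0.9
        # individual-level permutation has real resolution; the region-level
        # null has only 3 distinct relabelings so its P is bounded near 1/3
        assert res.phi_p["PhiPT"] <= 0.05
        assert res.phi_p["PhiRT"] <= 0.5


class TestTheta:
    def test_identical_balanced_groups_nonpositive(self):
        rows = [[0, 1], [1, 0], [0, 0], [1, 1]] * 4
        pops = ["pa", "pa", "pb", "pb"] * 4
        res = theta_weir(make_matrix(rows, pops), n_perm=19, seed=0)
        assert res.theta <= 0.0

    def test_fixed_differences_give_one(self):
        g = make_matrix([[0, 0]] * 10 + [[1, 1]] * 10,
                        ["pa"] * 10 + ["pb"] * 10)
        res = theta_weir(g, n_perm=19, seed=0)
        assert res.theta == pytest.approx(1.0)

    def test_scalar_arithmetic_oracle(self):
        # two groups, one biallelic locus, n = (10, 10), p = (0.9, 0.1)
        rows = [[0]] * 9 + [[1]] + [[0]] + [[1]] * 9
        pops = ["pa"] * 10 + ["pb"] * 10
        res = theta_weir(make_matrix(rows, pops), n_perm=19, seed=0)
        msp = (10 * 0.16 + 10 * 0.16) / 1          # per allele
        msg = (10 * 0.09 + 10 * 0.09) / 18
        n_c = (20 - 200 / 20) / 1
        expect = (2 * (msp - msg)) / (2 * (msp + (n_c - 1) * msg))
        assert res.theta == pytest.approx(expect, abs=1e-12)

    def test_monomorphic_locus_excluded(self):
        rows = [[0, 0]] * 5 + [[1, 0]] * 5
        res = theta_weir(make_matrix(rows, ["pa"] * 5 + ["pb"] * 5),
                         n_perm=19, seed=0)
        assert np.isnan(res.per_locus.theta.iloc[1])
        assert res.theta == pytest.approx(1.0)

    def test_permutation_preserves_group_sizes(self):
        g = make_matrix([[0], [0], [0], [1], [1], [1], [1], [1]],
                        ["pa"] * 3 + ["pb"] * 5)
        res = theta_weir(g, n_perm=49, seed=7)
        assert res.permutation.n_permutations == 49
        assert 0 < res.permutation.p_value <= 1
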