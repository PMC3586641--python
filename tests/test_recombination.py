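"""I_A / rBarD, pairwise LD, and phylogenetic compatibility."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonepop import (
    compatibility_summary,
    index_of_association,
    pair_compatibility,
    pairwise_ld,
)
from clonepop.simulate import simulate_panmictic

from conftest import make_matrix


def brute_force_ia(alleles):
    """Independent double-loop computation of V_O, V_E, I_A, rBarD."""
    n, L = alleles.shape
    ds = []
    for a in range(n):
        for b in range(a + 1, n):
            ds.append([int(alleles[a, j] != alleles[b, j]) for j in range(L)])
    ds = np.array(ds, float)
    var_j = [np.mean(ds[:, j] ** 2) - np.mean(ds[:, j]) ** 2 for j in range(L)]
    D = ds.sum(axis=1)
    v_o = np.mean(D**2) - np.mean(D) ** 2
    v_e = sum(var_j)
    denom = 2 * sum(
        np.sqrt(var_j[j] * var_j[k])
        for j in range(L) for k in range(j + 1, L)
    )
    return v_o, v_e, v_o / v_e - 1, (v_o - v_e) / denom


class TestIndexOfAssociation:
    def test_perfect_association(self):
        g = make_matrix([[0] * 5, [1] * 5] * 3)
        res = index_of_association(g, n_perm=49, seed=0)
        assert res.rbard == pytest.approx(1.0)
        assert res.ia == pytest.approx(4.0)  # L - 1

    def test_complete_two_locus_design(self):
        # the single 4-genotype block: exact value from the pair algebra
        g1 = make_matrix([[0, 0], [0, 1], [1, 0], [1, 1]])
        res1 = index_of_association(g1, n_perm=49, seed=0)
        assert res1.ia == pytest.approx(brute_force_ia(g1.alleles)[2])
        assert res1.ia == pytest.approx(-0.5)
        # replicated, the without-replacement bias vanishes: I_A -> 0
        g50 = make_matrix([[0, 0], [0, 1], [1, 0], [1, 1]] * 50)
        assert abs(index_of_association(g50, n_perm=0, seed=0).ia) < 0.02

    def test_matches_brute_force_oracle(self, rng):
        alleles = rng.integers(0, 3, size=(12, 6))
        g = make_matrix(alleles.tolist())
        res = index_of_association(g, n_perm=9, seed=1)
        v_o, v_e, ia, rbard = brute_force_ia(alleles)
        assert res.v_observed == pytest.approx(v_o, abs=1e-12)
        assert res.v_expected == pytest.approx(v_e, abs=1e-12)
        assert res.rbard == pytest.approx(rbard, abs=1e-12)

    def test_monomorphic_matrix_rejected(self):
        with pytest.raises(ValueError, match="no variation|distinct"):
            index_of_association(make_matrix([[0, 0]] * 5), n_perm=9, seed=0)

    def test_single_locus_rejected(self):
        with pytest.raises(ValueError):
            index_of_association(make_matrix([[0], [1], [0]]), n_perm=9,
                                 seed=0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_invariance_under_relabeling_and_reordering(self, seed):
        rng = np.random.default_rng(seed)
        alleles = rng.integers(0, 3, size=(10, 5))
        if len({tuple(r) for r in alleles}) < 2:
            return
        base = index_of_association(make_matrix(alleles.tolist()),
                                    n_perm=0, seed=0)
        # relabel alleles within a locus, permute loci and samples
        relabeled = alleles.copy()
        relabeled[:, 2] = 2 - relabeled[:, 2]
        relabeled = relabeled[rng.permutation(10)][:, rng.permutation(5)]
        other = index_of_association(make_matrix(relabeled.tolist()),
                                     n_perm=0, seed=0)
        assert other.rbard == pytest.approx(base.rbard, abs=1e-12)
        assert other.ia == pytest.approx(base.ia, abs=1e-12)


class TestPairwiseLd:
    def test_duplicated_locus_hits_floor_p(self, rng):
        col = rng.integers(0, 2, size=20)
        third = rng.integers(0, 2, size=20)
        alleles = np.column_stack([col, col, third])
        res = pairwise_ld(make_matrix(alleles.tolist()), n_perm=99, seed=2)
        assert res.p_values.iloc[0, 1] == pytest.approx(1 / 100)

    def test_type_one_error_near_alpha(self):
        # independent loci: about alpha of testable pairs come out significant
        rates = []
        for rep in range(8):
            g = simulate_panmictic(100, 8, p=0.5, seed=600 + rep)
            res = pairwise_ld(g, alpha=0.05, n_perm=99, seed=700 + rep)
            rates.append(res.percent_significant)
        assert np.mean(rates) < 15.0  # 28 pairs/rep; binomial slack on 5%

    def test_pair_statistic_equals_two_locus_restriction(self, rng):
        alleles = rng.integers(0, 2, size=(15, 3))
        g = make_matrix(alleles.tolist())
        res = pairwise_ld(g, n_perm=9, seed=3)
        for j, k in itertools.combinations(range(3), 2):
            sub = brute_force_ia(alleles[:, [j, k]])
            assert res.statistics.iloc[j, k] == pytest.approx(sub[3],
                                                              abs=1e-12)

    def test_monomorphic_pair_not_testable(self):
        alleles = [[0, 0, 0], [0, 1, 1], [0, 0, 1], [0, 1, 0]]
        res = pairwise_ld(make_matrix(alleles), n_perm=9, seed=4)
        assert np.isnan(res.p_values.iloc[0, 1])
        assert res.n_testable == 1


def union_find_is_forest(edges):
    """Cycle detection oracle: union-find over the bipartite combo graph."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru == rv:
            return False
        parent[ru] = rv
    return True


class TestPairCompatibility:
    def test_four_gamete_rule_exhaustive(self):
        # all 16 occupancy patterns of the 2x2 combination table
        for pattern in itertools.product([0, 1], repeat=4):
            combos = [c for c, keep in
                      zip([(0, 0), (0, 1), (1, 0), (1, 1)], pattern) if keep]
            if not combos:
                continue
            col_j = np.array([c[0] for c in combos])
            col_k = np.array([c[1] for c in combos])
            expected = len(combos) < 4
            assert pair_compatibility(col_j, col_k) is expected

    def test_multiallelic_cycle_detected(self):
        # 6-cycle of combos over 3x3 alleles
        combos = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (0, 2)]
        col_j = np.array([c[0] for c in combos])
        col_k = np.array([c[1] for c in combos])
        assert pair_compatibility(col_j, col_k) is False
        edges = {(("j", a), ("k", b)) for a, b in combos}
        assert union_find_is_forest(edges) is False

    def test_random_multiallelic_matches_union_find(self, rng):
        for _ in range(200):
            col_j = rng.integers(0, 4, size=12)
            col_k = rng.integers(0, 4, size=12)
            edges = {(("j", int(a)), ("k", int(b)))
                     for a, b in zip(col_j, col_k)}
            assert pair_compatibility(col_j, col_k) == \
                union_find_is_forest(edges)

    def test_monomorphic_trivially_compatible(self):
        assert pair_compatibility(np.zeros(5, int),
                                  np.array([0, 1, 2, 1, 0])) is True


class TestCompatibilitySummary:
    def test_strictly_clonal_fully_compatible(self):
        g = make_matrix([[0] * 6, [1] * 6] * 5)
        res = compatibility_summary(g, n_shuffles=99, seed=0)
        assert res.prc == 1.0

    def test_diverse_sample_prc_zero_p_one(self):
        # every pair shows all four gametes: PrC = 0 and P = 1
        g = simulate_panmictic(100, 8, p=0.5, seed=9)
        res = compatibility_summary(g, n_shuffles=99, seed=1)
        assert res.prc == 0.0
        assert res.permutation.p_value == 1.0

    def test_ir_near_one_under_panmixia(self):
        g = simulate_panmictic(100, 12, p=np.linspace(0.3, 0.7, 12), seed=10)
        res = compatibility_summary(g, n_shuffles=200, seed=2)
        assert res.ir == pytest.approx(1.0, abs=0.05)
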