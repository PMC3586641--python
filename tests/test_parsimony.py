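"""Fitch scoring, tree search, and the tree-length permutation test."""

import itertools

import numpy as np
import pytest

from clonepop import (
    enumerate_topologies,
    fitch_length,
    mp_search,
    parsimony_lower_bound,
    ptlpt,
)
from clonepop.parsimony import UnrootedTree, _copy_adj, mp_length
from clonepop.genotypes import MISSING
from clonepop.simulate import simulate_clonal, simulate_panmictic

from conftest import make_matrix


def sankoff_length(adj, leaf_states, n_states):
    """Unit-cost Sankoff DP oracle: list-of-lists, no bit tricks.

    `leaf_states[i]` is a set of admissible states for leaf i.
    """
    INF = 10**9
    n_leaves = len(leaf_states)
    root_leaf = 0
    root = next(iter(adj[root_leaf]))

    def cost(node, parent):
        if node < n_leaves:
            return [0 if s in leaf_states[node] else INF
                    for s in range(n_states)]
        kids = [cost(c, node) for c in adj[node] if c != parent]
        out = []
        for s in range(n_states):
            tot = 0
            for kc in kids:
                tot += min(kc[t] + (0 if t == s else 1)
                           for t in range(n_states))
            out.append(tot)
        return out

    c = cost(root, root_leaf)
    return min(c[s] + min((0 if t == s else 1) for t in leaf_states[root_leaf])
               for s in range(n_states))


class TestFitch:
    def test_single_bipartition_character(self):
        g = make_matrix([[0], [0], [1], [1]])
        for adj in enumerate_topologies(4):
            tree = UnrootedTree(list(g.samples), _copy_adj(adj))
            assert fitch_length(tree, g) in (1, 2)
        # the matching topology achieves the minimum of 1
        assert mp_search(g, seed=0)[1] == 1

    def test_four_gamete_minimum_is_three(self):
        g = make_matrix([[0, 0], [0, 1], [1, 0], [1, 1]])
        lengths = [
            fitch_length(UnrootedTree(list(g.samples), _copy_adj(adj)), g)
            for adj in enumerate_topologies(4)
        ]
        assert min(lengths) == 3

    def test_matches_sankoff_oracle(self, rng):
        for trial in range(30):
            alleles = rng.integers(0, 3, size=(8, 12))
            g = make_matrix(alleles.tolist())
            # draw a random 8-taxon topology by enumeration index
            target = int(rng.integers(10395))
            adj = None
            for i, a in enumerate(enumerate_topologies(8)):
                if i == target:
                    adj = _copy_adj(a)
                    break
            tree = UnrootedTree(list(g.samples), adj)
            got = fitch_length(tree, g)
            oracle = sum(
                sankoff_length(adj, [{int(alleles[i, j])} for i in range(8)],
                               3)
                for j in range(12)
            )
            assert got == oracle

    def test_missing_data_as_any_state(self):
        g = make_matrix([[0], [MISSING], [1], [1]])
        # missing leaf can adopt either state: best tree needs 1 change
        assert mp_search(g, seed=0)[1] == 1

    def test_rooting_and_character_order_invariance(self, rng):
        alleles = rng.integers(0, 2, size=(6, 8))
        g = make_matrix(alleles.tolist())
        gperm = make_matrix(alleles[:, rng.permutation(8)].tolist())
        adjs = list(enumerate_topologies(6))
        for k in (0, 17, 61):
            tree = UnrootedTree(list(g.samples), _copy_adj(adjs[k]))
            assert fitch_length(tree, g) == fitch_length(tree, gperm)

    def test_leaf_without_data_rejected(self):
        g = make_matrix([[0], [1], [0], [1]])
        tree = mp_search(g, seed=0)[0]
        tree.leaf_labels[0] = "missing_taxon"
        with pytest.raises(ValueError):
            fitch_length(tree, g)


class TestMpSearch:
    def test_identical_taxa_zero_length(self):
        g = make_matrix([[0, 0]] * 4)
        tree, length = mp_search(g, seed=0)
        assert length == 0
        tree.validate()

    def test_clonal_genealogy_recovers_mutation_count(self, rng):
        # taxa derived from a known genealogy with unique mutations
        base = np.zeros(12, int)
        taxa = [base.copy()]
        mutations = 0
        for j in range(5):
            parent = taxa[rng.integers(len(taxa))].copy()
            parent[j + 2] = 1  # fresh site: no homoplasy
            mutations += 1
            taxa.append(parent)
        g = make_matrix([t.tolist() for t in taxa])
        _, length = mp_search(g, seed=1)
        assert length == mutations

    def test_heuristic_never_beats_and_usually_equals_exhaustive(self, rng):
        wins = 0
        trials = 60
        for t in range(trials):
            alleles = rng.integers(0, 2, size=(7, 10))
            g = make_matrix(alleles.tolist())
            exact = mp_search(g, seed=0, exhaustive_limit=9)[1]
            heur = mp_search(g, seed=t, exhaustive_limit=4, restarts=5)[1]
            assert heur >= exact  # heuristic can never go below the optimum
            wins += heur == exact
        assert wins >= 0.95 * trials

    def test_never_below_parsimony_lower_bound(self, rng):
        for t in range(10):
            alleles = rng.integers(0, 3, size=(10, 6))
            g = make_matrix(alleles.tolist())
            _, length = mp_search(g, seed=t, restarts=3)
            assert length >= parsimony_lower_bound(g)

    def test_perfect_phylogeny_achieves_lower_bound(self):
        # pairwise-compatible characters: nested bipartitions
        alleles = [
            [0, 0, 0], [1, 0, 0], [1, 1, 0], [1, 1, 1], [1, 1, 1], [0, 0, 0],
        ]
        g = make_matrix(alleles)
        _, length = mp_search(g, seed=0)
        assert length == parsimony_lower_bound(g)

    def test_three_taxa_direct(self):
        g = make_matrix([[0], [1], [1]])
        tree, length = mp_search(g, seed=0)
        assert length == 1
        tree.validate()

    def test_newick_round_trip(self):
        import dendropy

        g = make_matrix(np.random.default_rng(3).integers(
            0, 2, size=(6, 5)).tolist())
        tree, _ = mp_search(g, seed=0)
        parsed = dendropy.Tree.get(data=tree.newick(), schema="newick")
        assert sorted(l.taxon.label for l in parsed.leaf_node_iter()) == \
            sorted(g.samples)


class TestPtlpt:
    def test_two_genotype_degenerate_case(self):
        g = make_matrix([[0, 0, 0], [1, 1, 0]] * 3)
        res = ptlpt(g, n_perm=49, seed=0)
        assert res.observed_length == 2  # Hamming distance of the two rows
        assert 0.0 <= res.p_value <= 1.0

    def test_panmictic_calibration(self):
        high = 0
        for rep in range(20):
            g = simulate_panmictic(10, 8, seed=3000 + rep)
            res = ptlpt(g, n_perm=99, seed=4000 + rep, restarts=2)
            high += res.p_value > 0.05
        assert high >= 0.9 * 20

    def test_clonal_power(self):
        low = 0
        for rep in range(20):
            g = simulate_clonal(10, 8, founders=5, seed=1000 + rep)
            res = ptlpt(g, n_perm=99, seed=2000 + rep, restarts=2)
            low += res.p_value <= 0.05
        assert low >= 0.9 * 20

    def test_zero_p_rendered_as_bound(self):
        g = make_matrix(
            (np.arange(10)[:, None] < 5).astype(int).repeat(8, 1).tolist())
        res = ptlpt(g, n_perm=19, seed=0)
        if res.p_value == 0.0:
            assert res.p_label.startswith("<")

    def test_dedup_length_equals_full_search(self, rng):
        alleles = rng.integers(0, 2, size=(6, 6))
        rows = np.vstack([alleles, alleles[:3]])  # duplicates appended
        g_full = make_matrix(rows.tolist())
        g_uniq = make_matrix(alleles.tolist())
        assert mp_length(g_full, seed=0) == mp_search(g_uniq, seed=0)[1]
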