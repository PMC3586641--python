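"""Fitch small parsimony, maximum-parsimony tree search, and the
Parsimony Tree Length Permutation Test (PTLPT).

Isolates are taxa; the allele at each locus is an unordered multistate
character with unit change cost.  The PTLPT compares the length of the
shortest tree for the observed genotypes with the lengths obtained
after shuffling alleles within each locus (which preserves allele
proportions but destroys genotype structure): a clonally reproducing
sample yields trees markedly shorter than its shuffled counterparts,
whereas under free recombination observed and shuffled lengths mix.

The search replaces certified branch-and-bound with exhaustive
enumeration of all unrooted topologies for small taxon sets and
random-order stepwise addition followed by NNI hill-climbing (best of
several restarts) above that; the permutation test needs relative, not
certified-optimal, lengths, and the identical search is applied to
observed and shuffled datasets so the comparison stays unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genotypes import MISSING, GenotypeMatrix

MAX_STATES = 63  # state masks are 64-bit


@dataclass
class UnrootedTree:
    """Unrooted leaf-labelled tree with degree-3 internal nodes.

    Leaves are nodes ``0..n-1`` (indices into `leaf_labels`); internal
    nodes carry larger ids.  Stored as an adjacency map.
    """

    leaf_labels: list[str]
    adj: dict[int, set[int]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_labels)

    def edges(self) -> list[tuple[int, int]]:
        return sorted(
            (min(u, v), max(u, v)) for u in self.adj for v in self.adj[u] if u < v
        )

    def validate(self) -> None:
        n = self.n_leaves
        for u in range(n):
            if len(self.adj[u]) != 1:
                raise ValueError(f"leaf {u} has degree {len(self.adj[u])}")
        n_nodes = len(self.adj)
        n_edges = len(self.edges())
        if n_edges != n_nodes - 1:
            raise ValueError("tree must be acyclic and connected")

    def newick(self) -> str:
        """Newick string (rooted arbitrarily at leaf 0's neighbour)."""
        if self.n_leaves == 1:
            return f"{self.leaf_labels[0]};"

        def sub(node: int, parent: int) -> str:
            if node < self.n_leaves:
                return self.leaf_labels[node]
            kids = [sub(c, node) for c in self.adj[node] if c != parent]
            return "(" + ",".join(kids) + ")"

        if self.n_leaves == 2:
            return f"({self.leaf_labels[0]},{self.leaf_labels[1]});"
        root = next(iter(self.adj[0]))
        kids = [sub(c, root) for c in self.adj[root] if c != 0]
        return f"({self.leaf_labels[0]},{','.join(kids)});"


# ----------------------------------------------------------------------
# Character state masks and Fitch scoring
# ----------------------------------------------------------------------

def packed_state_masks(g: GenotypeMatrix) -> tuple[list[int], list[int]]:
    """Pack every character's state set into one big integer per leaf.

    Character j occupies its own bit field; bitwise AND/OR then act on
    all characters at once (they never carry across fields), which is
    what makes pure-Python Fitch passes cheap.  Missing calls get the
    union of states observed at the locus (any-state).

    Returns (per-leaf masks, per-character field masks).
    """
    n, L = g.alleles.shape
    offsets, field_masks = [], []
    off = 0
    any_states = []
    for j in range(L):
        col = g.alleles[:, j]
        observed = np.unique(col[col != MISSING])
        width = int(observed.max()) + 1 if observed.size else 1
        if width > MAX_STATES:
            raise ValueError(f"locus {g.loci[j]}: allele code >= {MAX_STATES}")
        offsets.append(off)
        field_masks.append(((1 << width) - 1) << off)
        any_state = 0
        for a in observed:
            any_state |= 1 << (off + int(a))
        any_states.append(any_state if any_state else 1 << off)
        off += width
    masks = []
    for i in range(n):
        m = 0
        for j in range(L):
            a = g.alleles[i, j]
            m |= any_states[j] if a == MISSING else 1 << (offsets[j] + int(a))
        masks.append(m)
    return masks, field_masks


def _fitch_score(adj: dict[int, set[int]], masks: list[int],
                 field_masks: list[int]) -> int:
    """Minimum total state changes over all characters (Fitch, unit cost).

    The tree is rooted at its lowest-numbered leaf for the pass; the
    count is rooting-invariant for unordered characters.  `adj` may hold
    a subset of the leaves (partial trees during stepwise addition).
    """
    n_leaves = len(masks)
    if len(adj) <= 1:
        return 0
    changes = 0
    root_leaf = min(u for u in adj if u < n_leaves)
    root = next(iter(adj[root_leaf]))
    # iterative post-order from `root`, treating the root leaf as parent
    stack = [(root, root_leaf, False)]
    node_mask: dict[int, int] = {}
    while stack:
        node, parent, done = stack.pop()
        if node < n_leaves:
            node_mask[node] = masks[node]
            continue
        if not done:
            stack.append((node, parent, True))
            for c in adj[node]:
                if c != parent:
                    stack.append((c, node, False))
            continue
        kids = [node_mask.pop(c) for c in adj[node] if c != parent]
        m = kids[0]
        for k in kids[1:]:
            inter = m & k
            union = m | k
            if inter == union:  # identical state sets: no empty fields
                m = inter
                continue
            empty = 0
            for fm in field_masks:
                if not inter & fm:
                    changes += 1
                    empty |= fm
            m = inter | (union & empty)
        node_mask[node] = m
    top = node_mask[root] & masks[root_leaf]
    if top != node_mask[root] | masks[root_leaf]:
        for fm in field_masks:
            if not top & fm:
                changes += 1
    return changes


def fitch_length(tree: UnrootedTree, g: GenotypeMatrix) -> int:
    """Parsimony length of `g`'s characters on `tree`.

    Leaf labels must match sample IDs (a subset is allowed; the
    corresponding rows are used in tree-leaf order).
    """
    index = {s: i for i, s in enumerate(g.samples)}
    missing = [lab for lab in tree.leaf_labels if lab not in index]
    if missing:
        raise ValueError(f"leaves without data rows: {missing}")
    rows = [index[lab] for lab in tree.leaf_labels]
    sub = g.subset(rows) if rows != list(range(g.n_samples)) else g
    masks, field_masks = packed_state_masks(sub)
    return _fitch_score(tree.adj, masks, field_masks)


def parsimony_lower_bound(g: GenotypeMatrix) -> int:
    """sum_j (a_j - 1): no tree can be shorter."""
    return int(np.sum(np.maximum(g.n_alleles_per_locus() - 1, 0)))


# ----------------------------------------------------------------------
# Topology generation and search
# ----------------------------------------------------------------------

def _base_adj(n: int) -> dict[int, set[int]]:
    if n == 1:
        return {0: set()}
    if n == 2:
        return {0: {1}, 1: {0}}
    if n == 3:
        return {0: {3}, 1: {3}, 2: {3}, 3: {0, 1, 2}}
    raise ValueError


def _insert_leaf(adj: dict[int, set[int]], leaf: int, edge: tuple[int, int],
                 new_internal: int) -> None:
    u, v = edge
    adj[u].discard(v)
    adj[v].discard(u)
    adj[new_internal] = {u, v, leaf}
    adj[u].add(new_internal)
    adj[v].add(new_internal)
    adj[leaf] = {new_internal}


def _remove_leaf(adj: dict[int, set[int]], leaf: int, internal: int) -> None:
    u, v = (x for x in adj[internal] if x != leaf)
    del adj[leaf]
    del adj[internal]
    adj[u].discard(internal)
    adj[v].discard(internal)
    adj[u].add(v)
    adj[v].add(u)


def enumerate_topologies(n: int):
    """Yield the adjacency map of every unrooted binary topology on
    leaves 0..n-1 ((2n-5)!! trees); the map is reused — copy to keep."""
    if n < 4:
        yield _base_adj(n)
        return
    # internal ids start at n to avoid clashing with leaf ids
    adj: dict[int, set[int]] = {0: {n}, 1: {n}, 2: {n}, n: {0, 1, 2}}

    def rec(t: int):
        if t == n:
            yield adj
            return
        edges = [(u, v) for u in adj for v in adj[u] if u < v]
        w = n + t - 2  # internal ids n..2n-3
        for e in edges:
            _insert_leaf(adj, t, e, w)
            yield from rec(t + 1)
            _remove_leaf(adj, t, w)

    yield from rec(3)


def _copy_adj(adj: dict[int, set[int]]) -> dict[int, set[int]]:
    return {u: set(vs) for u, vs in adj.items()}


def _nni_neighbors(adj: dict[int, set[int]], n_leaves: int):
    """Yield (u, v, a, c) swaps: for internal edge u-v move subtree a
    (neighbour of u) against subtree c (neighbour of v)."""
    for u in adj:
        if u < n_leaves:
            continue
        for v in adj[u]:
            if v < n_leaves or v < u:
                continue
            a_side = [x for x in adj[u] if x != v]
            c_side = [x for x in adj[v] if x != u]
            a = a_side[0]
            for c in c_side:
                yield (u, v, a, c)


def _apply_swap(adj, u, v, a, c) -> None:
    adj[u].discard(a); adj[a].discard(u)
    adj[v].discard(c); adj[c].discard(v)
    adj[u].add(c); adj[c].add(u)
    adj[v].add(a); adj[a].add(v)


def mp_search(
    g: GenotypeMatrix,
    restarts: int = 10,
    seed: int | None = None,
    exhaustive_limit: int = 9,
) -> tuple[UnrootedTree, int]:
    """Shortest tree for `g` (exact for small taxon sets, else heuristic).

    Up to `exhaustive_limit` taxa every unrooted topology is scored; above
    that, random-order stepwise addition followed by NNI hill-climbing,
    best over `restarts` starts.  Deterministic given `seed`.
    """
    n = g.n_samples
    masks, field_masks = packed_state_masks(g)
    if n <= 3:
        tree = UnrootedTree(leaf_labels=list(g.samples), adj=_base_adj(n))
        return tree, _fitch_score(tree.adj, masks, field_masks)
    if n <= exhaustive_limit:
        best_adj, best_len = None, None
        for adj in enumerate_topologies(n):
            length = _fitch_score(adj, masks, field_masks)
            if best_len is None or length < best_len:
                best_len, best_adj = length, _copy_adj(adj)
        return UnrootedTree(list(g.samples), best_adj), best_len

    rng = np.random.default_rng(seed)
    best_adj, best_len = None, None
    for _ in range(max(1, restarts)):
        order = list(rng.permutation(n))
        # relabel so the first three seed the base star
        adj = _base_adj(3)
        relabel = {i: t for i, t in enumerate(order[:3])}
        adj = {relabel.get(u, u + n - 3): {relabel.get(v, v + n - 3) for v in vs}
               for u, vs in adj.items()}
        next_internal = 2 * n  # fresh ids, no clash with leaves
        for t in order[3:]:
            edges = [(u, v) for u in adj for v in adj[u] if u < v]
            best_e, best_s = None, None
            for e in edges:
                _insert_leaf(adj, t, e, next_internal)
                s = _fitch_score(adj, masks, field_masks)
                _remove_leaf(adj, t, next_internal)
                if best_s is None or s < best_s:
                    best_s, best_e = s, e
            _insert_leaf(adj, t, best_e, next_internal)
            next_internal += 1
        # NNI hill climbing to a local optimum (first-improvement)
        cur = _fitch_score(adj, masks, field_masks)
        improved = True
        while improved:
            improved = False
            for (u, v, a, c) in list(_nni_neighbors(adj, n)):
                _apply_swap(adj, u, v, a, c)
                s = _fitch_score(adj, masks, field_masks)
                if s < cur:
                    cur = s
                    improved = True
                    break  # neighbourhood changed; rescan
                _apply_swap(adj, u, v, c, a)  # undo
        if best_len is None or cur < best_len:
            best_len, best_adj = cur, _copy_adj(adj)
    return UnrootedTree(list(g.samples), best_adj), best_len


def mp_length(
    g: GenotypeMatrix,
    restarts: int = 10,
    seed: int | None = None,
    exhaustive_limit: int = 9,
) -> int:
    """Shortest-tree length only, deduplicating identical rows first.

    The minimum parsimony length is unchanged by duplicate genotypes
    (they attach as zero-length cherries), so collapsing them loses
    nothing and often brings a clonal sample under the exhaustive limit,
    where the length is exact.
    """
    _, uniq_idx = np.unique(g.alleles, axis=0, return_index=True)
    rows = sorted(uniq_idx)
    sub = g.subset(rows) if len(rows) < g.n_samples else g
    return mp_search(sub, restarts=restarts, seed=seed,
                     exhaustive_limit=exhaustive_limit)[1]


# ----------------------------------------------------------------------
# PTLPT
# ----------------------------------------------------------------------

@dataclass
class PtlptResult:
    observed_length: int
    null_lengths: np.ndarray = field(repr=False)
    p_value: float  # plain fraction #{null <= observed} / n_perm
    p_label: str  # "<1/n" rendering when the fraction is zero
    n_permutations: int
    seed: int | None
    restarts: int
    exhaustive_limit: int

    @property
    def null_range(self) -> tuple[int, int]:
        return int(self.null_lengths.min()), int(self.null_lengths.max())

    def to_dict(self) -> dict:
        return {
            "observed_length": self.observed_length,
            "null_min": self.null_range[0],
            "null_max": self.null_range[1],
            "p_value": self.p_value,
            "p_label": self.p_label,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
            "restarts": self.restarts,
            "exhaustive_limit": self.exhaustive_limit,
        }


def ptlpt(
    g: GenotypeMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    restarts: int = 10,
    exhaustive_limit: int = 7,
) -> PtlptResult:
    """Parsimony Tree Length Permutation Test.

    The observed shortest-tree length is compared with the shortest-tree
    lengths of `n_perm` datasets whose alleles are shuffled within each
    locus (allele proportions preserved).  P is the plain fraction of
    null lengths <= the observed length, reported as ``"<1/n_perm"``
    when zero; significantly short observed trees support clonality.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    obs = mp_length(g, restarts=restarts, seed=_spawn(rng),
                    exhaustive_limit=exhaustive_limit)
    null = np.empty(n_perm, dtype=int)
    for b in range(n_perm):
        shuffled = g.alleles.copy()
        for j in range(g.n_loci):
            shuffled[:, j] = shuffled[rng.permutation(g.n_samples), j]
        gb = GenotypeMatrix(
            samples=list(g.samples), loci=list(g.loci),
            alleles=shuffled, metadata=g.metadata,
        )
        null[b] = mp_length(gb, restarts=restarts, seed=_spawn(rng),
                            exhaustive_limit=exhaustive_limit)
    p = float(np.sum(null <= obs)) / n_perm
    label = f"<{1 / n_perm:g}" if p == 0.0 else f"{p:g}"
    return PtlptResult(
        observed_length=int(obs),
        null_lengths=null,
        p_value=p,
        p_label=label,
        n_permutations=n_perm,
        seed=seed,
        restarts=restarts,
        exhaustive_limit=exhaustive_limit,
    )


def _spawn(rng: np.random.Generator) -> int:
    return int(rng.integers(0, 2**31 - 1))
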