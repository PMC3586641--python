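"""Multilocus association and phylogenetic-compatibility tests.

These are the core clonality diagnostics: the index of association I_A
and its loci-standardized form rBarD, per-pair linkage disequilibrium,
and the four-gamete / phylogenetic compatibility battery (PrC, IR).
All permutation nulls shuffle alleles independently within each locus,
which preserves allele frequencies while destroying inter-locus
association — the operational meaning of free recombination here.

These tests are meaningful on clone-corrected data (the standard
workflow for field samples, avoiding pseudo-replication of clonal
lineages) but accept any genotype matrix; calibration on simulated data
with known clonal repetition uses the uncorrected matrix.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .permutation import PermutationResult, add_one_pvalue


# ----------------------------------------------------------------------
# Index of association / rBarD
# ----------------------------------------------------------------------

@dataclass
class AssociationResult:
    ia: float
    rbard: float
    v_observed: float
    v_expected: float
    per_locus_variance: np.ndarray
    permutation: PermutationResult

    def to_dict(self) -> dict:
        return {
            "ia": self.ia,
            "rbard": self.rbard,
            "v_observed": self.v_observed,
            "v_expected": self.v_expected,
            "permutation": self.permutation.to_dict(),
        }


def _pair_mismatch_vectors(alleles: np.ndarray) -> np.ndarray:
    """d_j(a,b) over the n(n-1)/2 sample pairs, one row per pair.

    Missing handled by pairwise deletion: a pair with a missing call at
    locus j contributes 0 mismatch there (conservative).
    """
    n, L = alleles.shape
    iu = np.triu_indices(n, k=1)
    out = np.empty((len(iu[0]), L), dtype=float)
    for j in range(L):
        col = alleles[:, j]
        ok = col != MISSING
        diff = (col[:, None] != col[None, :]) & ok[:, None] & ok[None, :]
        out[:, j] = diff[iu]
    return out


def _ia_rbard(d: np.ndarray) -> tuple[float, float, float, float, np.ndarray]:
    """(I_A, rBarD, V_O, V_E, per-locus variances) from mismatch vectors.

    Population variances (denominator = number of pairs) throughout.
    """
    var_j = d.var(axis=0)
    D = d.sum(axis=1)
    v_o = float(D.var())
    v_e = float(var_j.sum())
    ia = v_o / v_e - 1.0 if v_e > 0 else float("nan")
    cov_cap = 0.0
    for j, k in itertools.combinations(range(d.shape[1]), 2):
        cov_cap += np.sqrt(var_j[j] * var_j[k])
    rbard = (v_o - v_e) / (2 * cov_cap) if cov_cap > 0 else float("nan")
    return ia, rbard, v_o, v_e, var_j


def _shuffle_within_loci(alleles: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    out = np.empty_like(alleles)
    for j in range(alleles.shape[1]):
        out[:, j] = alleles[rng.permutation(alleles.shape[0]), j]
    return out


def index_of_association(
    g: GenotypeMatrix, n_perm: int = 999, seed: int | None = None
) -> AssociationResult:
    """I_A and rBarD with a within-locus shuffle permutation test.

    I_A = V_O/V_E - 1 where V_O is the variance over sample pairs of the
    allelic mismatch count D and V_E its value under inter-locus
    independence (sum of per-locus mismatch variances); rBarD divides
    V_O - V_E by its maximum 2*sum_{j<k} sqrt(var_j var_k), so rBarD <= 1
    and equals 1 for perfectly associated loci.  Loci monomorphic in the
    sample carry zero variance and drop out of both sums.  Tail:
    rBarD_perm >= rBarD_obs, add-one P.
    """
    if g.n_loci < 2:
        raise ValueError("index of association needs at least 2 loci")
    if g.n_samples < 3 or len({tuple(r) for r in g.alleles}) < 2:
        raise ValueError("need at least 3 samples and 2 distinct genotypes")
    d = _pair_mismatch_vectors(g.alleles)
    ia, rbard, v_o, v_e, var_j = _ia_rbard(d)
    if v_e == 0:
        raise ValueError("no variation: all loci monomorphic")
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for b in range(n_perm):
        db = _pair_mismatch_vectors(_shuffle_within_loci(g.alleles, rng))
        null[b] = _ia_rbard(db)[1]
    perm = PermutationResult(
        statistic="rbard",
        observed=rbard,
        n_permutations=n_perm,
        p_value=add_one_pvalue(rbard, null, "greater"),
        tail="greater",
        seed=seed,
        null_replicates=null,
    )
    return AssociationResult(
        ia=ia, rbard=rbard, v_observed=v_o, v_expected=v_e,
        per_locus_variance=var_j, permutation=perm,
    )


# ----------------------------------------------------------------------
# Pairwise linkage disequilibrium
# ----------------------------------------------------------------------

@dataclass
class PairwiseLdResult:
    p_values: pd.DataFrame  # loci x loci, NaN = non-testable
    statistics: pd.DataFrame  # two-locus rBarD
    percent_significant: float
    n_testable: int
    alpha: float
    n_permutations: int
    seed: int | None


def pairwise_ld(
    g: GenotypeMatrix,
    alpha: float = 0.05,
    n_perm: int = 999,
    seed: int | None = None,
) -> PairwiseLdResult:
    """Two-locus rBarD permutation test for every locus pair.

    Pairs with either locus monomorphic are non-testable (NaN).  The
    summary is 100 x (#pairs with P < alpha) / (#testable pairs).
    """
    L = g.n_loci
    rng = np.random.default_rng(seed)
    pmat = np.full((L, L), np.nan)
    smat = np.full((L, L), np.nan)
    poly = g.n_alleles_per_locus() >= 2
    n_testable = 0
    n_sig = 0
    for j, k in itertools.combinations(range(L), 2):
        if not (poly[j] and poly[k]):
            continue
        sub = g.alleles[:, [j, k]]
        d = _pair_mismatch_vectors(sub)
        rb = _ia_rbard(d)[1]
        null = np.empty(n_perm)
        for b in range(n_perm):
            null[b] = _ia_rbard(_pair_mismatch_vectors(
                _shuffle_within_loci(sub, rng)))[1]
        p = add_one_pvalue(rb, null, "greater")
        pmat[j, k] = pmat[k, j] = p
        smat[j, k] = smat[k, j] = rb
        n_testable += 1
        n_sig += p < alpha
    if n_testable == 0:
        raise ValueError("no testable locus pair")
    return PairwiseLdResult(
        p_values=pd.DataFrame(pmat, index=g.loci, columns=g.loci),
        statistics=pd.DataFrame(smat, index=g.loci, columns=g.loci),
        percent_significant=100.0 * n_sig / n_testable,
        n_testable=n_testable,
        alpha=alpha,
        n_permutations=n_perm,
        seed=seed,
    )


# ----------------------------------------------------------------------
# Phylogenetic compatibility
# ----------------------------------------------------------------------

def pair_compatibility(col_j: np.ndarray, col_k: np.ndarray) -> bool:
    """True iff two locus columns are phylogenetically compatible.

    Compatibility holds iff the bipartite graph whose edges are the
    observed (allele_j, allele_k) combinations is acyclic (a forest);
    for two biallelic loci this reduces exactly to the four-gamete test:
    incompatible iff all four combinations occur.  Pairs of calls with a
    missing value are dropped; a monomorphic column is trivially
    compatible.
    """
    col_j = np.asarray(col_j)
    col_k = np.asarray(col_k)
    ok = (col_j != MISSING) & (col_k != MISSING)
    combos = {(int(a), int(b)) for a, b in zip(col_j[ok], col_k[ok])}
    G = nx.Graph()
    for a, b in combos:
        G.add_edge(("j", a), ("k", b))
    if G.number_of_nodes() == 0:
        return True
    return nx.is_forest(G)


@dataclass
class CompatibilityResult:
    pair_flags: pd.DataFrame  # True = compatible; NaN diagonal
    prc: float
    n_incompatible: int
    n_pairs: int
    ir: float
    permutation: PermutationResult

    def to_dict(self) -> dict:
        return {
            "prc": self.prc,
            "n_incompatible": self.n_incompatible,
            "n_pairs": self.n_pairs,
            "ir": self.ir,
            "permutation": self.permutation.to_dict(),
        }


def _count_incompatible(alleles: np.ndarray) -> int:
    c = 0
    for j, k in itertools.combinations(range(alleles.shape[1]), 2):
        if not pair_compatibility(alleles[:, j], alleles[:, k]):
            c += 1
    return c


def compatibility_summary(
    g: GenotypeMatrix, n_shuffles: int = 1000, seed: int | None = None
) -> CompatibilityResult:
    """PrC (proportion of compatible locus pairs) and the incompatibility
    ratio IR, with a permutation test for PrC.

    IR = observed incompatible-pair count / mean incompatible-pair count
    over `n_shuffles` within-locus shuffled datasets; IR << 1 indicates
    clonality-suppressed incompatibility, IR near 1 free recombination.
    The PrC test counts shuffles with PrC_perm >= PrC_obs (clonality
    inflates compatibility), add-one P.
    """
    L = g.n_loci
    if L < 2:
        raise ValueError("need at least 2 loci")
    n_pairs = L * (L - 1) // 2
    flags = np.full((L, L), np.nan)
    for j, k in itertools.combinations(range(L), 2):
        compat = pair_compatibility(g.alleles[:, j], g.alleles[:, k])
        flags[j, k] = flags[k, j] = float(compat)
    n_incomp = int(n_pairs - np.nansum(flags) / 2)
    prc = 1.0 - n_incomp / n_pairs
    rng = np.random.default_rng(seed)
    null_incomp = np.empty(n_shuffles)
    for b in range(n_shuffles):
        null_incomp[b] = _count_incompatible(_shuffle_within_loci(g.alleles, rng))
    mean_null = float(null_incomp.mean())
    ir = n_incomp / mean_null if mean_null > 0 else float("nan")
    null_prc = 1.0 - null_incomp / n_pairs
    perm = PermutationResult(
        statistic="prc",
        observed=prc,
        n_permutations=n_shuffles,
        p_value=add_one_pvalue(prc, null_prc, "greater"),
        tail="greater",
        seed=seed,
        null_replicates=null_prc,
    )
    return CompatibilityResult(
        pair_flags=pd.DataFrame(flags, index=g.loci, columns=g.loci),
        prc=prc,
        n_incompatible=n_incomp,
        n_pairs=n_pairs,
        ir=ir,
        permutation=perm,
    )
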