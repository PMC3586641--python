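"""Hierarchical partitioning of genetic variation: population PCA,
two-level nested AMOVA with Phi statistics, and Weir's theta.

AMOVA here follows the standard nested decomposition of squared
individual distances (number of differing loci, the natural metric for
unordered alleles) into among-region, among-population-within-region and
within-population strata.  Variance components come from the observed
mean squares via the unbalanced-design coefficients; Phi statistics use
the raw (possibly negative) components while the percentage column uses
zero-truncated ones, and each Phi carries its own permutation P.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AlleleFrequencies, GenotypeMatrix
from .permutation import PermutationResult, add_one_pvalue

STRATA = ("among_regions", "among_populations", "within_populations")


# ----------------------------------------------------------------------
# PCA on population allele-frequency profiles
# ----------------------------------------------------------------------

@dataclass
class PcaResult:
    labels: list[str]
    coordinates: np.ndarray  # populations x components
    percent_variance: np.ndarray
    loadings: np.ndarray  # features x components
    feature_names: list[str]


def population_pca(freqs: AlleleFrequencies) -> PcaResult:
    """PCA of centred population x allele-frequency vectors.

    One column per allele with one reference allele (code 0) dropped per
    locus, so the features are linearly independent within a locus.
    Components are eigenvectors of the covariance matrix; the sign of
    each component is fixed so its largest-magnitude loading is positive.
    """
    groups = freqs.groups
    if len(groups) < 3:
        raise ValueError("population PCA needs at least 3 populations")
    cols, names = [], []
    for j, locus in enumerate(freqs.loci):
        n_codes = len(freqs.freqs[groups[0]][j])
        for a in range(1, n_codes):  # drop reference allele 0
            col = np.array([freqs.freqs[g][j][a] for g in groups])
            if np.any(np.isnan(col)):
                raise ValueError(f"incomplete frequency vector at locus {locus}")
            cols.append(col)
            names.append(f"{locus}:{a}")
    X = np.column_stack(cols)
    Xc = X - X.mean(axis=0)
    if np.allclose(Xc, 0):
        raise ValueError("rank-0 input: all populations identical")
    cov = np.cov(Xc, rowvar=False)
    evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(evals)[::-1]
    evals, evecs = np.clip(evals[order], 0.0, None), evecs[:, order]
    k = min(len(groups) - 1, len(names))
    evals, evecs = evals[:k], evecs[:, :k]
    # deterministic sign: largest-|loading| entry positive
    for c in range(evecs.shape[1]):
        i = np.argmax(np.abs(evecs[:, c]))
        if evecs[i, c] < 0:
            evecs[:, c] = -evecs[:, c]
    coords = Xc @ evecs
    total = evals.sum()
    pct = 100.0 * evals / total if total > 0 else np.zeros_like(evals)
    return PcaResult(
        labels=list(groups),
        coordinates=coords,
        percent_variance=pct,
        loadings=evecs,
        feature_names=names,
    )


# ----------------------------------------------------------------------
# AMOVA
# ----------------------------------------------------------------------

@dataclass
class AmovaResult:
    table: pd.DataFrame  # stratum, df, SS, MS, est_var, est_var_truncated, percent
    phi: dict[str, float]  # PhiRT, PhiPR, PhiPT (from raw components)
    phi_p: dict[str, float]
    n_permutations: int
    seed: int | None

    def to_dict(self) -> dict:
        return {
            "table": self.table.to_dict(orient="records"),
            "phi": self.phi,
            "phi_p": self.phi_p,
            "n_permutations": self.n_permutations,
            "seed": self.seed,
        }


def amova_table(df: np.ndarray, ss: np.ndarray, est_var: np.ndarray) -> pd.DataFrame:
    """Derive MS and %variance from df, SS and variance components.

    MS = SS/df per stratum; the percentage column uses zero-truncated
    components.  This is the arithmetic behind every AMOVA summary the
    package prints, exposed so published tables can be replayed.
    """
    df = np.asarray(df, dtype=float)
    ss = np.asarray(ss, dtype=float)
    est_var = np.asarray(est_var, dtype=float)
    ms = ss / df
    trunc = np.clip(est_var, 0.0, None)
    pct = 100.0 * trunc / trunc.sum() if trunc.sum() > 0 else np.zeros_like(trunc)
    return pd.DataFrame(
        {
            "stratum": list(STRATA)[: len(df)],
            "df": df.astype(int),
            "SS": ss,
            "MS": ms,
            "est_var": est_var,
            "est_var_truncated": trunc,
            "percent": pct,
        }
    )


def _mismatch_sq(alleles: np.ndarray) -> np.ndarray:
    """Squared distance = number of differing loci (pairwise deletion on
    missing)."""
    n = alleles.shape[0]
    D = np.zeros((n, n))
    for j in range(alleles.shape[1]):
        col = alleles[:, j]
        ok = col != MISSING
        diff = (col[:, None] != col[None, :]) & ok[:, None] & ok[None, :]
        D += diff
    return D


def _amova_ss(D2: np.ndarray, pops: np.ndarray, regions: np.ndarray):
    """Nested sums of squares from the squared-distance matrix."""
    n = D2.shape[0]
    ss_total = D2.sum() / (2 * n)
    ss_wp = 0.0
    for p in np.unique(pops):
        idx = np.flatnonzero(pops == p)
        ss_wp += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_wr = 0.0
    for r in np.unique(regions):
        idx = np.flatnonzero(regions == r)
        ss_wr += D2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    return ss_total - ss_wr, ss_wr - ss_wp, ss_wp  # among-R, among-P(R), within-P


def _amova_components(ss: tuple, pops: np.ndarray, regions: np.ndarray):
    """Variance components via the unbalanced-design coefficients."""
    n = len(pops)
    pop_labels, pop_sizes = np.unique(pops, return_counts=True)
    reg_of_pop = {p: regions[pops == p][0] for p in pop_labels}
    reg_labels = np.unique(regions)
    n_reg = {r: int(np.sum(regions == r)) for r in reg_labels}
    P, R = len(pop_labels), len(reg_labels)
    df = np.array([R - 1, P - R, n - P], dtype=float)
    if df[0] < 1 or df[1] < 1 or df[2] < 1:
        raise ValueError("degenerate design: need >1 region, nested pops, replication")
    ms = np.array(ss) / df
    sum_n2_within = sum(
        sum(pop_sizes[i] ** 2 for i in range(P) if reg_of_pop[pop_labels[i]] == r)
        / n_reg[r]
        for r in reg_labels
    )
    n_prime = (n - sum_n2_within) / (P - R)
    n_dprime = (sum_n2_within - np.sum(pop_sizes**2) / n) / (R - 1)
    n_tprime = (n - sum(n_reg[r] ** 2 for r in reg_labels) / n) / (R - 1)
    sigma_c = ms[2]
    sigma_b = (ms[1] - sigma_c) / n_prime
    sigma_a = (ms[0] - sigma_c - n_dprime * sigma_b) / n_tprime
    return np.array(ss), df, np.array([sigma_a, sigma_b, sigma_c])


def _phi_from_components(comp: np.ndarray) -> dict[str, float]:
    a, b, c = comp
    tot = a + b + c
    return {
        "PhiRT": a / tot if tot != 0 else float("nan"),
        "PhiPR": b / (b + c) if (b + c) != 0 else float("nan"),
        "PhiPT": (a + b) / tot if tot != 0 else float("nan"),
    }


def amova(
    g: GenotypeMatrix, n_perm: int = 999, seed: int | None = None
) -> AmovaResult:
    """Two-level nested AMOVA (regions / populations / individuals).

    Permutation schemes per statistic: PhiPT permutes individuals among
    all populations; PhiPR permutes individuals among populations within
    their region; PhiRT permutes whole populations among regions.  P
    values use the add-one convention, tail Phi_perm >= Phi_obs.
    """
    pops = g.population_of()
    regions = g.region_of()
    D2 = _mismatch_sq(g.alleles)
    ss, df, comp = _amova_components(_amova_ss(D2, pops, regions), pops, regions)
    phi = _phi_from_components(comp)
    rng = np.random.default_rng(seed)

    def phi_of(pp: np.ndarray, rr: np.ndarray) -> dict[str, float]:
        return _phi_from_components(
            _amova_components(_amova_ss(D2, pp, rr), pp, rr)[2]
        )

    null = {k: [] for k in phi}
    pop_labels = np.unique(pops)
    reg_of_pop = {p: regions[pops == p][0] for p in pop_labels}
    for _ in range(n_perm):
        # PhiPT: individuals among all populations
        perm = rng.permutation(g.n_samples)
        pp = pops[perm]
        rr = np.array([reg_of_pop[p] for p in pp])
        null["PhiPT"].append(phi_of(pp, rr)["PhiPT"])
        # PhiPR: individuals among populations within regions
        pp = pops.copy()
        for r in np.unique(regions):
            idx = np.flatnonzero(regions == r)
            pp[idx] = pops[idx][rng.permutation(len(idx))]
        rr = np.array([reg_of_pop[p] for p in pp])
        null["PhiPR"].append(phi_of(pp, rr)["PhiPR"])
        # PhiRT: whole populations among regions
        shuffled = rng.permutation([reg_of_pop[p] for p in pop_labels])
        remap = dict(zip(pop_labels, shuffled))
        rr = np.array([remap[p] for p in pops])
        null["PhiRT"].append(phi_of(pops, rr)["PhiRT"])
    phi_p = {
        k: add_one_pvalue(phi[k], np.array(null[k]), "greater") for k in phi
    }
    table = amova_table(df, ss, comp)
    return AmovaResult(
        table=table, phi=phi, phi_p=phi_p, n_permutations=n_perm, seed=seed
    )


# ----------------------------------------------------------------------
# Weir's theta (haploid)
# ----------------------------------------------------------------------

@dataclass
class ThetaResult:
    theta: float
    per_locus: pd.DataFrame  # locus, theta (NaN where monomorphic)
    permutation: PermutationResult

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "per_locus": self.per_locus.to_dict(orient="records"),
            "permutation": self.permutation.to_dict(),
        }


def _theta_terms(alleles: np.ndarray, groups: np.ndarray):
    """Per-locus (sum MSP-MSG, sum MSP+(nc-1)MSG) over alleles.

    Haploid Weir & Cockerham moment estimator: for each allele,
    MSP = sum_i n_i (p_i - p_bar)^2 / (r-1),
    MSG = sum_i n_i p_i (1-p_i) / sum_i (n_i - 1),
    n_c = (N - sum n_i^2 / N) / (r - 1).
    Loci monomorphic overall contribute nothing (0/0) and are skipped.
    """
    labels = np.unique(groups)
    r = len(labels)
    num_per_locus, den_per_locus = [], []
    for j in range(alleles.shape[1]):
        col = alleles[:, j]
        ok = col != MISSING
        colv, grpv = col[ok], groups[ok]
        sizes = np.array([np.sum(grpv == gl) for gl in labels], dtype=float)
        if np.any(sizes < 1):
            num_per_locus.append(np.nan)
            den_per_locus.append(np.nan)
            continue
        N = sizes.sum()
        n_c = (N - np.sum(sizes**2) / N) / (r - 1)
        codes = np.unique(colv)
        if len(codes) < 2:
            num_per_locus.append(np.nan)  # monomorphic: excluded
            den_per_locus.append(np.nan)
            continue
        num = den = 0.0
        for a in codes:
            p_i = np.array(
                [np.mean(colv[grpv == gl] == a) for gl in labels]
            )
            p_bar = np.sum(sizes * p_i) / N
            msp = np.sum(sizes * (p_i - p_bar) ** 2) / (r - 1)
            msg = np.sum(sizes * p_i * (1 - p_i)) / np.sum(sizes - 1)
            num += msp - msg
            den += msp + (n_c - 1) * msg
        num_per_locus.append(num)
        den_per_locus.append(den)
    return np.array(num_per_locus), np.array(den_per_locus)


def theta_weir(
    g: GenotypeMatrix,
    grouping: str = "population",
    n_perm: int = 999,
    seed: int | None = None,
) -> ThetaResult:
    """Multilocus Weir & Cockerham theta with a randomization test.

    The multilocus estimate sums numerator and denominator terms over
    alleles and loci (allele-and-locus weighted ratio of sums).  The
    null shuffles individuals among groups, preserving group sizes;
    tail theta_perm >= theta_obs, add-one P.
    """
    groups = g.metadata[grouping].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("theta needs at least 2 groups")

    def theta_of(grp: np.ndarray) -> float:
        num, den = _theta_terms(g.alleles, grp)
        ok = ~np.isnan(num)
        if not ok.any() or np.sum(den[ok]) == 0:
            return float("nan")
        return float(np.sum(num[ok]) / np.sum(den[ok]))

    obs = theta_of(groups)
    num, den = _theta_terms(g.alleles, groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_locus = num / den
    rng = np.random.default_rng(seed)
    null = np.array(
        [theta_of(groups[rng.permutation(g.n_samples)]) for _ in range(n_perm)]
    )
    perm = PermutationResult(
        statistic="theta",
        observed=obs,
        n_permutations=n_perm,
        p_value=add_one_pvalue(obs, null[~np.isnan(null)], "greater"),
        tail="greater",
        seed=seed,
        null_replicates=null,
    )
    return ThetaResult(
        theta=obs,
        per_locus=pd.DataFrame({"locus": g.loci, "theta": per_locus}),
        permutation=perm,
    )
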