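"""Diversity statistics, genetic/geographic distance matrices, the
locus-saturation curve, and Mantel tests.

Two diversity indices are reported per population and labelled
explicitly, because field software differs in what it calls
"genotype diversity":

* mean unbiased gene diversity over loci,
  ``h_j = n/(n-1) * (1 - sum_a p_ja^2)``;
* Simpson genotypic diversity over multilocus genotype counts,
  ``1 - sum_k (c_k/n)^2``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import (
    MISSING,
    AlleleFrequencies,
    GenotypeMatrix,
    clone_correct,
)
from .permutation import PermutationResult, add_one_pvalue

EARTH_RADIUS_KM = 6371.0


# ----------------------------------------------------------------------
# Diversity
# ----------------------------------------------------------------------

@dataclass
class DiversityReport:
    """Per-population sample sizes and diversity indices."""

    table: pd.DataFrame  # population, n, n_genotypes, gene_diversity,
                         # simpson_genotypic_diversity, percent_polymorphic

    def to_dict(self) -> dict:
        return self.table.to_dict(orient="records")


def simpson_genotypic_diversity(counts) -> float:
    """1 - sum (c_k/n)^2 over multilocus-genotype counts c_k."""
    c = np.asarray(counts, dtype=float)
    n = c.sum()
    return float(1.0 - np.sum((c / n) ** 2))


def unbiased_gene_diversity(g: GenotypeMatrix) -> float:
    """Mean over loci of n/(n-1) * (1 - sum p^2); NaN for n < 2."""
    hs = []
    for j in range(g.n_loci):
        col = g.alleles[:, j]
        col = col[col != MISSING]
        n = col.size
        if n < 2:
            continue
        p = np.bincount(col).astype(float) / n
        hs.append(n / (n - 1) * (1.0 - np.sum(p**2)))
    return float(np.mean(hs)) if hs else float("nan")


def percent_polymorphic(g: GenotypeMatrix) -> float:
    """100 x (#loci with >= 2 observed alleles) / L."""
    return float(100.0 * np.sum(g.n_alleles_per_locus() >= 2) / g.n_loci)


def diversity_report(g: GenotypeMatrix) -> DiversityReport:
    """Per-population diversity block (plus a total-sample row).

    Populations with a single isolate get NaN for the unbiased gene
    diversity (the estimator is undefined at n = 1).
    """
    rows = []
    for name, sub in list(g.by_population().items()) + [("__total__", g)]:
        cc = clone_correct(sub, scope="dataset")
        rows.append(
            {
                "population": name,
                "n": sub.n_samples,
                "n_genotypes": cc.n_samples,
                "gene_diversity": unbiased_gene_diversity(sub),
                "simpson_genotypic_diversity": simpson_genotypic_diversity(
                    cc.multiplicity
                ),
                "percent_polymorphic": percent_polymorphic(sub),
            }
        )
    return DiversityReport(table=pd.DataFrame(rows))


def locus_rarefaction(
    g: GenotypeMatrix, reps: int = 100, seed: int | None = None
) -> pd.DataFrame:
    """Mean distinct-genotype count as loci are subsampled (saturation curve).

    For each k in 1..L, loci are drawn without replacement `reps` times
    and the number of distinct multilocus genotypes on those k loci is
    averaged.  At k = L the value is exact (no subsampling).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if g.n_loci < 2:
        raise ValueError("need at least 2 loci for a saturation curve")
    rng = np.random.default_rng(seed)
    means = []
    for k in range(1, g.n_loci + 1):
        if k == g.n_loci:
            means.append(float(len({tuple(r) for r in g.alleles})))
            continue
        vals = []
        for _ in range(reps):
            cols = rng.choice(g.n_loci, size=k, replace=False)
            vals.append(len({tuple(r) for r in g.alleles[:, cols]}))
        means.append(float(np.mean(vals)))
    return pd.DataFrame({"n_loci": np.arange(1, g.n_loci + 1), "mean_genotypes": means})


# ----------------------------------------------------------------------
# Distance matrices
# ----------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances with zero diagonal."""

    labels: list[str]
    values: np.ndarray
    kind: str  # "nei" | "geographic_km" | "altitude_m"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("diagonal must be zero")
        finite = np.isfinite(self.values)
        if not np.allclose(
            self.values[finite], self.values.T[finite.T], atol=1e-9
        ) or not np.array_equal(finite, finite.T):
            raise ValueError("matrix must be symmetric")
        with np.errstate(invalid="ignore"):
            if np.any(self.values[finite] < -1e-12):
                raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        """Upper-triangle (off-diagonal) values in row-major order."""
        iu = np.triu_indices(len(self.labels), k=1)
        return self.values[iu]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def nei_distance(freqs: AlleleFrequencies) -> DistanceMatrix:
    """Nei's (1972) standard genetic distance between groups.

    D = -ln( J_XY / sqrt(J_X * J_Y) ) where the J's are locus-wise means
    of sum_a x_a y_a, sum_a x_a^2 and sum_a y_a^2.  D = 0 iff the
    frequency profiles coincide; populations sharing no alleles at any
    locus give J_XY = 0 and D = +inf.
    """
    groups = freqs.groups
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for grp in groups:
        if len(freqs.all_missing[grp]) == len(freqs.loci):
            raise ValueError(f"group {grp!r} has no data at any locus")
    n = len(groups)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        jxy, jx, jy = [], [], []
        for loc in range(len(freqs.loci)):
            x = freqs.freqs[groups[i]][loc]
            y = freqs.freqs[groups[j]][loc]
            if np.any(np.isnan(x)) or np.any(np.isnan(y)):
                continue  # locus unusable in one of the two groups
            jxy.append(np.dot(x, y))
            jx.append(np.dot(x, x))
            jy.append(np.dot(y, y))
        if not jxy:
            raise ValueError(
                f"no shared scorable locus between {groups[i]} and {groups[j]}"
            )
        Jxy, Jx, Jy = np.mean(jxy), np.mean(jx), np.mean(jy)
        if Jxy == 0.0:
            d = float("inf")
        else:
            d = max(0.0, -math.log(Jxy / math.sqrt(Jx * Jy)))
        D[i, j] = D[j, i] = d
    return DistanceMatrix(labels=list(groups), values=D, kind="nei")


def haversine_km(lat1: float, lon1: float, lat2: float, lon2: float) -> float:
    """Great-circle distance in km (haversine, Earth radius 6371 km)."""
    p1, p2 = math.radians(lat1), math.radians(lat2)
    dphi = p2 - p1
    dlam = math.radians(lon2 - lon1)
    a = math.sin(dphi / 2) ** 2 + math.cos(p1) * math.cos(p2) * math.sin(dlam / 2) ** 2
    return 2 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))


def _population_coords(g: GenotypeMatrix) -> pd.DataFrame:
    coords = (
        g.metadata.groupby("population", sort=False)[
            ["latitude", "longitude", "altitude"]
        ].first()
    )
    return coords


def geographic_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """Pairwise 2-D great-circle distances (km) between populations."""
    coords = _population_coords(g)
    if coords[["latitude", "longitude"]].isna().any().any():
        bad = coords.index[coords[["latitude", "longitude"]].isna().any(axis=1)]
        raise ValueError(f"missing coordinates for populations: {list(bad)}")
    lat, lon = coords["latitude"].to_numpy(), coords["longitude"].to_numpy()
    if np.any(np.abs(lat) > 90) or np.any(np.abs(lon) > 180):
        raise ValueError("coordinates out of range")
    n = len(coords)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = haversine_km(lat[i], lon[i], lat[j], lon[j])
    return DistanceMatrix(labels=list(coords.index), values=D, kind="geographic_km")


def altitude_distance(g: GenotypeMatrix) -> DistanceMatrix:
    """|altitude difference| in metres between populations."""
    coords = _population_coords(g)
    if coords["altitude"].isna().any():
        bad = coords.index[coords["altitude"].isna()]
        raise ValueError(f"missing altitude for populations: {list(bad)}")
    alt = coords["altitude"].to_numpy(dtype=float)
    D = np.abs(alt[:, None] - alt[None, :])
    return DistanceMatrix(labels=list(coords.index), values=D, kind="altitude_m")


# ----------------------------------------------------------------------
# Mantel test
# ----------------------------------------------------------------------

def mantel_test(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    exact: bool = False,
) -> PermutationResult:
    """Mantel correlation between two distance matrices.

    The statistic is the Pearson correlation of the off-diagonal
    elements; the null is built by simultaneously permuting rows and
    columns of `d2`.  One-tailed P for positive association, with the
    add-one convention; with ``exact=True`` all n! permutations are
    enumerated (including the identity) and P is the plain fraction of
    permutations with r >= r_obs.
    """
    if d1.labels != d2.labels:
        raise ValueError("distance matrices must share labels and order")
    n = len(d1.labels)
    if n < 4:
        raise ValueError("Mantel test needs at least 4 items")
    x = d1.condensed()
    if np.std(x) == 0 or np.std(d2.condensed()) == 0:
        raise ValueError("constant distance matrix: correlation undefined")
    iu = np.triu_indices(n, k=1)

    def corr(perm: np.ndarray) -> float:
        y = d2.values[np.ix_(perm, perm)][iu]
        return float(stats.pearsonr(x, y)[0])

    identity = np.arange(n)
    r_obs = corr(identity)
    if exact:
        null = np.array([corr(np.asarray(p)) for p in itertools.permutations(range(n))])
        # tolerance so permutations tied with the observed r count as >=
        p_value = float(np.mean(null >= r_obs - 1e-9))
        n_used = null.size
    else:
        rng = np.random.default_rng(seed)
        null = np.array([corr(rng.permutation(n)) for _ in range(n_perm)])
        p_value = add_one_pvalue(r_obs, null, "greater")
        n_used = n_perm
    return PermutationResult(
        statistic="mantel_r",
        observed=r_obs,
        n_permutations=n_used,
        p_value=p_value,
        tail="greater",
        seed=seed,
        null_replicates=null,
    )
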