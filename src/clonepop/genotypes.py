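"""Haploid multilocus genotype matrices: container, I/O, clone correction,
allele frequencies.

The unit of observation is an isolate scored at ``L`` loci; each locus
carries a small set of unordered allele codes (e.g. PCR-RFLP banding
patterns), so codes are opaque integers with no biological ordering.
Isolates carry a nested region/population label pair plus habitat and
coordinates, which drive every downstream grouping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

#: metadata columns expected in a genotype table, in canonical order
META_COLUMNS = (
    "sample_id",
    "region",
    "population",
    "habitat",
    "latitude",
    "longitude",
    "altitude",
)


class GenotypeValidationError(ValueError):
    """Raised when a genotype table violates the data-model invariants."""


@dataclass
class GenotypeMatrix:
    """n isolates x L loci of haploid allele codes plus per-isolate metadata.

    Parameters
    ----------
    samples : list of str
        Unique isolate identifiers, one per row.
    loci : list of str
        Locus identifiers (e.g. ``"frag2_HindIII"``), one per column.
    alleles : ndarray of int, shape (n, L)
        Small non-negative allele codes; :data:`MISSING` (= -1) marks a
        missing call.
    metadata : pandas.DataFrame
        Indexed by sample id with columns region, population, habitat,
        latitude, longitude, altitude.
    """

    samples: list[str]
    loci: list[str]
    alleles: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.alleles = np.asarray(self.alleles, dtype=np.int64)
        self.validate()

    # -- invariants ------------------------------------------------------
    def validate(self) -> None:
        n, L = len(self.samples), len(self.loci)
        if n < 1 or L < 1:
            raise GenotypeValidationError("need at least one sample and one locus")
        if self.alleles.shape != (n, L):
            raise GenotypeValidationError(
                f"allele table shape {self.alleles.shape} != ({n}, {L})"
            )
        if len(set(self.samples)) != n:
            dupes = sorted({s for s in self.samples if self.samples.count(s) > 1})
            raise GenotypeValidationError(f"duplicate sample IDs: {dupes}")
        if len(set(self.loci)) != L:
            raise GenotypeValidationError("duplicate locus IDs")
        if (self.alleles < MISSING).any():
            raise GenotypeValidationError("allele codes must be >= 0 or missing (-1)")
        if list(self.metadata.index) != list(self.samples):
            raise GenotypeValidationError("metadata index must equal sample list")
        # populations nest within regions
        pr = self.metadata.groupby("population", sort=False)["region"].nunique()
        bad = pr[pr > 1]
        if len(bad):
            raise GenotypeValidationError(
                f"populations mapped to multiple regions: {list(bad.index)}"
            )

    # -- conveniences ----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def populations(self) -> list[str]:
        """Population labels in order of first appearance."""
        return list(dict.fromkeys(self.metadata["population"]))

    @property
    def regions(self) -> list[str]:
        return list(dict.fromkeys(self.metadata["region"]))

    def population_of(self) -> np.ndarray:
        return self.metadata["population"].to_numpy()

    def region_of(self) -> np.ndarray:
        return self.metadata["region"].to_numpy()

    def n_alleles_per_locus(self) -> np.ndarray:
        """Number of distinct observed (non-missing) alleles at each locus."""
        out = np.empty(self.n_loci, dtype=int)
        for j in range(self.n_loci):
            col = self.alleles[:, j]
            out[j] = len(np.unique(col[col != MISSING]))
        return out

    def subset(self, rows: np.ndarray | list[int]) -> "GenotypeMatrix":
        """Row subset preserving order; returns a new matrix."""
        rows = np.asarray(rows)
        return GenotypeMatrix(
            samples=[self.samples[i] for i in rows],
            loci=list(self.loci),
            alleles=self.alleles[rows],
            metadata=self.metadata.iloc[rows],
        )

    def by_population(self) -> dict[str, "GenotypeMatrix"]:
        pops = self.population_of()
        return {
            p: self.subset(np.flatnonzero(pops == p)) for p in self.populations
        }


@dataclass
class CloneCorrectedMatrix(GenotypeMatrix):
    """A GenotypeMatrix in which, within `scope`, every multilocus genotype
    occurs once; `multiplicity[i]` counts the collapsed isolates."""

    multiplicity: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    scope: str = "dataset"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.multiplicity = np.asarray(self.multiplicity, dtype=np.int64)
        if self.multiplicity.shape != (self.n_samples,):
            raise GenotypeValidationError("multiplicity must have one entry per row")
        if (self.multiplicity < 1).any():
            raise GenotypeValidationError("multiplicities must be >= 1")
        if self.scope not in ("dataset", "population"):
            raise GenotypeValidationError(f"unknown scope {self.scope!r}")


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def read_genotype_table(path, dialect: str = "\t") -> GenotypeMatrix:
    """Read a delimited genotype table into a :class:`GenotypeMatrix`.

    The header must start with the metadata columns
    ``sample_id region population habitat latitude longitude altitude``
    followed by one column per locus.  Missing calls are ``NA``.  Row
    order is preserved.
    """
    df = pd.read_csv(path, sep=dialect, dtype={"sample_id": str})
    missing_meta = [c for c in META_COLUMNS if c not in df.columns]
    if missing_meta:
        raise GenotypeValidationError(f"{path}: missing columns {missing_meta}")
    locus_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not locus_cols:
        raise GenotypeValidationError(f"{path}: no locus columns found")
    try:
        alleles = (
            df[locus_cols]
            .apply(pd.to_numeric, errors="raise")
            .fillna(MISSING)
            .to_numpy()
        )
    except (ValueError, TypeError) as exc:
        raise GenotypeValidationError(f"{path}: non-numeric allele code: {exc}")
    if not np.all(alleles == np.floor(alleles)):
        bad = np.argwhere(alleles != np.floor(alleles))[0]
        raise GenotypeValidationError(
            f"{path}: non-integer allele code at row {bad[0] + 1}, "
            f"locus {locus_cols[bad[1]]}"
        )
    samples = list(df["sample_id"])
    meta = df[list(META_COLUMNS[1:])].copy()
    meta.index = pd.Index(samples, name="sample_id")
    return GenotypeMatrix(
        samples=samples,
        loci=locus_cols,
        alleles=alleles.astype(np.int64),
        metadata=meta,
    )


def write_genotype_table(g: GenotypeMatrix, path, dialect: str = "\t") -> None:
    """Write `g` in the dialect :func:`read_genotype_table` reads (lossless)."""
    df = g.metadata.reset_index()
    df.columns = list(META_COLUMNS)
    allele_df = pd.DataFrame(g.alleles, columns=g.loci).astype(object)
    allele_df[g.alleles == MISSING] = "NA"
    pd.concat([df, allele_df], axis=1).to_csv(path, sep=dialect, index=False)


# ----------------------------------------------------------------------
# Clone correction
# ----------------------------------------------------------------------

def clone_correct(g: GenotypeMatrix, scope: str = "dataset") -> CloneCorrectedMatrix:
    """Collapse isolates sharing an identical multilocus genotype.

    Two isolates belong to the same clone only if their allele vectors are
    identical at every locus *including* the missing pattern (conservative:
    an isolate with a missing call never merges with a complete one).  The
    representative of each clone is its first occurrence in input order.

    Parameters
    ----------
    scope : {"dataset", "population"}
        ``dataset`` collapses across the whole matrix; ``population``
        collapses within each population label, so the same genotype may
        appear once per population in which it occurs.
    """
    if scope not in ("dataset", "population"):
        raise ValueError(f"unknown clone-correction scope {scope!r}")
    pops = g.population_of()
    seen: dict[tuple, int] = {}
    keep: list[int] = []
    mult: list[int] = []
    for i in range(g.n_samples):
        key = tuple(g.alleles[i])
        if scope == "population":
            key = (pops[i],) + key
        if key in seen:
            mult[seen[key]] += 1
        else:
            seen[key] = len(keep)
            keep.append(i)
            mult.append(1)
    rows = np.asarray(keep)
    return CloneCorrectedMatrix(
        samples=[g.samples[i] for i in rows],
        loci=list(g.loci),
        alleles=g.alleles[rows],
        metadata=g.metadata.iloc[rows],
        multiplicity=np.asarray(mult),
        scope=scope,
    )


# ----------------------------------------------------------------------
# Allele frequencies
# ----------------------------------------------------------------------

@dataclass
class AlleleFrequencies:
    """Per-group, per-locus allele frequencies on a shared allele space.

    ``freqs[group][j]`` is a vector over allele codes ``0..A_j-1`` where
    ``A_j`` is the number of codes observed anywhere in the source matrix
    at locus ``j``; ``counts[group][j]`` is the number of non-missing
    calls behind it.  Loci with zero calls in a group are flagged in
    ``all_missing`` and carry NaN frequencies.
    """

    groups: list[str]
    loci: list[str]
    freqs: dict[str, list[np.ndarray]]
    counts: dict[str, np.ndarray]
    all_missing: dict[str, list[str]]

    def as_frame(self) -> pd.DataFrame:
        """Long-format table (group, locus, allele, frequency, n_calls)."""
        rows = []
        for grp in self.groups:
            for j, locus in enumerate(self.loci):
                for a, f in enumerate(self.freqs[grp][j]):
                    rows.append((grp, locus, a, f, int(self.counts[grp][j])))
        return pd.DataFrame(
            rows, columns=["group", "locus", "allele", "frequency", "n_calls"]
        )


def allele_frequencies(g: GenotypeMatrix, by: str = "population") -> AlleleFrequencies:
    """Tally per-locus allele frequencies within each group.

    `by` is ``"population"``, ``"region"`` or ``"all"``.  Counts use
    non-missing calls only; frequencies within a (group, locus) cell sum
    to 1.
    """
    if by == "all":
        labels = np.array(["all"] * g.n_samples)
        groups = ["all"]
    elif by in ("population", "region"):
        labels = g.metadata[by].to_numpy()
        groups = list(dict.fromkeys(labels))
    else:
        raise ValueError(f"unknown grouping {by!r}")

    # allele space per locus is global so groups are comparable
    n_codes = [
        int(col[col != MISSING].max()) + 1 if (col != MISSING).any() else 0
        for col in g.alleles.T
    ]
    freqs: dict[str, list[np.ndarray]] = {}
    counts: dict[str, np.ndarray] = {}
    flagged: dict[str, list[str]] = {}
    for grp in groups:
        rows = g.alleles[labels == grp]
        if rows.shape[0] == 0:
            raise ValueError(f"empty group {grp!r}")
        fs, cs, miss = [], np.zeros(g.n_loci, dtype=int), []
        for j in range(g.n_loci):
            col = rows[:, j]
            col = col[col != MISSING]
            cs[j] = col.size
            if col.size == 0:
                fs.append(np.full(n_codes[j], np.nan))
                miss.append(g.loci[j])
            else:
                tab = np.bincount(col, minlength=n_codes[j]).astype(float)
                fs.append(tab / tab.sum())
        freqs[grp] = fs
        counts[grp] = cs
        flagged[grp] = miss
    return AlleleFrequencies(
        groups=groups, loci=list(g.loci), freqs=freqs, counts=counts,
        all_missing=flagged,
    )
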