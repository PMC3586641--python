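"""Synthetic structured, partially clonal haploid populations and
mutated fragment pairs.

The generator emulates the features the statistics assume: a nested
region/population design, per-population allele-frequency differentiation
under the Balding-Nichols model (frequencies drawn from a Dirichlet/Beta
around ancestral values with a known F, giving a known target for theta
recovery), and partial clonality by founder copying (a fraction c of
isolates copy one of a few founder genotypes, matching the
few-genotypes-at-high-multiplicity pattern of real clonal samples).
Synthetic populations sit on a latitude line so geographic distance is a
controllable axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import META_COLUMNS, GenotypeMatrix
from .snp import AlignedFragmentPair

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


@dataclass
class SimConfig:
    """Study design for :func:`simulate_structured`.

    Defaults emulate a 6-region / 10-subpopulation survey genotyped at
    12 biallelic loci with moderate differentiation and strong partial
    clonality, the regime the analyses here are built for.
    """

    n_regions: int = 6
    pops_per_region: tuple[int, ...] = (2, 2, 2, 2, 1, 1)
    n_per_pop: tuple[int, ...] = (29, 21, 28, 20, 30, 21, 29, 16, 5, 29)
    n_loci: int = 12
    alleles_per_locus: int = 2
    ancestral_freqs: np.ndarray | None = None  # (L, A); default U(0.1, 0.9) draws
    fst: float = 0.15
    migration: float = 0.0  # prob. an individual draws from the ancestral pool
    clonal_fraction: float = 0.7
    founders_per_pop: int = 4
    mutation_rate: float = 0.001  # per locus per clonal copy
    lat0: float = 24.0
    lat_spacing: float = 2.0  # degrees between successive populations
    seed: int = 0

    def validate(self) -> None:
        if len(self.pops_per_region) != self.n_regions:
            raise ValueError("pops_per_region must have n_regions entries")
        n_pops = sum(self.pops_per_region)
        if len(self.n_per_pop) != n_pops:
            raise ValueError("n_per_pop must have one entry per population")
        if min(self.n_per_pop) < 1 or self.n_loci < 1 or self.alleles_per_locus < 2:
            raise ValueError("sizes must be >= 1 and loci at least biallelic")
        for p, name in ((self.fst, "fst"), (self.migration, "migration"),
                        (self.clonal_fraction, "clonal_fraction"),
                        (self.mutation_rate, "mutation_rate")):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.founders_per_pop > min(self.n_per_pop):
            raise ValueError("founders_per_pop exceeds the smallest population")


def _population_frequencies(cfg: SimConfig, rng: np.random.Generator):
    """(ancestral (L,A), per-pop list of (L,A)) Balding-Nichols draws."""
    L, A = cfg.n_loci, cfg.alleles_per_locus
    if cfg.ancestral_freqs is not None:
        anc = np.asarray(cfg.ancestral_freqs, dtype=float)
        if anc.shape != (L, A):
            raise ValueError(f"ancestral_freqs must be shape ({L}, {A})")
    elif A == 2:
        p = rng.uniform(0.1, 0.9, size=L)
        anc = np.column_stack([p, 1 - p])
    else:
        anc = rng.dirichlet(np.ones(A) * 2, size=L)
    n_pops = sum(cfg.pops_per_region)
    pop_freqs = []
    for _ in range(n_pops):
        if cfg.fst == 0:
            pop_freqs.append(anc.copy())
        else:
            scale = (1 - cfg.fst) / cfg.fst
            f = np.empty_like(anc)
            for j in range(L):
                f[j] = rng.dirichlet(np.clip(anc[j] * scale, 1e-6, None))
            pop_freqs.append(f)
    return anc, pop_freqs


def simulate_structured(cfg: SimConfig) -> GenotypeMatrix:
    """Draw a structured, partially clonal genotype matrix.

    Within each population the first `founders_per_pop` isolates are
    independent draws from the population frequencies; each further
    isolate copies a uniformly chosen founder with probability
    `clonal_fraction` (then mutates each locus with `mutation_rate`),
    and is otherwise a fresh recombinant draw.  With probability
    `migration` a fresh draw uses the ancestral pool instead.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    anc, pop_freqs = _population_frequencies(cfg, rng)
    L, A = cfg.n_loci, cfg.alleles_per_locus

    samples, rows, meta_rows = [], [], []
    pop_idx = 0
    for r in range(cfg.n_regions):
        for _ in range(cfg.pops_per_region[r]):
            n_i = cfg.n_per_pop[pop_idx]
            freqs = pop_freqs[pop_idx]

            def fresh_draw() -> np.ndarray:
                src = anc if (cfg.migration and rng.random() < cfg.migration) \
                    else freqs
                if A == 2:
                    return (rng.random(L) >= src[:, 0]).astype(np.int64)
                return np.array(
                    [rng.choice(A, p=src[j]) for j in range(L)], dtype=np.int64
                )

            founders = [fresh_draw() for _ in range(cfg.founders_per_pop)]
            pop_name = f"pop{pop_idx:02d}"
            lat = cfg.lat0 + cfg.lat_spacing * pop_idx
            for i in range(n_i):
                if i < cfg.founders_per_pop:
                    geno = founders[i].copy()
                elif rng.random() < cfg.clonal_fraction:
                    geno = founders[rng.integers(len(founders))].copy()
                    if cfg.mutation_rate:
                        hits = rng.random(L) < cfg.mutation_rate
                        geno[hits] = rng.integers(0, A, size=hits.sum())
                else:
                    geno = fresh_draw()
                samples.append(f"{pop_name}_s{i:03d}")
                rows.append(geno)
                meta_rows.append(
                    (f"region{r}", pop_name, "synthetic", lat, 100.0,
                     1000.0 + 150.0 * pop_idx)
                )
            pop_idx += 1
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS[1:]))
    meta.index = pd.Index(samples, name="sample_id")
    return GenotypeMatrix(
        samples=samples,
        loci=[f"locus{j:02d}" for j in range(L)],
        alleles=np.array(rows),
        metadata=meta,
    )


# printed survey design: (region, site, n, habitat, lat, lon, altitude m)
SURVEY_DESIGN = (
    ("Dianchi", "Dianchi_Lake", 29, "polluted_water", 25.00, 102.41, 1895),
    ("Dianchi", "Xishan_Mountain", 21, "forest_soil", 25.00, 102.41, 1895),
    ("Heijing", "Ancient_salt_mine", 28, "high_salt_soil", 25.21, 101.44, 1700),
    ("Heijing", "Feilai_Mountain", 20, "forest_soil", 25.21, 101.44, 1700),
    ("Gejiu", "Laochang_mining_area", 30, "heavy_metal_soil", 23.21, 103.09, 1688),
    ("Gejiu", "Laochang_Mountain", 21, "forest_soil", 23.21, 103.09, 1688),
    ("Jiuzhaigou", "Nuorilang", 29, "forest_soil", 32.55, 103.16, 2600),
    ("Jiuzhaigou", "Panda_Lake", 16, "pristine_water", 32.55, 103.16, 2600),
    ("Turfan", "Desert_Botanical_Garden", 5, "desert_soil", 48.2, 87.34, -87),
    ("Kanas", "Kanas_Forest", 29, "forest_soil", 48.81, 87.04, 1370),
)


def simulate_table1_design(
    seed: int,
    fst: float = 0.15,
    clonal_fraction: float = 0.7,
    founders_per_pop: int = 4,
) -> GenotypeMatrix:
    """A 228-isolate matrix on the published survey design.

    Ten subpopulations in six geographic regions with the printed sample
    sizes (29, 21, 28, 20, 30, 21, 29, 16, 5, 29), coordinates and
    altitudes, scored at 12 biallelic loci; clonality and
    differentiation are free parameters of the generator.
    """
    cfg = SimConfig(
        fst=fst,
        clonal_fraction=clonal_fraction,
        founders_per_pop=founders_per_pop,
        seed=seed,
    )
    g = simulate_structured(cfg)
    # overwrite synthetic labels/coordinates with the survey design
    meta_rows, samples = [], []
    i = 0
    new_meta = g.metadata.copy()
    new_samples = list(g.samples)
    for k, (region, site, n, habitat, lat, lon, alt) in enumerate(SURVEY_DESIGN):
        for s in range(n):
            new_samples[i] = f"{site}_s{s:03d}"
            meta_rows.append((region, site, habitat, lat, lon, float(alt)))
            i += 1
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS[1:]))
    meta.index = pd.Index(new_samples, name="sample_id")
    return GenotypeMatrix(
        samples=new_samples, loci=list(g.loci), alleles=g.alleles, metadata=meta
    )


def simulate_ibd_line(
    n_pops: int = 10,
    n_per_pop: int = 20,
    n_loci: int = 12,
    step: float = 0.08,
    seed: int = 0,
) -> GenotypeMatrix:
    """Isolation-by-distance panel: allele frequencies random-walk along a
    line of populations, so genetic divergence grows with distance.

    Each population is one region (no nesting); coordinates advance one
    degree of latitude per population.
    """
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.3, 0.7, size=n_loci)
    samples, rows, meta_rows = [], [], []
    for k in range(n_pops):
        if k > 0:
            p = np.clip(p + rng.normal(0.0, step, size=n_loci), 0.02, 0.98)
        pop = f"pop{k:02d}"
        for i in range(n_per_pop):
            rows.append((rng.random(n_loci) < p).astype(np.int64))
            samples.append(f"{pop}_s{i:03d}")
            meta_rows.append((pop, pop, "synthetic", 20.0 + k, 100.0, 1000.0))
    meta = pd.DataFrame(meta_rows, columns=list(META_COLUMNS[1:]))
    meta.index = pd.Index(samples, name="sample_id")
    return GenotypeMatrix(
        samples=samples,
        loci=[f"locus{j:02d}" for j in range(n_loci)],
        alleles=np.array(rows),
        metadata=meta,
    )


def simulate_panmictic(
    n: int = 30, n_loci: int = 12, p: float | np.ndarray = 0.5, seed: int = 0
) -> GenotypeMatrix:
    """Single gene pool in linkage equilibrium: biallelic loci sampled
    independently at frequency `p` (scalar or per-locus)."""
    rng = np.random.default_rng(seed)
    p = np.broadcast_to(np.asarray(p, dtype=float), (n_loci,))
    alleles = (rng.random((n, n_loci)) < p).astype(np.int64)
    samples = [f"s{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        [("region0", "pop00", "synthetic", 20.0, 100.0, 1000.0)] * n,
        columns=list(META_COLUMNS[1:]),
    )
    meta.index = pd.Index(samples, name="sample_id")
    return GenotypeMatrix(
        samples=samples,
        loci=[f"locus{j:02d}" for j in range(n_loci)],
        alleles=alleles,
        metadata=meta,
    )


def simulate_clonal(
    n: int = 30,
    n_loci: int = 12,
    founders: int = 5,
    p: float = 0.5,
    seed: int = 0,
) -> GenotypeMatrix:
    """Strictly clonal sample: `founders` independent genotypes, the rest
    exact copies (a single gene pool with clonal_fraction = 1)."""
    if founders > n:
        raise ValueError("founders exceed sample size")
    rng = np.random.default_rng(seed)
    base = (rng.random((founders, n_loci)) < p).astype(np.int64)
    picks = rng.integers(0, founders, size=n - founders)
    alleles = np.vstack([base, base[picks]])
    samples = [f"s{i:03d}" for i in range(n)]
    meta = pd.DataFrame(
        [("region0", "pop00", "synthetic", 20.0, 100.0, 1000.0)] * n,
        columns=list(META_COLUMNS[1:]),
    )
    meta.index = pd.Index(samples, name="sample_id")
    return GenotypeMatrix(
        samples=samples,
        loci=[f"locus{j:02d}" for j in range(n_loci)],
        alleles=alleles,
        metadata=meta,
    )


# ----------------------------------------------------------------------
# Fragment pairs with planted SNPs
# ----------------------------------------------------------------------

def simulate_fragment_pair(
    length: int,
    n_transitions: int,
    n_transversions: int,
    n_indels: int,
    seed: int = 0,
    fragment_id: str = "sim",
) -> AlignedFragmentPair:
    """Mutate a random reference at non-adjacent positions with exact
    planted class counts (each indel a single-column gap run).

    Raises if the events cannot be packed with >= 1 spacing.
    """
    n_events = n_transitions + n_transversions + n_indels
    if n_events > (length + 1) // 2:
        raise ValueError(
            f"cannot place {n_events} non-adjacent events in {length} sites"
        )
    rng = np.random.default_rng(seed)
    ref = rng.choice(list("ACGT"), size=length)
    # choose non-adjacent positions by spacing a sorted uniform draw
    pos = np.sort(rng.choice(length - n_events + 1, size=n_events, replace=False))
    pos = pos + np.arange(n_events)  # enforce gaps >= 1 between events
    kinds = (["transition"] * n_transitions + ["transversion"] * n_transversions
             + ["indel"] * n_indels)
    rng.shuffle(kinds)
    alt = ref.copy()
    for p, kind in zip(pos, kinds):
        base = ref[p]
        if kind == "transition":
            alt[p] = TRANSITION[base]
        elif kind == "transversion":
            alt[p] = rng.choice(list(TRANSVERSIONS[base]))
        else:
            alt[p] = "-"
    return AlignedFragmentPair(
        fragment_id=fragment_id,
        seq_a="".join(ref),
        seq_b="".join(alt),
        source_strains=("ref", "mut"),
    )
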