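# Methods

This note documents the statistical models and procedures implemented
in `clonepop`, the choices made where the design was genuinely open,
and what the synthetic-data calibrations do and do not establish.

## Data model

A genotype matrix holds `n` haploid isolates scored at `L` loci. Allele
codes are opaque small integers per locus — RFLP banding patterns carry
no biological ordering, so no statistic in the package assumes one.
Missing calls use a sentinel (−1). Each isolate carries a nested
region/population label pair (each population belongs to exactly one
region), a habitat label, decimal-degree coordinates and altitude in
metres (negative altitudes are legal: below-sea-level sites exist).

**Clone correction.** Isolates with identical multilocus genotypes are
treated as members of one clone and collapsed to their first occurrence,
with multiplicities recorded. Two isolates match only if they agree at
every locus *including the missing pattern*; this is conservative — an
incomplete genotype is never merged into a complete one, so clone
correction can only under-collapse in the presence of missing data.
Dataset-level scope is the default; population-level scope (one entry
per genotype per population) is available because per-population
batteries naturally re-admit genotypes shared across populations.

## SNP discovery

Fragment pairs from two strains are globally aligned
(Needleman–Wunsch, linear gap; default match/mismatch/gap = +1/−1/−2)
with a fixed tie-break (diagonal first, then gap in the second
sequence) so alignments are reproducible. Substitution columns are
classified transition vs transversion by the purine/pyrimidine rule.
A maximal run of gap columns counts as **one** indel event by default:
single mutational events commonly insert or delete several adjacent
bases, and counting columns would conflate event counts with event
lengths (a per-column mode exists). Columns containing N are excluded
from both site and SNP counts. The aggregate report carries per-fragment
and overall SNP percentages (100 × SNPs / compared sites) and the
transition:transversion ratio computed directly from the class counts.

## Diversity and distances

Two indices are computed per population and labelled explicitly,
because field software is inconsistent about what "genotype diversity"
means:

- mean unbiased gene diversity over loci,
  `h_j = n/(n−1) · (1 − Σ_a p_{ja}²)` (undefined at n = 1, reported as
  missing);
- Simpson genotypic diversity over clone multiplicities,
  `1 − Σ_k (c_k/n)²`.

Neither is claimed to reproduce any particular published "multilocus
genotype diversity" column; survey tables often use unstated formulas.

The locus-saturation curve subsamples `k` of `L` loci without
replacement and averages the distinct-genotype count; at `k = L` the
value is exact.

Nei's (1972) standard distance between allele-frequency profiles is
`D = −ln(J_XY / √(J_X J_Y))` with the J's locus-wise means of
`Σ x y`, `Σ x²`, `Σ y²`. Populations sharing no alleles anywhere give
`J_XY = 0`, reported as `+inf` rather than an arbitrary cap. Geographic
distance is 2-D great-circle (haversine, R = 6371 km) on population
coordinates; altitude differences form a separate matrix and are never
folded into a 3-D distance — the two axes answer different questions.

The Mantel statistic is the Pearson correlation of off-diagonal
entries; the null permutes rows and columns of the second matrix
simultaneously. P uses the add-one convention
`(1 + #{r_perm ≥ r_obs})/(1 + n_perm)`; for ≤ a handful of items an
exact mode enumerates all n! permutations, counting ties (within 1e−9)
as extreme.

## Hierarchical partitioning

**PCA** operates on centred population × allele-frequency vectors, one
column per allele with the locus's reference allele dropped (the
frequencies are affinely dependent within a locus). Component signs are
fixed by making the largest-magnitude loading positive.

**AMOVA.** The individual-level distance is the number of differing
loci (squared Euclidean on allele-mismatch indicators — the natural
metric for unordered alleles; alternative metrics are out of scope).
Sums of squares follow the standard nested decomposition computed from
the distance matrix; variance components come from the mean squares via
the unbalanced-design coefficients. Negative components are *retained*
for the Phi statistics (truncating first would bias Phi toward zero)
and truncated to zero for the percentage column, and both are reported.
Permutation schemes match the stratum each Phi tests: PhiPT permutes
individuals among all populations, PhiPR permutes individuals among
populations within their region, PhiRT permutes whole populations among
regions. Note the PhiRT null is coarse when regions and populations are
few (the number of distinct relabelings bounds the attainable P).

**θ.** The haploid Weir & Cockerham moment estimator: per allele,
`MSP = Σ_i n_i (p_i − p̄)² / (r−1)`,
`MSG = Σ_i n_i p_i (1−p_i) / Σ_i (n_i − 1)`,
`n_c = (N − Σ n_i²/N)/(r−1)`, and
`θ = Σ (MSP − MSG) / Σ (MSP + (n_c − 1) MSG)` with sums over alleles
and loci (ratio-of-sums weighting). Loci monomorphic in the pooled
sample contribute 0/0 and are excluded. The randomization shuffles
individuals among groups, preserving group sizes; this also destroys
any linkage disequilibrium between groups, which we treat as equivalent
to randomizing alleles per locus for the purpose of the test.

Permutation P values throughout the partitioning and association
modules use the add-one convention with 999 permutations by default.

## Clonality and recombination battery

All association tests are defined for any genotype matrix; the standard
field workflow applies them to clone-corrected data (pseudo-replicated
clones otherwise dominate), while calibrations on simulated data with
known clonal repetition use the uncorrected matrix — the signal *is*
the repetition there.

**I_A / r̄d.** Population variances over all n(n−1)/2 pairs, consistent
in numerator and denominator. Loci monomorphic in the sample have zero
mismatch variance and drop out of both sums. The null shuffles each
locus column independently; the one-tailed test counts
`r̄d_perm ≥ r̄d_obs`. Note that for a *single* complete two-locus
design {00, 01, 10, 11} the finite-sample I_A is −0.5 (pairs are drawn
without replacement, inducing negative covariance between loci); I_A
approaches 0 only as such a design is replicated. The tests encode both
facts.

**Pairwise LD.** The per-pair statistic is the two-locus restriction of
r̄d with its own permutation P; pairs with a monomorphic member are
non-testable. The summary is 100 × significant / testable pairs.

**Compatibility.** Two loci are compatible iff the bipartite graph on
observed (allele_j, allele_k) combinations is acyclic; for biallelic
loci this is exactly the four-gamete test ("all four combinations
observed" ⇔ incompatible). The multiallelic generalization via graph
acyclicity is this package's choice. PrC is the proportion of
compatible pairs over all pairs (monomorphic pairs are trivially
compatible). IR divides the observed incompatible-pair count by the
*mean* count over shuffled datasets (default 1000 shuffles; a single
shuffled dataset would make IR needlessly noisy). The PrC permutation
counts `PrC_perm ≥ PrC_obs`, since clonality inflates compatibility —
a maximally diverse sample where every pair shows four gametes yields
PrC = 0 with P = 1.

**PTLPT.** Isolates are taxa; loci are unordered multistate characters
scored by Fitch's algorithm (unit cost; missing = any observed state;
the pass roots arbitrarily and the count is rooting-invariant). The
shortest tree is found exactly by enumerating all unrooted topologies
up to 9 taxa in `mp_search`, and above that by random-order stepwise
addition followed by NNI hill-climbing, best of several restarts.
Inside the permutation test the exhaustive cutoff defaults to 7 taxa:
scoring 10⁴–10⁵ topologies per shuffled dataset is two orders of
magnitude too slow for 1000-replicate nulls, and the heuristic matched
the exact optimum in ≥95% of seeded trials at these sizes. Identical
search settings are applied to observed and shuffled datasets, so the
comparison is internally unbiased even when lengths are not certified
optimal. Duplicate genotypes are collapsed before the search — the
minimum length is invariant to duplicates (they attach as zero-length
cherries), so this is an exact optimization, not a setting. P is the
plain fraction `#{L_perm ≤ L_obs}/n_perm` (matching the convention in
which an observed length below the whole null range prints as
"< 1/n_perm"), reported as a label when zero.

## Synthetic data

The generator emulates the features the analyses assume, with known
parameters:

- **Differentiation**: per-population allele frequencies drawn from the
  Balding–Nichols Beta/Dirichlet around ancestral frequencies with a
  specified F — chosen precisely because it gives a known recovery
  target for θ.
- **Clonality**: within each population the first `founders` isolates
  are independent draws; each later isolate copies a uniformly chosen
  founder with probability `c` (then mutates each locus with a small
  rate, default 10⁻³ per locus per copy), else is a fresh recombinant
  draw. Founder copying reproduces the few-genotypes-at-high-
  multiplicity pattern of real clonal samples.
- **Geography**: synthetic populations sit on a latitude line with
  increasing altitude, so geographic distance is controllable; a
  dedicated isolation-by-distance generator random-walks allele
  frequencies along the line for Mantel power checks.
- A fixed survey-design generator reproduces a published sampling
  layout — 228 isolates in 10 subpopulations (sizes 29, 21, 28, 20, 30,
  21, 29, 16, 5, 29) across 6 regions with the printed coordinates and
  altitudes, 12 biallelic loci — with clonality and differentiation
  left free.

What the generator does **not** emulate: genealogical structure among
founders (founders are independent draws, so clone-corrected clonal
data carries no residual tree signal — real clonal lineages accumulate
mutations and do), linkage maps (loci are exchangeable), null alleles
or scoring error, and migration beyond a crude ancestral-pool draw.
Passing calibrations therefore demonstrate estimator correctness under
the stated models, not robustness to these real-data complications.

## Calibration sizes and outcomes checked by the test suite

- θ recovery: 20 populations × 50 isolates, 100 biallelic loci,
  F = 0.2 → θ̂ within [0.15, 0.25].
- r̄d test: type-I error within 0.05 ± 0.025 over 500 panmictic
  replicates (n = 30, L = 12, 199 permutations); power > 0.9 over 500
  five-founder clonal replicates.
- PTLPT: over 30 replicates of a 10 × 8 design, P ≤ 0.05 in ≥ 90% of
  five-founder clonal samples and P > 0.05 in ≥ 90% of panmictic
  samples (99 permutations, 2 restarts).
- IR within 1 ± 0.05 on a panmictic 100 × 12 sample (200 shuffles).
- Monotone concordance across clonal fractions {0, 0.5, 0.9, 1}:
  median r̄d and PrC non-decreasing, median PTLPT P non-increasing,
  with strict movement across the full range (matched seeds).

These sizes were chosen as the smallest designs at which the quantities
stabilize; `scripts/acceptance.py` recomputes the same battery (300
replicates for the r̄d rates) from any `--seed`.

## Numerical and degenerate-input conventions

- Permutation P: add-one `(1 + b)/(1 + N)` everywhere except PTLPT
  (plain fraction, see above); P is never reported as exactly zero
  outside PTLPT's labelled bound.
- Nei distance clamps tiny negative logs to 0; disjoint profiles give
  +inf.
- A population of one isolate: unbiased gene diversity is reported
  missing, not extrapolated.
- AMOVA requires ≥ 2 regions, nesting, and within-population
  replication; degenerate designs raise rather than silently collapsing
  strata, and the pipeline records the skip.
- Allele codes are capped at 62 per locus (packed 64-bit state masks in
  the parsimony scorer); RFLP panels have ≤ a handful.
- All generators and tests are deterministic under a fixed seed; stage
  seeds in the pipeline are spawned from the master seed via
  `SeedSequence`.

## Known limitations

- The AMOVA unbalanced-design coefficients are verified against direct
  nested-ANOVA algebra on balanced designs and on printed-table
  arithmetic; fully unbalanced cases are checked only for internal
  consistency (df/SS/MS identities, %var = 100).
- mp_search above the exhaustive limit is a local search; lengths are
  upper bounds. The PTLPT is insulated by using identical settings on
  both sides, but a single reported tree is not guaranteed optimal.
- The pairwise-LD per-pair P values are not multiplicity-adjusted; the
  percent-significant summary inherits the nominal per-pair α, as is
  conventional for this descriptive statistic.
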