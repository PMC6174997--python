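# Methods

This note records the models implemented in `namrecomb`, the defaults and
why they were chosen, what the synthetic data do and do not emulate, and
the numerical conventions a user should know before trusting a result.

## Meiosis and inbreeding model

Crossovers are a homogeneous Poisson process on genetic distance (Haldane
model): a chromosome of length *L* cM receives on average *L*/100
crossovers per meiosis, with no interference and no obligate crossover.
This keeps the cM unit exact by construction and admits closed-form
oracles (Haldane map function, RIL expansion *R* = 2*r*/(1+2*r*),
junction-accumulation limits). Real wheat meiosis shows positive
interference and obligate crossovers; consequences are discussed under
*Limitations*.

Families are produced by single-seed descent: the F1 (common parent ×
founder, heterozygous at every founder-divergent locus) is selfed
`n_generations − 1` times, each selfing drawing two independent meioses.
At F7 the expected residual heterozygosity is (1/2)⁶ ≈ 1.56% per locus
(measured 1.55% at n = 2000 lines).

Two truth quantities are recorded per RIL and deliberately kept distinct:

* `junctions_true` — the mean junction count of the two final haplotypes.
  Its density approaches the Haldane–Waterman limit of 2 junctions per
  Morgan in fully inbred selfed lines; at F7 the theoretical value is
  2·(1−2⁻⁶) = 1.969/Morgan and the simulator measures 1.96–1.98.
* `tco_true` — the observable phase-change count after residual
  heterozygous segments are masked (what a dense, error-free genotype
  matrix shows once heterozygous calls are set to missing). It sits ~4–5%
  below `junctions_true` at F7 because junctions adjacent to heterozygous
  residue are hidden; the two converge with further inbreeding.

## Recombination modifiers

A modifier is a locus with multiplicative effect on meiotic crossover
intensity: a plant with high-allele dosage *d* ∈ {0, ½, 1} recombines at
`1 + Σ β·d` times the base rate within the modifier's scope (whole genome,
its own chromosome, or the pericentromeric arm regions of every
chromosome). Heterozygous dosage ½ means the modifier's influence changes
as it segregates during inbreeding, so the RIL-level effect in crossover
units is *emergent*: roughly one third of β times the baseline crossover
count, because the F1 meiosis (which contributes half of all junctions)
sees dosage ½ in every lineage and the later meioses only gradually
diverge between lineages that fix the high or the low allele. The package
therefore measures effects rather than asserting them:
`realized_modifier_effect` (difference in mean true junction count between
fixed classes) and `experiments._calibrate_observed` (the same difference
on the *called* phenotype), and calibrates β against a target effect by
iterated scaling.

Calibration for the QTL studies targets the called-phenotype scale: finite
marker resolution loses proportionally more double crossovers in
high-intensity lines, so a modifier that adds +5 true junctions may add
only +4 called crossovers. Since mapped QTL effects are always reported in
called-crossover units, that is the scale on which "+4 CO" is defined
here.

## Crossover calling

Per RIL and chromosome, calls are ordered by map position, missing (and
recoded heterozygous) calls dropped, the remainder compressed into
maximal same-phase runs; runs shorter than *k* (default 2) — including
terminal runs — are discarded as probable genotyping or map-placement
error, adjacent surviving equal-phase runs merged, and one crossover
emitted per remaining transition, placed at the genetic midpoint of the
flanking informative interval. The two-marker rule trades a known loss of
genuine tight double crossovers for robustness to isolated miscalls: under
per-marker error ε with M informative markers, the single-marker rule
calls ≈ 2εM spurious extra crossovers per RIL, which the two-marker rule
suppresses (verified within 15% of 2εM at ε = 0.005, M ≈ 2000). Double
crossovers inside one marker interval are undetectable by construction.

Redundancy collapse groups markers that agree at every RIL where both are
typed and share at least `min_overlap` (default 15) informative RILs,
closing the relation transitively; the delegate is the member with fewest
missing calls. Collapse is exactly lossless for single-marker-rule calling;
under the two-marker rule a run supported only by bin-redundant markers
loses support when collapsed, a deliberate consequence of counting
redundant markers as genuine support.

## Arm partition and trait decomposition

Each chromosome arm is split at a fixed fraction from the telomere
(default 1/3): the outer third is *distal*, the inner two thirds
*pericentromeric*; a breakpoint exactly on the boundary counts as
pericentromeric. TCO = pCO + dCO = Σ per-chromosome counts always holds.
The partition is computed on genetic coordinates by default (physical
coordinates can be supplied through the genome model).

## QTL mapping

Single-family scans use regression (Haley–Knott) composite interval
mapping: the expected alternate-allele dosage at a test position is the
two-flank conditional expectation under a symmetric two-state chain with
RIL-expanded Haldane transition probabilities (observed call at typed
markers, 0.5 with no informative flank). Cofactors come from
forward/backward stepwise selection at p = 0.01 both ways; cofactors
within 10 cM of the test position are dropped at that position.
LOD = (*n*/2)·log₁₀(RSS_reduced/RSS_full). Genome-wide thresholds are
empirical (1−α) quantiles of max-LOD over phenotype permutations; the
data-selected cofactors are reused across permutations by default
(`reselect=True` redoes selection per permutation). This reuse is mildly
anticonservative — measured genome-wide false-positive rate ≈ 9.5%
instead of 5% on null families — because cofactors chosen on the real
phenotype deflate the permuted max-LOD; the null-calibration study
therefore evaluates the plain interval scan (measured 4–8.5% across
seeds), and users wanting exact calibration with cofactors should pass
`reselect=True`. Peaks above the threshold get 2-LOD support intervals
(contiguous grid run with LOD ≥ peak − 2); distinct peaks must be ≥ 20 cM
apart or separated by a ≥ 2-LOD valley. Effects are signed positive when
the common-parent allele increases the trait.

Joint mapping enters each locus as a block of family-nested dosage effects
on top of per-family intercepts (all design columns have single-family
support, so the least-squares problem separates by family — used for
speed). Forward selection stops when no locus beats `p_enter` (default
1e-4) on the block F-test; model R² is non-decreasing along the path. The
joint interval scan compares family-intercepts-only against nested-dosage
models on a grid, with thresholds from within-family permutations.

## Cis/trans classification

For each significant QTL the phenotype is recomputed without the
harbouring chromosome (TCO) or without the matching arm region (pCO/dCO),
and the scan repeated from scratch with reselected cofactors and a fresh
5% permutation threshold. The QTL is *trans* if a significant peak recurs
at the original locus — support intervals intersecting (closed intervals:
sharp peaks can give single-grid-point intervals) or peaks within 10 cM
(2-LOD intervals understate peak wander between scans of the same data; at
the study conditions the strict interval-intersection rule misclassified
~20% of genuinely global modifiers). Measured operating characteristics at
n = 200, 20 + 20 replicates: sensitivity 1.0 on global modifiers,
specificity 1.0 on single-chromosome modifiers.

## Additivity of stacked alleles

The allele-stacking analysis regresses the phenotype on the number of
recombination-increasing alleles carried at the QTL peak markers
(orientation from the per-family effect signs; lines missing or
heterozygous at any peak marker are dropped). Because modifier dosages
enter the meiotic intensity linearly, stacked effects are near-additive;
the reference per-allele effect is measured independently by Monte Carlo
at the same β, and the study condition (four equal modifiers on separate
chromosomes of a 12-Morgan genome, n = 600) recovers it within a few
percent (ratio ≈ 0.98). Note that junction-count variance under
segregating modifiers is roughly twice Poisson (intensity heterogeneity
across generations), so R² of the allele-count regression is ~0.12–0.24 —
lower than a Gaussian-noise intuition would suggest — while the slope
remains the meaningful quantity. Pericentromeric-scoped modifiers raise
pCO with no detectable dCO response.

## Load, LD and IBD contrasts

Chromosomes are cut into equal genetic bins; high-recombining bins are
those whose scaled midpoint lies in the distal 10% of either end. The load
contrast is a one-sided Fisher exact test for a *lower*
deleterious/(deleterious+non-deleterious) proportion in the high class
(p equals the hypergeometric tail by construction). The annotation
simulator draws SNP deleterious flags with odds θ-fold higher in
non-high bins (θ = 2 detected in ≥ 90% of replicates at 10⁴ SNPs).
Founder LD is the mean pairwise squared Pearson correlation of allele
indicators per bin (monomorphic markers excluded; bins with < 2 usable
markers dropped); for independent loci across n founders E[r²] ≈ 1/(n−1),
which the tests verify. The LD-generating option of the founder simulator
is a Markov copying chain whose decay rate tracks a local intensity
profile — a deliberately simple stand-in for coalescent LD that produces
the qualitative negative LD–recombination relationship (measured Pearson
r ≈ −0.95 on the synthetic study). The IBD contrast compares per-region
crossover counts (region is IBD when ≥ 50% covered by the family founder's
IBD tracts) with a Mann–Whitney U test; U is reported for the IBD sample
(pairs where an IBD count exceeds a non-IBD count, ties half), one-sided
for *more* crossovers in IBD regions.

## Study conditions used by the validation studies

Chosen once as desk-scale analogues; `scripts/acceptance.py` and
`tests/test_acceptance.py` use exactly these:

| study | genome | n lines | other |
|---|---|---|---|
| junction accumulation | 8 × 300 cM (24 Morgan) | 2000 | F7; mean ≈ 47.1 junctions vs limit 48 |
| residual heterozygosity | 2 × 100 cM | 2000 | F7 |
| CO caller | 8 × 300 cM, 2000 markers | 150 | ε = 0.005 |
| QTL recovery | 3 × 200 cM, 1 marker/cM | 150 × 20 reps | +4 CO calibrated, 200 perms |
| cis/trans | 3 × 200 cM | 200 × (20+20) reps | +4 CO calibrated |
| additivity | 4 × 300 cM | 600 | 4 × +3 CO modifiers |
| null scan calibration | 3 × 200 cM | 100 × 200 reps | no cofactors |
| null joint model | 3 × 200 cM | 5 × 80 × 20 reps | p_enter 1e-4 |
| load contrast | 24-Morgan bins | 10⁴ SNPs × 20 reps | θ = 2 |

The 24-Morgan genome gives selfed RILs a mean total of ≈ 48 junctions —
the scale of a hexaploid wheat map — while the QTL studies use 6–12-Morgan
genomes so that a +4-crossover effect is a realistically detectable
fraction of the phenotype variance at family sizes near 150 (on a
24-Morgan genome the same absolute effect drowns in the ~√48 junction
noise and no scan of this type could reach 80% power).

The fully divergent founder pair (every marker informative) realizes the
one-informative-marker-per-cM condition of the QTL studies; with MAF-0.5
founders roughly half the markers segregate per family, which is what the
pipeline's default configuration uses for realism.

## What the synthetic data do not emulate

No crossover interference or obligate crossover; no selection during
inbreeding; founder haplotypes have no coalescent genealogy (LD is a
copying-chain surrogate); genotyping error is independent per call rather
than clustered by marker or line; IBD tracts are injected, not inferred;
and marker density is uniform rather than concentrated in genic regions.
Passing tests therefore demonstrate the correctness and calibration of the
algorithms under the stated stochastic model, not the biological fidelity
of that model to any particular dataset.

## Numerical conventions

0-based cM floats; half-open `[start, end)` intervals everywhere except
2-LOD support intervals (closed grids) and the pericentromeric side of the
arm-partition boundary (closed); permutation quantile = order statistic
`ceil((1−α)·n_perm)`; stepwise ties break toward the lower marker index;
delegate ties break toward map order; all simulation randomness flows from
a single integer seed through fixed arithmetic, and identical seeds give
byte-identical pipeline output.
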