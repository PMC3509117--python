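# Methods

This note documents the statistical machinery of `ystrpop`: the estimators
and their conventions, the network algorithms, the simulation model, and
the choices made where the literature leaves the design open.

## Data model

A haplotype is a vector of non-negative integer repeat counts on an ordered
locus panel. Three pairwise metrics are used throughout: the
**allele-difference** (number of loci with different alleles), the
**step-difference** (sum over loci of |Δ repeats|, the single-step mutation
count if every step is visible), and the **squared-step** distance (sum of
squared differences, the quantity with linear time-expectation under the
stepwise mutation model). Diversity and AMOVA default to the
allele-difference metric — the conventional "number of different alleles"
choice for haplotypic STR data — while network branch lengths and ρ dating
use step-differences and Rst/TD use squared steps. Every function exposes
the metric argument.

Raw 17-locus Yfiler panels are reduced to 15 analysis loci by dropping the
multicopy DYS385a/b pair (its two values cannot be assigned to copies, so
step distances are undefined) and scoring DYS389II minus DYS389I (the
DYS389II amplicon physically contains DYS389I). Both rules are configurable
(`PanelRules`); they follow standard Yfiler practice rather than any single
study's unstated convention. Rows with missing repeat values are dropped
with a warning by default; a strict mode raises instead, because all the
statistics here assume complete haplotypes.

## Diversity estimators

* **HD** = n/(n−1)·(1 − Σpᵢ²) over haplotype frequencies pᵢ. The SD is
  Nei's (1987) sampling variance of gene diversity,
  V = 2/(n(n−1))·{2(n−2)[Σp³ − (Σp²)²] + Σp² − (Σp²)²}. For a sample of 13
  singletons this gives HD = 1.0000 ± 0.0302, matching published ± values
  for all-distinct Y-STR samples.
* **MPD** is the mean metric value over all unordered pairs of individuals
  (pairs within a repeated haplotype contribute zero). The SD is Tajima's
  total (sampling + genealogical) variance in the form
  V = b₁π + b₂π², b₁ = (n+1)/(3(n−1)), b₂ = 2(n²+n+3)/(9n(n−1)), which is
  defined for every n ≥ 2. Published MPD ± values in this literature come
  from unstated estimators and are not asserted against this choice.
* **Repeat variance** is the mean over loci of the per-locus sample
  variance (n−1 denominator).
* The **modal haplotype** is the most frequent whole haplotype, ties broken
  by the lexicographically smallest repeat vector; a per-locus-mode
  (consensus) variant is available and is the default *root* for
  whole-population expansion dating (below).
* **AMD** is the mean metric distance of individuals from a reference
  haplotype. The modal haplotype does not in general minimise AMD, and no
  such property is assumed.

## Between-population statistics

**PiXY** is the mean metric value over all nA×nB cross-population pairs
(self-pairs included when the populations share haplotypes). **(δμ)²** is
the mean over loci of the squared difference in mean repeat count; under
SMM its expectation grows as 2μt with divergence time, which the test suite
verifies by simulation.

**AMOVA** follows the distance-matrix formulation: the metric value of a
pair enters the sums of squares directly as the squared distance. Two-level
(among/within populations) and three-level (among groups / among
populations within groups / within populations) designs are implemented
with the standard n-coefficients for unequal sample sizes; Φ_ST, Φ_SC and
Φ_CT are ratios of the raw variance components. Raw components may be
negative; reports clamp them (and pairwise Rst values) at zero while the
result object retains the raw estimates. A label-permutation test for Φ_ST
is provided (seeded, configurable count) but no published p-values are
reproduced because none are printed in this literature. Pairwise **Rst**
is the two-population Φ_ST under the squared-step metric, verified in the
tests against an independent brute-force sums-of-squares implementation.
A single printed "Fst" for a two-group comparison does not identify which
Φ was meant; the group-comparison report therefore prints Φ_ST by default
and exposes Φ_CT/Φ_SC alongside.

**MDS** is classical (Torgerson) scaling: double-centre the squared
distance matrix, eigendecompose, scale eigenvectors by the square roots of
the non-negative eigenvalues. The full eigenvalue spectrum is returned so
negative-eigenvalue mass (non-Euclidean input) is visible rather than
silently discarded. SMACOF-style stress majorisation is deliberately not
used: the classical solution is deterministic and exactly recovers
Euclidean configurations, which the tests assert to Procrustes RMS < 1e-8.

## Haplotype networks

The **minimum spanning network** is the union of all minimum spanning
trees: an edge at distance d is kept iff its endpoints are in different
components of the graph formed by all strictly shorter pairs (single-pass
Kruskal over equal-weight tiers). A tolerance ε ≥ 0 relaxes the threshold
to d − ε. Distances are weighted step-differences; the default weight is a
uniform 10 per locus, the convention of the widely used network software
for STR data. Haplotypes and candidate medians are processed in
lexicographic order, so networks are reproducible.

The **median-joining** construction iterates: build the MSN over the
current node set; for every connected triplet (two of its three links
present) compute the quasi-median (per-locus median of the three repeat
vectors, which for the L1 step metric achieves the half-perimeter Steiner
cost); add each new vector whose star connection is strictly cheaper than
linking the triplet pairwise; repeat to a fixed point (an iteration cap
guards termination, which is guaranteed because quasi-medians stay inside
the coordinate bounding box). Leaf median vectors are removed at the end —
they can lie in no shortest connection of observed nodes.

**Maximum-parsimony pruning** keeps exactly the links and median vectors
contained in at least one minimum-total-length tree that spans all observed
haplotypes (medians optional). It enumerates median subsets, takes the MST
of each connected induced subgraph, and applies the cut rule (an edge is in
some MST iff strictly shorter edges leave its endpoints disconnected) over
every optimal subset. The search is exponential in the number of medians
and is capped (default 16; callers choose error or skip on overflow); the
pipeline skips pruning on large simulated networks. On small instances the
tests verify the output against exhaustive enumeration of all spanning
structures.

**Founder clusters.** Roots are network nodes carrying both focal and
source population labels — shared haplotypes, the natural founder
candidates — or, failing that, focal nodes adjacent to a source-carrying
node. Each focal node joins the root with the shortest network path that
passes through no other root (ties to the lexicographically smallest
root; if every path crosses another root, plain shortest distance decides).
Published founder assignments were made by eye on network diagrams, so a
user-supplied assignment can replace the automatic rule to reproduce a
published clustering exactly.

## Dating

With L loci mutating at rate μ per locus per generation:

* **ρ** is the multiplicity-weighted mean step distance from the root;
  t̂ = ρ/(L·μ) generations. The SD follows Saillard's estimator
  σ² = Σ_b l_b·n_b²/n² over genealogy branches (l_b mutations, n_b
  subtended samples); without a genealogy a star is assumed, giving
  σ = √(Σdᵢ)/n.
* **TD/ASD**: the mean squared repeat difference from the founder per
  locus; t̂ = ASD/μ. Its SD propagates the across-locus standard error of
  the per-locus ASD values.
* μ defaults to 6.9×10⁻⁴ per locus per generation — the evolutionary
  effective Y-STR rate calibrated on 25-year generations — and years are
  obtained by multiplying generations by the generation time (default
  25 y). A germline-rate alternative is a parameter change, not a code
  change.
* The **founder-age summary** across clusters is the unweighted mean age ±
  the unweighted mean of cluster SDs, the convention of founder-analysis
  summary rows in this literature (it exactly reproduces the published
  1405 ± 688 from the three cluster rows 1110±785 / 1024±407 / 2081±873);
  inverse-variance weighting is available by pre-weighting the inputs.
* **Whole-population expansion ages** treat the population as a star
  around a central haplotype. The default centre is the per-locus
  consensus: in an old expansion every sampled haplotype can be unique, so
  the whole-haplotype mode degenerates to an arbitrary tie-break far from
  the centre and inflates ρ roughly two-fold, while the consensus
  approximates the founder. Published per-region ages used an unstated
  rooting and are not reproduced exactly; only orderings are meaningful,
  and the tests assert ordering on simulated expansions of known depth.

**Estimator bias under SMM.** ρ counts net, not actual, mutational steps:
multi-hit loci partially cancel, giving a downward saturation bias of
about 3% of t at μt ≈ 0.07 per locus and ~20% at μt ≈ 0.5 (the Poisson
multi-hit calculation, confirmed by simulation). TD is exactly unbiased
under single-step SMM because the squared displacement of a ±1 walk has
expectation equal to its step count. Recovery tests therefore assert that
the mean recovered age lies within two single-replicate standard errors of
the truth, a band that accommodates ρ's small-depth bias; at star depths
≤300 generations ρ and TD agree within 10% in expectation, which is tested.

## Simulation model

Mutations are single-step and symmetric (±1 with equal probability), with
no allele-range constraints; counts that drift below 1 are floored at 1
only when a sample is materialised, with a warning (relevant only at
unrealistically deep times × rates). Star populations draw, per individual
and locus, Poisson(μt) steps. Coalescent populations use an msprime
Kingman genealogy (haploid, no recombination) with SMM mutations dropped
on branches here. All generators are deterministic under their seed;
sub-streams are spawned per population, and msprime seeds are derived from
the same stream.

The **diaspora scenario** encodes the study conditions this package is
aimed at: three source populations as star expansions 720/640/1000
generations deep (18/16/25 KYA at 25 y/generation, the published range of
regional expansion ages) with n = 40/30/30, and three focal populations
(n = 20/30/40, the published diaspora sample-size scale) each founded by a
single haplotype drawn from the first source population's sample 56
generations (1400 years) ago — the published mean founder age. Regional
source founders drift 300 generations from a common ancestral haplotype so
the sources are differentiated. The ground truth (founders, times,
per-individual founder assignment) is returned and serialisable to JSON.

What the generator does **not** emulate: population growth curves and
post-founding drift (each population is a pure star or a constant-size
coalescent), migration and admixture after founding, locus-specific
mutation rates, multi-step mutations, and genotyping artefacts. Passing
recovery tests therefore demonstrate estimator correctness under the
stated model, not robustness to those real-data complications.

## Problem sizes and numerical conventions

Replicate counts in the tests (e.g. 100 star replicates of n = 200 for
dating recovery, 50 scenario replicates for the pipeline check, 200 random
draws for the AMOVA cross-check, exhaustive network search on ≤6-haplotype
instances) were chosen to keep Monte-Carlo error well below the asserted
tolerances while the whole suite runs in a few minutes on one CPU. Ties are
always broken lexicographically; floating-point comparisons in the network
code use a 1e-9 slack on lengths; Φ statistics are reported as 0 when the
total variance is non-positive; reports round ages to whole years or to
two decimals in KYA. Degenerate inputs (n < 2 estimators, empty
populations, panel mismatches, groups without within-population degrees of
freedom) raise `ValueError` with the offending quantity named.

## Known limitations

* The exact estimators behind published ± values for MPD, and the rooting
  behind published per-region expansion ages, are not identifiable from
  the printed tables alone; this package documents its own choices and
  asserts only what those choices can legitimately reproduce.
* MP pruning is exact but exponential in the number of median vectors;
  large median-joining networks are exported unpruned (with a warning path)
  rather than approximately pruned.
* ρ dating saturates at deep times under SMM (see above); for expansion
  ages ≳500 generations the TD statistic or a rate recalibrated for
  saturation is preferable.
* The automatic founder-assignment rule is a deterministic proxy for what
  is, in the source literature, a manual reading of network diagrams; the
  override input exists precisely because the two can differ.
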