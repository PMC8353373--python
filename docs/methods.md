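# Methods

This note records the models behind each stage, the parameters that
matter, the numerical choices, and what the synthetic-data validation
does and does not demonstrate.

## Genotypes, coordinates and QC

A panel is a samples × markers matrix of minor-allele dosages {0, 1, 2}
with a distinct missing sentinel, never conflated with dosage 0. All
coordinates are 1-based inclusive base pairs; BED input is converted on
read. Genetic positions use the bovine rule of thumb 1 Mb = 1 cM
(10⁻⁸ Morgan/bp); chromosome labels are opaque strings, so sex or
unplaced contigs are excluded only if the caller subsets them.

The minor allele is defined per marker from the parsed panel; an exact
0.5/0.5 tie resolves to the lexicographically smaller allele symbol so
parsing is deterministic. QC removes markers with call rate <0.95 or
MAF <0.01 (MAF over non-missing calls only), then samples with call rate
<0.85 on the retained markers. The pass is single-shot by design — marker
statistics are not recomputed after sample removal — which makes the
filter deterministic and idempotent whenever the sample filter is not
binding. Removing every marker raises an explicit "empty panel" error.

## LD decay (Sved fit)

The LD statistic is the composite (Rogers–Huff style) r²: the squared
Pearson correlation of unphased dosage vectors over samples non-missing
at both markers. Pairs are restricted to the same chromosome and to both
an index-separation limit (default 5 SNPs) and a physical limit (default
1,000 kb); the *N*e stage overrides both because it needs pairs out to
12.5 Mb. Zero-variance or <2-complete-sample pairs are skipped.

The decay model E[r²] = 1/(1 + 4βd) is fit by bounded nonlinear least
squares (trust-region reflective). The start value β₀ = 1/(4·median d)
puts the curve's half-decay point mid-cloud; on failure up to five
restarts perturb β₀ by factors 10±1, 10±2, 10³. Tolerances are set to
machine precision (xtol = ftol = gtol = 5 × 10⁻¹⁶) with an analytic
Jacobian, so noiseless clouds are recovered exactly. The standard error
comes from the asymptotic covariance; residuals are treated as
homoscedastic Gaussian with no pair weighting. β̂ scales inversely with
the distance unit (kb vs bp), so unit errors are detectable by eye.

Curve equality is tested pairwise by the Wald statistic
z = (β̂ₐ − β̂ᵦ)/√(SEₐ² + SEᵦ²) with two-sided normal p-values and
Bonferroni adjustment across the pairs — the minimal test consistent
with comparing the curves through their decay coefficients. Breeds are
grouped by Ward/Euclidean agglomeration of the scalar β̂ values; the cut
k is user-set or chosen by maximum mean silhouette over k ∈ [2, min(8,
n−1)]. The silhouette stands in for multi-index consensus voting; k is
always overridable. The dendrogram exports as newick with merge heights
as branch lengths.

## Effective population size

Each distance bin with representative distance c Morgan yields
Ne = (1/4c)(1/r̄² − 1) for generation T = 1/(2c). The four bins are
(0, 0.01], (0.01, 0.03], (0.03, 0.05] and (0.05, 0.125] Morgan. Two
deliberate conventions:

* the representative c per bin is 1/(2T) for T = 50, 16.6…, 10, 5 — not
  the empirical mean pair distance — so reported generations are exact;
* the open-ended ">0.05" bin is capped at 0.125 Morgan (12.5 Mb);
  the cap is configurable.

Bin means are arithmetic; empty bins are flagged, never fabricated, and
r̄² = 0 is rejected rather than returned as infinite Ne. No 1/n sampling
correction is applied to r̄². Consequences at small samples: sampling
inflates r̄² by ≈1/n for unlinked dosages, and bin-averaging a convex
curve inflates it further, so the estimator is biased low — a constant
N = 100 simulation sampled at n = 50 reads out at roughly 50–70 across
all four generations. The validation band ([50, 200]) is set around that
known bias; trajectory *shape* (e.g. a recent contraction showing as
Ne(T=5) ≪ Ne(T=50)) is recovered much more reliably than level, which is
how such trajectories should be read in practice. The oldest-vs-newest
contrast ΔNe = Ne(T=50) − Ne(T=5) is reported per population.

## Runs of homozygosity

Window scan: a window of 50 consecutive markers is homozygous iff it
holds ≤1 heterozygote (dosage 1) and ≤5 missing calls; missing never
counts as heterozygous. A marker's score is the homozygous fraction of
the windows covering it, with the reduced denominator at chromosome
edges; a chromosome shorter than the window is scored by its single
truncated window. Candidate runs are maximal stretches of markers
scoring strictly above 0.05, split where adjacent markers are >1,000 kb
apart, and emitted only if they span ≥1,000 kb *and* ≥120 SNPs. Segment
bounds snap to the outermost marker positions, and length is end − start
— the convention that reproduces the bundled reference island lengths
exactly. The ambiguous "minimum number of potential marked SNPs"
parameter seen in published PLINK parameter lists is exposed as an
optional per-segment SNPs-per-Mb floor (`min_density_snp`) and is off by
default.

Length classes for summaries are (0, 5], (5, 10], (10, 20], (20, 31] and
>31 Mb, with per-population percentages of total ROH length. The lowest
class is open at 0 so a segment at exactly the 1 Mb minimum is counted.

Islands are computed from per-marker incidence — the fraction of a
population's individuals whose segments cover the marker — as maximal
runs of incidence strictly >0.5. This is deterministic and
order-independent (unlike pool-overlap grouping) and matches the
"shared by more than 50% of individuals" definition directly. The
reported carrier fraction is the *minimum* incidence across the island,
a conservative summary. Gene annotation assigns any interval overlapping
an island by ≥1 bp, in genomic order, from BED6 or GFF3 `gene` features.

## Breed structure

Population distances are Euclidean on allele-frequency vectors over the
markers defined in every population (markers with any undefined
frequency are dropped and counted). The neighbor-joining implementation
is the standard Saitou–Nei Q-matrix agglomeration; ties in Q break by
the lexicographically lowest pair of node keys (a node's key is the
smallest leaf label beneath it), making the tree independent of input
order, and negative branch lengths are clamped to zero with a log entry.
PCA mean-imputes missing calls per marker, drops zero-variance markers,
centers columns (optional 1/√(p(1−p)) scaling), and fixes each
component's sign so its largest-magnitude loading is positive. A greedy
r²-threshold pruner is available as plumbing but off by default, since
pruning is not assumed for distance/PCA summaries.

## Wright–Fisher simulator

Forward-in-time diploid simulation with exact per-generation control of
N — the property that matters for *N*e recovery tests and that coalescent
simulators do not expose as directly. Gametes start from standing
variation (every marker at frequency 0.5, linkage equilibrium); each
generation draws 2N gametes from random parents with Poisson(genetic
length) crossovers placed uniformly, no interference and no mutation.
After t generations, n diploids are sampled without replacement and
missing calls are masked at the configured rate. Two-epoch histories
shrink or grow the gamete pool at the boundary. All randomness flows
from one integer seed.

Defaults model a scaled-down cattle panel: 10 chromosomes × 50 Mb (real
bovine autosomes span 42–158 Mb; ≥25 Mb is required anyway so the *N*e
bins out to 12.5 Mb have room), 50 kb marker spacing (≈50K-array
density), N = 100, 50 sampled, 150 generations. Chromosome count was
chosen for replicate stability of mean r², which is dominated by
evolutionary (not sampling) variance.

What the simulator does **not** emulate: mutation (so diversity only
decays, and long runs fix entire chromosomes — validation uses
generation counts where segregation is ample), selection, migration,
array ascertainment bias, genotyping error, and non-uniform
recombination. Passing tests therefore demonstrate correctness of the
estimators under the idealized neutral model, not robustness to real
array data artifacts.

Because of the drift-only start and conditioning on segregation, the
composite r̄² of simulated panels follows 1/(1 + 4Nc) + 1/(2n) only to
within a factor of ~2 (below the curve at small c, where equilibrium
takes ≈1/(2c) generations to build; above it at large c). The simulator
consistency test asserts that banded agreement plus monotone decay, not
pointwise equality.

Tract implanting for ROH validation overwrites the region with
major-allele homozygotes in ceil(f·n) carriers chosen as the first
samples of a seeded shuffle, so tests can enumerate carriers from the
same seed. The Sved pair generator emits r² = 1/(1+4βd) + N(0, σ²)
truncated to [0, 1]; validation clouds sample distances log-uniformly on
[1 kb, 1 Mb] so the curve's informative region (d ≈ 1/4β) is well
covered rather than drowned by far-field pairs.

## Pipeline

One YAML config drives QC → LD → *N*e → ROH → islands → structure. QC is
applied once to the pooled panel and per-breed stages run on subsets,
keeping all breed-level tables on a common marker set. A stage failure
in one breed is recorded and skips only that breed's dependents. Config
validation reports every problem in one pass (unknown keys, type and
range errors, missing files) and echoes injected defaults. All numeric
output uses fixed %.10g formatting and the manifest holds versions,
parameters (minus output location) and input checksums, so identical
config + seed reproduces every file byte-for-byte. Per-stage seeds
derive from the root seed by hashing stable stage names.

## Problem sizes used in validation

Chosen so the full suite runs in ~1.5 min and the acceptance script in
~1 min on a single CPU: Sved recovery uses 20 replicates of 5,000 pairs;
constant-N *N*e recovery 3 replicates of the default genome; the
contraction contrast 10 seeds; island recovery 20 seeds of a 100-sample,
20 Mb, 10 kb-spacing panel with a 5 Mb implant at carrier fraction 0.7;
ROH oracle equivalence uses brute-force window enumeration on panels up
to 500 markers; NJ additivity uses random 5–8 leaf trees at 10⁻⁹
tolerance.

## Known limitations

* Haplotype-phase (EM) r², D/D′, and Fst are out of scope; r² is always
  the composite estimator.
* *N*e estimates carry the no-correction bias described above; levels at
  small n should be read as lower bounds.
* The ROH caller follows the windowed-score definition; model-based
  (HMM) callers will disagree near segment edges.
* Islands are per-population; no cross-population consensus regions.
* Binary PLINK BED/BIM/FAM, multi-allelic markers, and imputation are
  unsupported; admixture-proportion estimation is deliberately excluded.
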