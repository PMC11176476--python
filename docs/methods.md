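# Methods

## Model and rationale

The framework infers *shared vulnerabilities* — susceptibility axes in
cancer cell lines exploited by two mechanistically distinct drug classes —
from monotherapy cytotoxicity screens alone. The unit of evidence is a drug
pair whose AUC profiles across cell lines correlate recurrently in
independent datasets; the unit of inference is the class pair, tested for
overrepresentation of such recurrently correlated pairs.

Rank correlation (Spearman, mid-ranks for ties) is used because the three
emulated screens report AUC on different native scales; any within-dataset
monotone rescaling leaves every downstream statistic unchanged, which is
also why the preparation step deliberately does **not** harmonize AUC
across datasets. Spearman p-values are computed nowhere: the per-pair
sample sizes and panel overlaps differ, so the p-values are not
exchangeable and cannot be jointly adjusted; pruning uses magnitude
(|ρ| ≥ 0.25, inclusive), recurrence (≥ 2 datasets), and sign consistency
across *all* datasets where the magnitude criterion is met. Pairs failing
sign consistency are dropped from the recurrent set but retained in the
enrichment background — they were tested, and the background models the
testing process, not the outcome.

## Enrichment

Instances are weighted by dataset counts — background weight = datasets
tested (2 or 3), foreground weight = datasets correlated — so pairs tested
in three screens do not get an automatic advantage over pairs tested in
two. Weights are small integers by construction, keeping the hypergeometric
counts integral. The test is the upper tail P(X ≥ k) including the observed
count (the standard overrepresentation convention; evaluated through the
survival function, which is stable in log space for large counts).

Order of operations: same-class pairs are removed before
Benjamini–Hochberg (they are enriched by construction and would distort the
family); miscellaneous-type catch-all classes (default registry D01AE,
L01AX, L01CX, L01DC, L01EX, L01XX, extensible from the class map) remain in
the FDR family and are excluded only from the final report, because their
labels describe the absence of a class, not a mechanism. Only class pairs
present in the recurrent set are tested. Ties in the final ranking break
lexicographically on the class-pair key, so output order is deterministic.

Prioritization of significant class pairs (distinct pathway groups,
targeted-only) is driven entirely by curation flags supplied in the class
map; nothing is inferred from structure or names, since that judgement is
domain knowledge, not an algorithm.

## Matrix, pruning, clustering

The class × class matrix holds adjusted p-values; cells for class pairs in
the background but not the recurrent set, same-class cells and the diagonal
are set to 1.0 ("no evidence of enrichment"), a convention required to form
complete rows for Euclidean distances. Class pairs never tested in any
dataset are genuinely missing; completeness is restored by removing
offender classes — a manual drop list first (mirroring a curator's choice),
then greedily by most-missing-cells with lexicographic tie-break, which
terminates because every step strictly reduces the missing count.
Clustering is agglomerative with complete linkage on Euclidean distances
between rows of adjusted p-values (not −log p; distances operate on the
same scale the matrix displays). Leaf order is canonicalized by ordering
subtrees by their smallest class code, making the displayed order invariant
to input permutation when merge heights are untied.

## Synergy metrics

Dose matrices are fractions affected in [0, 1] relative to vehicle (1 =
complete kill). Single agents are fit with a variable-slope four-parameter
logistic on log concentration, with a deterministic initialization (extreme
responses for bottom/top, mid-response interpolation for EC50, hill = 1);
flat curves yield a flagged degenerate fit rather than an exception. The
Loewe-additive reference at a dose pair solves d_a/D_a(y) + d_b/D_b(y) = 1
by bracketed root-finding (tolerance 1e-8) over the effect range both
inverse-4PL dose functions can attain, clipping to the range edge where the
doses exceed it (cells with no common attainable range are excluded with a
warning). Loewe and HSA scores are the mean observed-minus-expected effect
over all combination cells × 100 (percentage points): the published
thresholds (> 10 synergistic) imply a percentage-point scale but no
aggregation formula, and the mean-excess convention matches common synergy
software. The combination index uses median-effect fits of the single-agent
edges (log(fa/(1−fa)) on log D), computes CI per combination cell with
0 < fa < 1, averages CI at duplicated fa values, and linearly interpolates
to fa = 0.75; when the observed fa range does not bracket the effect level
the nearest-fa CI is returned with an extrapolation flag.

Screen-level validation sets the cutoff at a linear-interpolation
percentile (90th default) of **all** (pair, cell line) scores, calls a pair
synergistic on a strict exceedance in ≥ 1 cell line, and a class pair on
≥ 1 synergistic member; the headline number is the fraction of identified
class pairs, restricted to those evaluable in the screen, receiving a call.

## Synthetic data

The generator emulates the structure the pipeline consumes, not any real
screen's values: a pool of cell lines carries independent standard-normal
latent vulnerability factors; drug AUC = baseline − loading × factor +
Gaussian noise, with baselines U(4, 8) and per-dataset affine rescaling
(rank-preserving) standing in for native AUC scales. Lower AUC = more
sensitive, so vulnerability enters negatively. Defaults define the study
conditions used throughout the tests: 3 datasets × 40 cell lines sampled
without replacement from a pool sized for 75% panel overlap, six classes of
five drugs, one cross-class pair planted on a shared factor at loading 1,
noise SD 0.3. Under these conditions a same-factor drug pair has population
Spearman ρ ≈ 0.9 and a cross-factor pair ≈ 0, so the planted class pair is
recoverable but not trivial. What the generator does **not** emulate: batch
and plate effects, heavy-tailed response noise, lineage-specific structure,
drug-specific curve shapes, missing-at-random holes in the drug × line
grid, or inter-dataset disagreement beyond panel differences — so passing
tests demonstrate correctness of the machinery under the stated model, not
robustness to real-screen pathologies.

Checkerboard surfaces are generated directly from a named reference model
(Loewe-additive or highest-single-agent) with optional constant excess and
noise, on default grids of 8 × 5 doses in 1:5 serial dilutions from 8 µM
and 1.6 µM tops. Generated surfaces are not clipped to [0, 1], so
constant-excess surfaces have exactly known scores.

## Numerical and degenerate-input choices

Zero rank variance makes ρ undefined; such pair/dataset entries are skipped
and logged, never imputed as 0. Duplicate (drug, cell line) records
collapse by arithmetic mean (symmetric, order-independent). Unmapped cell
lines are retained with a warning; unannotated drugs in the enrichment path
are a hard error listing the full missing set (silent dropping would
silently change the background). Identifier matching is exact-string after
optional case-folding/trimming. An empty recurrent set propagates as empty
well-formed outputs, not errors. All analytical stages are deterministic;
randomness exists only in the generator and is fully seeded.

## Problem sizes

The default simulated experiment (3 × 40 lines, 30 drugs → 435 pairs × 3
datasets) runs in well under a second; repeated-seed studies in the tests
and the acceptance script use 50 replicates, chosen as the point where the
Monte-Carlo standard error of a recovery rate (~3 percentage points) is
small against the properties being checked.

## Known limitations

- **Clumped instances make the enrichment anti-conservative.** The
  hypergeometric treats weighted pair-instances as independent draws, but a
  recurrent pair contributes 2–3 instances at once, pairs share drugs, and
  drugs within a class share a factor — so under realistic null structure
  (classes on private factors) class-level significance is inflated, and
  even at the complete null the per-family any-rejection rate exceeds the
  nominal level. The per-test rejection rate at the complete null stays
  within Monte-Carlo error of nominal. Rankings (which pair is top) are far
  more robust than absolute p-values, and the planted-recovery tests rely
  on rank, not level.
- No lineage-specific inference: correlations pool all non-excluded
  lineages, trading lineage sensitivity for cross-lineage robustness.
- Class assignment is user curation; a wrong map propagates silently.
- Dose-matrix scores treat the checkerboard as a static surface; sequential
  dosing schedules affect only how the data were produced.
- Pathway-level interpretation of enriched class pairs (perturbational
  transcriptomics) is outside the package's scope and is not implemented.
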