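# Methods

## The test

Given two samples X (m points) and Y (n points) in the p-dimensional marker
feature space, the Friedman–Rafsky procedure pools the N = m + n points,
builds the minimum spanning tree of their pairwise distances, and counts
runs R = (number of edges joining the two samples) + 1. Conditionally on
the tree, the permutation-null moments of R are closed-form (see README for
the formulas; the variance depends on the tree only through C = Σ_v
deg(v)(deg(v)−1)/2, the number of edge pairs sharing a node). The reported
p-value is the one-sided normal approximation p = Φ(W) with
W = (R − E[R])/√Var[R]: few runs ⇒ W < 0 ⇒ small p ⇒ evidence the
distributions differ.

Assumptions: exchangeability of labels under the null (automatic, since the
null is conditional on the pooled points) and enough points for the normal
approximation (the implementation requires N ≥ 6; with the default
subsample size the test always runs at N = 20).

**Discreteness.** R is integer-valued, so no deterministic p-value can be
exactly uniform. Φ(W) approximates the *mid-p* of the exact permutation
distribution (verified against Monte-Carlo enumeration in the tests), which
keeps the test calibrated on average: at N = 40 the measured type-I error
at α = 0.05 is within the Monte-Carlo margin of 0.05. The exact permutation
p-value `permutation_pvalue` — p = (1 + #{R_perm ≤ R_obs})/(1 + n_perm) —
is the CDF rather than the mid-p; it is valid (conservative) and differs
from Φ(W) by about P(R = R_obs)/2, which is noticeable (up to ~0.1) at
N = 20 and vanishes as N grows. A continuity-corrected normal p would track
the CDF instead, at the price of conservative calibration; the mid-p-like
behaviour was chosen because calibration of the matching threshold matters
more than agreement with the conservative estimator.

**MST construction.** Prim's algorithm on the dense distance matrix
(O(N²), ample for post-subsampling sizes), ties broken toward the smallest
node index so results are deterministic even with duplicate points. The
tree's total weight is cross-checked against an independent sparse-graph
implementation and, at tiny sizes, against brute-force enumeration of all
spanning trees.

**Distances.** Euclidean, or cosine distance 1 − x·y/(‖x‖‖y‖) ∈ [0, 2].
Cosine is invariant to positive per-cell rescaling, which makes the test
insensitive to platform dynamic-range differences. A zero vector has no
direction; its distance to every other point is defined as 1 (neutral) with
a warning — never NaN — so dropout-silenced cells cannot poison a test.

## Matching schemes

For each (query cluster j, reference cluster k) pair, `subsamp_iter`
iterations each draw `subsamp_size` cells without replacement from both
sides and run the test:

- *cell-to-cluster*: each drawn query cell's p_ck is max-updated with the
  iteration p-value. A cell's final p against its true type is therefore
  the maximum of ~(iterations × size / cluster size) null-ish draws, close
  to 1, while against a different type every draw yields a near-zero p.
  Entries of never-drawn (cell, reference) pairs stay NA — distinguishable
  from "always rejected" — and draw counts are recorded as coverage.
- *cluster-to-cluster*: the median p over iterations for the pair.

Defaults (2000 iterations, size 10, BH adjustment, significance level 0.1)
follow the established convention for this procedure. If a cluster has
fewer cells than the subsample size, the draw size shrinks to the smaller
cluster (with a warning); clusters under 3 cells are skipped. BH is applied
jointly over the whole matrix by default (`bh_scope="row"` is available);
assignment is the argmax of the adjusted row, or *unassigned* below the
significance level. Exact argmax ties — which BH's step-up plateaus make
common near p = 1 — are broken by the raw p (the ordering the adjustment
collapsed) and only then by reference column order, with a tie flag.

Parallelism is partitioned by cluster pair; each pair's RNG is derived
deterministically from (seed, j, k), so results are bit-identical across
worker counts and schedulings.

## Normalization

Cross-platform matching first projects both datasets onto the reference
marker genes, then min–max rescales each gene (x̃_g = x_g / max x_g; an
all-zero gene stays zero by the 0/0 := 0 convention, since dropout-heavy
panels contain such rows). For high-sensitivity plate platforms the
cluster-wise weighting step multiplies each gene row within cluster b by
that row's within-cluster mean or median and rescales the cluster submatrix
to max 1. Markers selected for near-binary expression give near-binary
weights, so median weighting zeroes genes expressed in a minority of a
cluster's cells — removing exactly the background noise that plate
protocols add. Weighting is gated by the platform tag (default: applied to
`smartseq`-tagged data only; `norm_by="none"` disables it), because
same-platform comparisons need only the rescaling.

## Synthetic data

Two generators define the validation conditions.

**MVN two-sample scenarios** (`SimulationScenario`): X, Y ~ MVN_p with
p = 40, equicorrelated Σ (ρ = 0.2), under a null (identical distributions)
or alternatives — location (mean shift δ, grid {0.25, 0.5, 1}), shape
(covariance scale {1.5, 2}), or both — at small (m = n = 20) and large
(m = n = 100) sample sizes. The magnitudes are not canonical; they were
fixed once to span no-power to full-power regimes. The *scale-mismatch*
scenario emulates cross-platform expression data: a positive baseline mean
(μ = 3 per coordinate, placing points in the positive orthant like
expression values), a cell-type difference expressed as a marker-pattern
shift (δ on half the coordinates, changing the direction of the mean, not
just its norm), and one sample multiplied by 5 (the dynamic-range
mismatch). A mean-zero version of this scenario would place the scaled
sample on a shell around the other — a geometry with no analog in
non-negative expression data — so the baseline is part of the scenario
definition. In this study the euclidean test rejects everything under the
scale nuisance (AUC ≈ 0.5) while the cosine test is unaffected by the
multiplier and retains power, which is the rationale for the cosine option.

**Marker-structured atlases** (`SyntheticAtlas`): K clusters (default 5 ×
200 cells) each own a disjoint block of markers (2 per cluster) that are
"on" in their cells (negative-binomial counts, mean 60, gamma-Poisson shape
2, 10% zero-inflation) and essentially "off" elsewhere (mean 0.05 stray
counts), plus 10 moderately expressed background genes that stabilize
library sizes. These defaults model strong subclass-level binary markers in
droplet data: rare stray off-target counts and modest dropout. (Heavier
settings — e.g. 25% zero-inflation or mean-0.3 off-target counts — make a
fifth of cells degenerate after log-CPM compression and contradict the
binary-barcode regime this generator is meant to emulate, so they are not
the defaults.) `platform_style="bimodal"` emulates plate data (stronger
signal, 6× background, little dropout ⇒ bimodal log-CPM marginals) vs
`"rightskew"` for droplet data (sparser, right-skewed). Counts are
preprocessed as log2(1 + CPM); the pseudocount keeps zeros at zero and is
exposed (`pseudocount=`) because plain log(CPM) is also in use.

What the generator does *not* model: correlated gene modules, ambient RNA,
doublets, batch effects within a platform, and continuous/transitional cell
states. Passing tests therefore demonstrate the statistical machinery —
calibration, novelty detection, under-partition splitting — under clean
cluster structure, not robustness to every artifact of real data.

**Evaluation harnesses**: `run_power_study` builds paired null/alternative
p-value samples per scenario and metric and summarizes them by rejection
rates and the rank-based AUC (cross-checked against an exact pairwise-count
oracle); `loocv_unassigned_eval` drops each reference cluster in turn,
reruns the full pipeline, and scores the *unassigned* call as a binary
classifier (accuracy and type-I error of novelty detection);
`simulate_cell_atlas_pair(..., merge_clusters=...)` produces the
under-partitioned-query scenario, where a merged cluster should split its
assignments across both true types.

## Problem sizes and determinism

The validation studies use: 200,000 label permutations for the moment
check; 50 fixtures × 20,000 permutations for the oracle comparison; 2,000
null replicates (m = n = 20) for calibration and 1,000 (m = n = 100) for
uniformity; 500 replicates per scenario/metric for AUCs; and 5 × 200-cell
atlases with the default 2,000 × 10 subsampling for the matching studies.
Every random draw flows from an explicit seed through per-study
`SeedSequence` spawns; identical seeds give bit-identical outputs.

## Known limitations

- The normal-approximation p is mid-p-like; users needing a strictly
  conservative p at very small N should use `permutation_pvalue`.
- The paper-style max-update rule means cell-level p-values against the
  true type concentrate near 1; they are confidence scores for ranking, not
  uniform p-values, and only the thresholded decision is calibrated through
  the underlying test.
- Coverage: with fixed iteration counts, very large query clusters get few
  draws per cell; `target_draws` auto-scales iterations when set.
- Cosine distance treats anti-correlated patterns (distance ~2) as merely
  "far"; with non-negative expression this region is unused.
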