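# Methods

## The model

Each cell in a flow-cytometry sample is treated as one realization of a
J-dimensional random variable x = (x_1, …, x_J), one coordinate per measured
marker channel. Because samples contain 10^4–10^7 cells while J is small
(7–14), the marginal and pairwise statistics of x can be estimated very
accurately, and the full joint density p(x) is approximated by a
tree-structured Bayesian network

    q(x) = P(x_root) · ∏_(child, parent) Q(x_child | x_parent),

where the (child, parent) pairs are the edges of a spanning tree over the
markers. The tree is learned with the Chow–Liu construction: among all
spanning trees, the one maximizing the total pairwise mutual information
minimizes the KL divergence from the empirical joint to any tree-factorized
distribution. In practice:

1. Every marker column of the pooled control cohort is min-max normalized to
   [0, 1] and discretized into Nx equal-width bins.
2. All J(J−1)/2 pairwise joint histograms are tallied and their plug-in
   mutual information (in bits) computed.
3. Kruskal's algorithm on edges sorted by (−MI, j, k) yields the maximum-MI
   spanning tree; the lexicographic tie-break makes the tree deterministic.
4. The model stores the tree, one integer joint-count grid per edge, and the
   root marginal counts. Counts are never smoothed: an empty bin must stay
   exactly empty.

The factorization is invariant to the choice of root (verified exhaustively
in the tests), so the root is fixed at the lowest marker index by convention.

## Scoring and the NoZ statistic

A new sample is normalized and binned the same way, and each cell's
probability under q is evaluated. A conditional Q(a | b) is the ratio of two
training counts and is defined as zero when either the joint count N(a, b) or
the parent count N(b) is zero; a cell's probability is zero exactly when at
least one of its tree factors has a zero training count. This zero test is
performed on the integer counts themselves — the numeric probability is
computed in the log domain only for reporting, so underflow of a product of
many small factors can never masquerade as a structural zero.

The sample-level statistic is **NoZ**: the percentage of a sample's cells
with probability exactly zero, i.e. the fraction of cells whose binned marker
pattern falls outside the support of the control model. Healthy samples
resemble the pooled controls and score near zero; samples containing cell
phenotypes absent from the control pool score higher.

Every zero factor of every zero cell is attributed to markers: a zero edge
factor increments both endpoint markers, a zero root factor increments the
root marker. Summed over a cohort and normalized, these counts rank the
markers that drive the discrimination. When a cell carries several zero
factors all of them are counted; the alternative (first factor only) would
make the statistic depend on the arbitrary factor ordering.

## Group comparison

NoZ scores of the two groups are compared with the two-sided Mann–Whitney U
test and ROC analysis. AUC is computed rank-based — the probability that a
diseased sample's NoZ exceeds a control's, ties counted ½ — which equals the
trapezoidal area under the empirical ROC and satisfies U = AUC·n1·n2. For
combined group sizes ≤ 12 the exact p-value is obtained by enumerating all
C(n, n1) label assignments (correct under ties); otherwise the tie-corrected
normal approximation with continuity correction is used. Samples are called
diseased when NoZ exceeds a threshold (strict inequality); by default the
Youden-optimal threshold (maximum TPR − FPR, ties resolved toward the lower
threshold) is chosen from the scored data, and it can be overridden.

## Parameters

| parameter | default | meaning |
| --- | --- | --- |
| `n_bins` (Nx) | 200 | bins per marker after min-max normalization; higher Nx refines the support and can only increase NoZ (bin-nesting monotonicity) |
| `n_pooled_patients` | 20 | control samples pooled for tree fitting |
| `n_markers` | 7 | markers per combination in sweeps |
| `normalization` | `per_file` | each sample normalized by its own column min/max; `from_training` reuses the training min/max with `oob_policy` `clip` (clamp) or `zero` (out-of-range ⇒ zero probability) |
| `threshold` | Youden | NoZ percent above which a sample is called diseased |

The 7-marker / 200-bin / 20-patient defaults are the configuration reported
to perform best on real cohorts of ~10^6 cells per sample. The test suite and
acceptance script run at Nx = 50 with 2·10^4 cells per sample, which keeps
the support occupancy per bin comparable at desk scale.

Whether test files should be normalized per-file or with training statistics
is genuinely open; per-file is the default because inference on a new patient
is described in terms of that patient's own normalized values, and per-file
normalization requires no stored statistics. `from_training` is provided for
pipelines that need a fixed reference frame.

## Synthetic cohorts

`synthetic_data.simulate_cohorts` emulates a two-group study: cells are drawn
from a Gaussian mixture whose markers follow a correlation tree (generated
root-to-leaves, so the dependence structure is known exactly), with a small
per-sample jitter of the population means mimicking inter-individual
variation. Disease samples are identical draws except that a configurable
fraction of cells is displaced by a fixed number of standard deviations in a
chosen marker subset — an aberrant low-abundance subpopulation, the regime the
zero-probability statistic is designed to detect. Default study conditions:
J = 7 markers in a chain with ρ = 0.6, 20 samples per group, 2·10^4 cells per
sample, 10% of disease cells shifted by 4 SD in markers 2 and 5, jitter
0.05 SD.

What the generator does **not** emulate: spectral spillover and compensation
artifacts, acquisition drift, debris/doublets, heavy-tailed or multimodal
marker distributions beyond the configured mixture, and between-sample
variation richer than a mean shift. Passing tests therefore show that the
method behaves as specified on clean tree-structured data, not that it will
reach the same AUC on real cytometry files.

`sample_from_tree_model` draws directly from an explicit discrete tree
distribution (ancestral sampling) and is the ground truth for structure
recovery: a 6-marker chain with stay-probability 0.6 at Nx = 8 and 5·10^4
cells is recovered edge-for-edge in essentially every seeded replicate.

## Numerical choices and degenerate inputs

- Bin index: floor(u·Nx) with u = 1 mapped to bin Nx−1; equal-width bins on
  [0, 1]. Binning is order-preserving per column, and bins nest exactly
  across halvings of Nx (`TreeModel.merge_bins`), giving the monotonicity
  NoZ(Nx/2) ≤ NoZ(Nx) with the tree held fixed.
- A constant marker column makes min-max normalization undefined and is a
  hard error; silently dropping it would change J and the tree.
- Mutual information uses the plug-in estimator, base 2. The estimator's bias
  does not affect the argmax tree on the sample sizes involved.
- A zero-total pair histogram (all cells out of range) is an error rather
  than a silent zero-MI edge.
- Tiny negative MI from floating-point round-off is clamped to 0.
- Every stochastic step — patient pooling, cell subsampling, marker
  combination sampling, cohort simulation — takes an explicit integer seed
  and records it in outputs.

## Problem sizes in the test suite

The acceptance-style checks run the default synthetic conditions above;
structure recovery uses 20 replicates of 5·10^4 cells; the null configuration
(zero effect) is averaged over 20 seeds; the input-cell-count experiment uses
12 samples per group at 10^3/10^4/10^5 cells per sample over 10 seeds, with
half the controls pooled for fitting in all experiments. These sizes were
chosen so each stage's sampling error is small relative to the effects under
test.

## Known limitations

- The statistic is strictly zero/one per cell: a sample can be arbitrarily
  unlikely yet score NoZ = 0 as long as every cell stays inside the training
  support. Soft likelihood thresholds are deliberately out of scope.
- One fitted tree separates exactly two outcomes; multi-class problems need
  one model per reference cohort.
- NoZ depends on Nx and on the number of pooled training cells through the
  occupancy of the support; comparisons are only meaningful at a fixed
  configuration.
- Marker attribution credits both endpoints of every zero edge, so a
  displaced marker's tree neighbors inherit part of its attribution mass;
  with weak effects a neighbor can outrank a truly affected marker.
- Per-file normalization makes scores invariant to affine per-sample
  intensity shifts but ties the bin grid to each sample's own extremes, so a
  single extreme outlier cell rescales a whole column.
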