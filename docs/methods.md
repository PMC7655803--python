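# Methods

## The object of analysis

A mitochondria interaction network (MIN) is extracted from a skeletonized
3D image: every skeleton voxel with a 26-neighborhood count different
from 2 is a node (branch point or end point), chains of degree-2 voxels
between nodes are links, and the adjacency entry A_ij stores the voxel
count of the traced chain *including both terminal node voxels* — so a
present link always has A_ij ≥ 2, and "A_ij > 0" is the link indicator.
MINs are heavily disconnected; all topological analysis operates on the
connected components, whose node count s is the "size" throughout.

Conventions the extraction fixes where the upstream tooling is silent:
voxel connectivity is 26 (matching the classical 3D thinning tools);
two directly adjacent branch points form a link of weight 2; parallel
voxel paths between one node pair collapse into a single link with summed
voxel count; a chain returning to its origin node is dropped; a pure
voxel cycle with no branch point collapses to one isolated node (size-1
component, retained for size statistics). The terminal-branch length
threshold `thr` defaults to 0 (keep everything); positive values prune
shorter endpoint chains before node detection.

## Metrics

Weights are ignored by every topology metric (the link rule thresholds
A_ij > 0); they matter only for I/O fidelity. Per component: normalized
degree k* = k/N; link density; max degree; ASPL, diameter and efficiency
from one all-pairs BFS (topological distance); Louvain modularity (seeded,
node-order canonicalized — the partition search is stochastic but the
published quantity is a scalar Q, so reproducibility wins over partition
variety); degree assortativity as the Pearson correlation of endpoint
degrees over both orientations of each link, with an explicit *undefined*
result on regular components (the correlation is 0/0 there; undefined
values are excluded from every downstream distribution rather than forced
to 0); transitivity; small-worldness against the component's null
ensemble.

Size-1 components appear in size statistics only; size-2 components get
pairwise metrics but vacuous (0) transitivity and no motifs. Size filters
("size ≥ 24"-style) are inclusive at both ends.

**Information content.** The mesoscale-regularity score is operationalized
as a greedy agglomeration on the binary adjacency matrix: at each of the
s − 1 steps, merge the pair of nodes whose rows disagree in the fewest
positions (each disagreement = one bit; the two entries inside the pair
are excluded; ties break on the lowest original node-id pair), combine
rows by union, and accumulate the bits. Complete graphs and stars cost 0
bits; irregular mesoscale structure costs more. This is a fixed, tested
operationalization of the "bits lost when iteratively merging node pairs"
idea; it is documented by its own invariants, not as a reimplementation of
any specific reference procedure.

## Null model and Z-scores

Each component is normalized against 100 random graphs with exactly its
(n, l), each required to be a single connected component: a draw from
G(n, l) conditioned on connectivity, via rejection sampling (cap 10⁴
draws, then a spanning-tree-plus-random-links fallback with a logged
warning — the fallback is biased toward tree-like graphs and essentially
never triggers at typical MIN component sizes). Degree sequences are *not*
preserved; this is the literal "same nodes and links, single component"
null, and Z magnitudes would differ under a configuration-model null.
Z = (M − μ)/σ with σ the sample SD (ddof = 1) over the defined ensemble
values; σ = 0 yields an undefined record that is dropped (and counted)
rather than ±∞. Ensembles depend only on (n, l), so they are cached per
class and seeded from (seed, n, l) — results do not depend on component
order. Z-histograms (probability m/n per bin) default to width 0.5 over
[−5, 5] with open outer bins.

## Component-size law

The size distribution is modeled as P(s) ~ k^s — exponential in s; the
field's "power-law slope k" naming is kept. (A strict power law
p(s) ~ s^(−γ) is available behind a flag; Clauset-style maximum-likelihood
fitting and cutoff power laws are out of scope.) Fitting is
Levenberg–Marquardt least squares of a·k^s after discarding the lowest
and highest 10% of the *distinct observed sizes* (sparse, noisy tails).
Two groups are compared by representing each slope as a normal variable
N(k̂, sd²) and testing the difference against zero, two-sided.

Two numerical choices here were genuinely open and were decided by
calibration against the test's own nominal level:

* **Density, not cumulative, curve.** The LM covariance assumes
  independent residuals. Per-size densities are near-independent
  multinomial fractions; cumulative values are partial sums with strongly
  correlated errors. Fitting the cumulative curve understates Var(k̂)
  roughly four-fold and drives the slope test's empirical type-I error
  above 60% at nominal 5% (still ≈ 40% at tens of thousands of components).
  The default fits the density; the cumulative curve (the quantity
  plotted in size-distribution figures) remains available via `curve=`.
* **SD = the CI width, i.e. 2 standard errors.** A "68% confidence
  interval's width" spans from −1 SE to +1 SE. Combined with the density
  fit, this reading gives an empirical type-I error of 4.0% (400 null
  pairs, k = 0.7, 5000 components per side) with 100% power at
  k = 0.6 vs 0.8 — the half-width reading is anti-conservative. Both
  readings are exposed via `ci_mode=`.

Measured under the defaults: slope recovery within ±0.03 of k = 0.7 in
100/100 cohorts of 5000 components; noiseless a·0.9^s data recovered to
10⁻⁶.

## Group statistics and clinical correlation

Group contrasts use the two-sample two-sided Kolmogorov–Smirnov test on
pooled per-component values — Z-scores by default, raw values by flag.
The exact p-value is used when both sides have ≤ 25 observations,
asymptotic above. Family-wise significance is flagged by Šidák:
per-test threshold 1 − (1 − α)^(1/m), one family per comparison panel
(m = the number of metrics in that panel; configurable). Pooling
components ignores within-subject correlation — a documented limitation
inherent to this analysis design; the leave-one-subject-out and
random-subsample stability reports quantify how much any single subject
drives a contrast.

Clinical correlation: per subject, the mean of a metric over that
subject's components of one configured size (subjects lacking such
components are dropped); Pearson r against UPDRS with the two-sided
t-distribution p-value (≥ 3 complete pairs required). At desk-scale
component counts a single-size mean is noise-dominated, so the acceptance
script averages over the large-component band (size ≥ 10) instead of one
exact size; the exact-size aggregator remains the library primitive.

## Classification

Instances are components — each person contributes many neurons and
networks, so subject identity, not instance identity, is what must not
leak; features are metric and motif Z-scores.
Leave-one-subject-out CV: for each subject, a model trained on all *other*
subjects' instances scores that subject's instances; pooled scores give
one ROC/AUC (trapezoidal, midrank ties — numerically identical to the
normalized Mann–Whitney U, which the tests assert). A fold-audit log
records every train/test subject split and is asserted disjoint. The
default model is a single-hidden-layer perceptron (16 units, lbfgs,
max 500 iterations, seeded; any scikit-learn classifier can be
substituted). Imputation (training-fold median) and standardization
(training-fold statistics) happen inside each fold. The chance control
permutes labels across subjects — every instance of a subject moves
together, class counts preserved — and reruns the full LOSO-CV per
permutation (50 by default).

A property of LOSO permutation nulls worth knowing: holding out a subject
leaves its permuted class slightly under-represented in training, biasing
the null AUC below 0.5 by O(1/n_subjects) (≈ 0.36 at 10 subjects, ≈ 0.45
at 20 in our measurements). Sanity checks of the chance level therefore
use 20-subject cohorts.

## Synthetic cohorts

The generator produces what the analysis assumes about real data, at desk
scale:

* **Sizes** from the exact truncated distribution p(s) ∝ k^s on
  [min_size, max_size] (discrete sampling: sizes are integers even
  though the fitted decay curve is continuous). Defaults: support [2, 30].
* **Wiring** is generative scaffolding invented for this package (the
  analysis measures metrics, it does not presuppose a wiring mechanism): a spanning tree by
  sequential attachment — new node joins the previous node with
  probability `chain_bias`, else a uniformly random earlier node — then
  Binomial(size, 0.3) extra links, each closing a random open triad with
  probability `triangle_propensity`, else joining a random non-adjacent
  pair. `chain_bias` = 1 with no extras is exactly a path (maximal
  ASPL/diameter, minimal efficiency); `triangle_propensity` steers
  transitivity and the triangle census. Link weights are uniform integers
  in [2, 20].
* **Groups.** Defaults mirror a realistic clinical-cohort scale (11 disease vs 10
  control
  subjects, two networks each for left/right side) with contrasts in the
  reported *directions* — disease: heavier size tail (k 0.75 vs 0.65),
  more triangle closure (0.6 vs 0.3), more chain-like wiring (0.7 vs
  0.35). No published effect magnitudes exist to copy; these values were
  chosen once as a plausible medium effect and are spec fields, not
  constants. Disease subjects carry a severity scalar ~ U(0.7, 1.3)
  (mean 1 ⇒ group means equal the group parameters) that scales their
  deviation from control parameters and generates a synthetic UPDRS score
  (15 + 35·severity + N(0, 2)), giving the clinical-correlation stage a
  real target.

What the generator does *not* emulate: fluorescence, staining noise,
segmentation artifacts, spatially realistic geometry, within-subject
network heterogeneity beyond component resampling, or any specific real
effect size. Passing tests therefore demonstrate the *pipeline's*
correctness and calibration, not biological conclusions about real
cohorts.

## Voxel round-trip fixtures

`rasterize_to_skeleton` draws a component as a clean 3D skeleton whose
extraction reproduces it: nodes on the y-axis at ≥ 6-voxel spacing
(random order), each link a strictly y-monotone voxel path found by BFS
under clearance constraints (monotonicity makes paths self-clean; no path
voxel may touch other material; interior voxels keep Chebyshev distance
≥ 3 from non-endpoint nodes; the two layers nearest each endpoint stay in
their attachment corner's quadrant). A voxel skeleton caps embeddable
node degree at 8 (the 26-neighborhood admits at most 8 pairwise
non-adjacent first steps). Crucially, a degree-2 graph node is
*unobservable* in a skeleton — a voxel with exactly two neighbors is link
interior by definition (extracted MINs never contain degree-2 nodes for
the same reason) — so the rasterizer first smooths degree-2 chains and
returns the smoothed graph with realized voxel counts as the expected
round-trip target; inputs without degree-2 nodes round-trip identically.
Components that smooth to self-loops or pure cycles are refused
(`EmbeddingError`), and fixture loops simply redraw. An independent
geometric verification (neighbor-count audit of the produced volume) runs
inside the rasterizer before anything is returned.

## Problem sizes and numerical notes

Test and acceptance runs use: 200 random components (s ≤ 40) for metric
oracles; 30 components (s ≤ 20) for motif oracles; 100-member ensembles
with exact-uniformity checks on all enumerable (n ≤ 4) classes; 100
replicates × 5000 components for slope recovery, 200 pairs for
calibration; 100 voxel round trips; 20 subjects × 10 instances for
classification sanity. The synthetic-cohort analysis in the acceptance
script runs 21 subjects × 250 components (max size 24) with 100-member
nulls — a desk-scale stand-in for real cohorts, which pool tens of thousands
of components per group. Louvain is seeded per ensemble member; ties in the
information-content merge break lexicographically; `curve_fit` uses
p0 = (1, 0.5) and the unbounded LM path throughout.

## Known limitations

* The information-content score is a fixed operationalization, not a
  reimplementation of any particular published procedure.
* The G(n, l)-conditioned null ignores degree sequences; Z-scores under a
  degree-preserving null would differ systematically.
* Pooled KS tests treat components as independent despite within-subject
  clustering.
* The exponential size law is assumed, not selected; heavy-tail
  alternatives are deliberately out of scope.
* Motif classes stop at 4 nodes; enumeration is exhaustive and O(s⁴),
  fine for s ≤ ~40 but not for giant components.
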