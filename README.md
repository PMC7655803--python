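# mitotopo

Topological analysis of **mitochondria interaction networks (MINs)** —
graphs extracted from skeletonized 3D fluorescence microscopy of
mitochondrial staining, in which nodes are skeleton branch/end points,
links are physically observed connections, and the link weight is the
voxel count of the traced path. Mitochondria constantly fuse and divide,
and within a neuron they form thousands of small, disconnected
subnetworks; the shape of those subnetworks turns out to carry disease
signal (e.g. in Parkinson's disease, where enteric-neuron MINs show larger
components, lower efficiency and more triangles than in healthy
controls). This package implements the full analysis chain for
researchers who want to quantify such effects in their own imaging data —
and a synthetic cohort generator so the whole pipeline is testable without
hundreds of gigabytes of images.

## What it computes

Given binary skeleton volumes (TIFF stacks) or pre-extracted weighted edge
lists, per connected component of each MIN:

- **Metric battery** — normalized degree k\* = k/N, link density
  l_d = 2l/(N(N−1)), max degree, average shortest path length
  ASPL = ⟨d_ij⟩, diameter = max d_ij, efficiency E = ⟨1/d_ij⟩, Louvain
  modularity Q, degree assortativity, transitivity (3·triangles /
  connected triples), an information-content score (bits lost under
  iterative pairwise node merging) and small-worldness
  (T/⟨T_rand⟩)/(ASPL/⟨ASPL_rand⟩).
- **Motif census** — induced 3-node (V-shape, triangle) and all six
  connected 4-node classes (path/U-shape, star, paw, cycle, diamond,
  complete), by exhaustive enumeration.
- **Null-model Z-scores** — each metric/motif count M is normalized as
  Z = (M − μ(M_R))/σ(M_R) against 100 connected random graphs with the
  component's exact node and link counts (G(n, l) conditioned on
  connectivity).
- **Component-size law** — the size distribution decays as P(s) ~ k^s;
  the base k is fitted by Levenberg–Marquardt least squares with 10% tail
  trimming, and two groups are compared by a normal test on the fitted
  slopes (SD = the width of the 68% CI).
- **Group statistics** — two-sample two-sided Kolmogorov–Smirnov tests on
  pooled per-component distributions with Šidák family-wise flagging
  (threshold 1 − (1 − α)^(1/m)), and Pearson correlation of per-subject
  metric means with clinical UPDRS scores.
- **Classification** — leave-one-*subject*-out cross-validated MLP
  classification of disease status from component-level feature panels
  (plain leave-one-out would leak, because each subject contributes many
  components), with pooled ROC/AUC and a 50× subject-level
  label-reshuffling control.

## Worked example

```python
import numpy as np
from mitotopo.cohort import CohortSpec, generate_cohort
from mitotopo.pipeline import component_metrics_table
from mitotopo.sizedist import compare_slopes, fit_component_sizes
from mitotopo.groupstats import ks_compare

spec = CohortSpec(n_group_a=5, n_group_b=5, components_per_subject=40,
                  max_size=20, seed=1)
table = component_metrics_table(generate_cohort(spec), n_random=50, seed=1)

pd_sizes = table.loc[table.group == "PD", "size"]
ct_sizes = table.loc[table.group == "control", "size"]
f1, f2 = fit_component_sizes(pd_sizes), fit_component_sizes(ct_sizes)
test = compare_slopes(f1, f2)
print(f"slope PD {f1.k:.3f}  control {f2.k:.3f}  p {test.p_value:.2e}")

ks = ks_compare(table.loc[table.group == "PD", "efficiency_z"],
                table.loc[table.group == "control", "efficiency_z"])
print(f"KS efficiency_z D {ks.statistic:.3f}  p {ks.p_raw:.4f}")
```

prints

```
slope PD 0.763  control 0.633  p 4.47e-02
KS efficiency_z D 0.206  p 0.0241
```

i.e. the disease-like group's components are governed by a heavier size
law (k = 0.763 vs 0.633 — larger subnetworks; at this toy cohort size the
slope test is just at the 5% boundary, and grows decisive with more
components), and the per-component efficiency Z-scores differ between the
groups (D = 0.206): disease-like wiring transfers "energy" less
efficiently, exactly the contrast the generator was asked to produce.

A command-line interface wraps the same stages:

```sh
mitotopo simulate --out cohort/ --seed 5
mitotopo extract  --in stack.tif --thr 0 --out net.tsv
mitotopo metrics  --manifest cohort/manifest.tsv --out metrics.tsv
mitotopo sizedist --manifest cohort/manifest.tsv --out slopes.json
mitotopo classify --manifest cohort/manifest.tsv \
    --features efficiency_z,aspl_z,tri3_z --min-size 8 --out cv.json
```

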