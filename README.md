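# tractometry

DTI tractometry of the superior longitudinal fasciculus (SLF): diffusion
tensor fitting, deterministic FACT tractography, waypoint-ROI dissection of
the SLF into its language-related II and III sub-branches, 100-node
diffusion-metric tract profiles, and node-wise group comparison with
family-wise error control — plus a synthetic DWI phantom and two-group
cohort generator so the whole pipeline can be validated end to end against
known ground truth.

## Who this is for

Neuroimaging researchers comparing white-matter microstructure between a
patient group and controls along a fiber tract rather than as a single
bundle average. The package implements the classical tractometry chain on
preprocessed diffusion-weighted images (eddy/motion/bias correction is
assumed done upstream) and is built around an acquisition of 3 b = 0 frames
plus 64 isotropically distributed directions at b = 1,000 s/mm² on a 1.5 mm
isotropic grid, although any single-shell scheme with ≥ 7 informative
frames works.

## The model and statistics

**Tensor.** Per voxel, the signal follows the Stejskal–Tanner single-tensor
model S(b, g) = S₀ exp(−b gᵀDg). Taking logs makes the fit linear in the six
unique components of D plus ln S₀; the package solves it by ordinary least
squares (a weighted variant is available). From the sorted eigenvalues
λ₁ ≥ λ₂ ≥ λ₃ of D:

- FA = √½ · √((λ₁−λ₂)² + (λ₂−λ₃)² + (λ₃−λ₁)²) / √(λ₁²+λ₂²+λ₃²)
- MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2

**Tracking.** FACT (fiber assignment by continuous tracking): from every
voxel with FA ≥ 0.3, follow the principal eigenvector of the current voxel
(nearest-voxel lookup, sign-aligned with the previous step, both polarities
from the seed), terminating on FA < 0.2, a turning angle > 30°, the grid
edge, or a length bound.

**Dissection.** A streamline belongs to a tract when it intersects both
waypoint ROIs of that tract: SLF II and III share a posterior coronal ROI
(MNI y = −25 mm) and are split by dorsal vs. ventral anterior ROIs on the
anterior-commissure plane (y = 2 mm); the whole SLF uses the union of the
anterior boxes. Bundles are scored against a fiber probability map and
cleaned of low-probability streamlines and length outliers.

**Profiles and statistics.** Each cleaned streamline is resampled to 100
equally spaced nodes, oriented anterior→posterior; FA/MD/AD/RD are sampled
trilinearly at each node and averaged across streamlines. Groups are
compared with an independent two-sample t-test per node, corrected for the
100-node family by permutation max-T (default) or Bonferroni, at α = 0.05;
summary tables report tract means (mean ± SD across subjects) and star a
metric when more than 10 nodes are significant.

## Worked example

Simulate a 15 + 15 cohort on the SLF-like phantom with a 10 % axial
diffusivity (AD) increase on nodes 30–70 of the right dorsal bundle in the
patient group, run every subject through the pipeline, and compare groups:

```python
import numpy as np, pandas as pd
import tractometry as tm

scene = tm.make_slf_like_scene(shape=(30, 36, 20))
effect = tm.EffectSpec(bundle="R_SLF_II", metric="ad",
                       node_range=(30, 70), factor=1.1, group="patient")
spec = tm.CohortSpec(n_per_group=15, snr=30.0, rng_seed=7, effects=(effect,))
subjects, truth, scene = tm.make_cohort(spec, scene)

frames = []
for s in subjects:
    profiles, qc = tm.analyze_subject(s.dwi, scene.rois, scene.prob_maps,
                                      subject_id=s.subject_id, group=s.group)
    frames.append(tm.profiles_to_dataframe(profiles))
cohort = pd.concat(frames, ignore_index=True)

model = tm.NodewiseGroupComparison(cohort, "patient", "control")
results = model.fit(method="permutation_maxT", n_perm=2000, rng_seed=7)

res = results[("SLF_II", "R", "ad")]
sig = np.flatnonzero(res.significant) + 1
print(f"R SLF_II AD: {res.n_significant} significant nodes "
      f"(nodes {sig.min()}-{sig.max()}), min FWE p = {res.p_fwe.min():.4f}")

summary = results.summary(min_sig_nodes=10,
                          scale={"md": 1e3, "ad": 1e3, "rd": 1e3})
view = summary[(summary.hemisphere == "R") & (summary.metric == "ad")]
print(view[["group", "tract", "metric", "cell", "n_sig_nodes"]]
      .to_string(index=False))
```

This prints:

```
R SLF_II AD: 43 significant nodes (nodes 29-71), min FWE p = 0.0005
  group   tract metric         cell  n_sig_nodes
patient     SLF     ad 1.21 ± 0.00*           41
control     SLF     ad 1.18 ± 0.00*           41
patient  SLF_II     ad 1.23 ± 0.00*           43
control  SLF_II     ad 1.18 ± 0.00*           43
patient SLF_III     ad  1.18 ± 0.00            0
control SLF_III     ad  1.18 ± 0.00            0
```

The injected effect is recovered where it was planted: the right SLF II AD
comparison is significant over nodes 29–71 (the true range was 30–70, so
localization is within one node), the whole right SLF — which contains the
affected streamlines — is starred too, and the unaffected SLF III shows no
significant nodes. AD cells are in 10⁻³ mm²/s; the between-subject SD of
these phantom tract means is below 0.005 and rounds to 0.00 at two
decimals.

The same run is available from the shell: `tractometry phantom` writes a
cohort as NIfTI + bval/bvec, `tractometry run-subject` processes one
subject from a YAML config, and `tractometry run-group` writes node-wise
statistics, a summary table and profile figures with significance
asterisks.

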