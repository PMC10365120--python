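# Methods

This note documents the models, algorithms, parameter defaults and design
choices behind the package, and what the synthetic phantom does and does
not establish about real data.

## Coordinate conventions

World coordinates are RAS+ millimeters; voxel indices are 0-based with the
voxel center at the integer index; a dataset's 4×4 affine maps homogeneous
voxel indices to world mm. Streamlines are stored in world mm (TrackVis
.trk on disk, 32-bit floats, hence the 1e-4 mm round-trip tolerance).
Gradient tables follow the FSL text layout; frames with b ≤ 50 s/mm² count
as b = 0, which tolerates nominally nonzero b0 frames.

## Tensor estimation

The single-tensor Stejskal–Tanner model is linearized by taking logs:
ln S = X·(Dxx, Dyy, Dzz, Dxy, Dxz, Dyz, ln S₀), with design row
−b·(gx², gy², gz², 2gxgy, 2gxgz, 2gygz) plus an intercept column for ln S₀.
The default estimator is ordinary least squares on the log signal:
deterministic, closed-form, and accurate at the SNR regimes the phantom
emulates. A one-pass weighted variant (`fit_method="wls"`, weights =
squared OLS-predicted signals) is available for low-SNR data where the
log transform's heteroscedasticity matters.

Numerical guards:

- signals ≤ 0 are floored at 1e-6 × max(b0 signal) before the log, so
  noisy background voxels cannot produce −∞;
- voxels whose frames are all ≤ 0 get NaN outputs;
- negative eigenvalues (a noise artifact that would push FA above 1) are
  clamped to 0 and counted in `n_clamped_eigenvalues` for QC;
- FA of the zero tensor is defined as 0.

Scalar maps are FA, MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2; the
identity MD = (AD + 2·RD)/3 holds to machine precision by construction.

## FACT tracking

The tracker follows the per-voxel principal eigenvector with
nearest-voxel lookup (no interpolation — the defining property of FACT),
bidirectionally from each seed, concatenating the two half-tracks. The
eigenvector's sign is resolved by dot-product alignment with the previous
step direction; at the seed both polarities are tracked.

Termination: entering a voxel with FA < `fa_stop` (0.2; the offending
point is not appended), a turning angle between consecutive step
directions above `max_angle_deg` (30°, measured over a one-step lag),
leaving the grid, or exceeding `max_len_mm`. Tracks shorter than
`min_len_mm` are discarded.

Defaults and why:

- `step_mm = None` resolves to half the smallest voxel dimension (0.75 mm
  at 1.5 mm voxels). Sub-voxel stepping keeps the 30° angle rule
  meaningful while the eigenvector stays piecewise constant per voxel;
  `step_mm = 1.5` (one voxel) reproduces the classical center-to-center
  behaviour and is what the length validation uses.
- Seeding: one seed at the center of every voxel with FA ≥ 0.3, raster
  order, optional seeded jitter / multi-seeding. The seed FA threshold is
  deliberately above the stopping threshold so tracks start in coherent
  white matter.
- `min_len_mm = 20`, `max_len_mm = 250`: conventional bounds for
  association fibers; both configurable.
- Everything is deterministic given the parameters; jitter is the only
  stochastic element and is driven by `rng_seed`.

Not implemented (out of scope by design): probabilistic tracking,
trilinear eigenvector interpolation, and crossing-fiber models — the
single-tensor principal direction cannot represent crossing populations,
which is the method's main anatomical limitation.

## SLF dissection

A streamline joins a bundle when it has at least one point inside each ROI
of the bundle's waypoint pair. SLF II and III share the posterior
commissure coronal ROI (MNI y = −25 mm) and are separated on the anterior
commissure plane (y = 2 mm): SLF II dorsal, SLF III ventral. The whole
SLF is dissected with the union of the two anterior boxes, so its
streamline set contains both sub-branches — summary statistics of the SLF
therefore co-vary with effects in either branch.

The two plane y-coordinates are anatomy; the in-plane box extents shipped
as defaults are **not** anatomically validated — they are configurable
placeholders documented in `DEFAULT_SLF_ROI_CONFIG`, and all quantitative
validation uses phantom-space ROIs whose correctness is by construction.
MNI→native registration is reduced to a user-supplied affine (identity in
phantom space): estimating nonlinear warps is out of scope, and any
externally computed transform can be passed in. Affines that keep coronal
planes coronal transform plane ROIs analytically; others require
rasterizing the ROI to a mask first (nearest-neighbor resampling).

Cleaning: streamlines scoring below the 5 % quantile of the bundle's
probability-map score (mean trilinearly interpolated probability along the
track) are dropped, then length outliers with |z| > 3 are pruned
iteratively (z-scores recomputed each round, at most 5 rounds). The lesion
screen marks a tract affected when any lesion voxel lies at fiber
probability > 0.5 (strict); a majority-voxel variant is exposed as a flag
because the any-voxel reading is a choice, not a law.

## Tract profiles

Streamlines are resampled to `n_nodes = 100` points equally spaced in arc
length (piecewise-linear, endpoints preserved), oriented
anterior→posterior (decreasing world y; ties broken by distance to the
anterior ROI centroid), and the scalar maps are sampled trilinearly at
each node point. The node value is the uniform mean across streamlines
(default), with `gaussian_distance` weighting available — weights
exp(−d²/2σ²) with d the distance to the node's cross-streamline mean
position and σ the node's RMS point-cloud spread. Uniform is the default
for transparency; the two coincide on tight bundles. Node SE is the
(weighted) SD across streamlines divided by √m.

## Group statistics

Per node, an independent two-sample t-test (equal-variance by default;
Welch by flag) on subject-level node values, df = n₁ + n₂ − 2. Nodes with
zero pooled variance get t = 0, p = 1 and a degeneracy flag.

Family-wise error over the 100 nodes is controlled by permutation max-T:
group labels are permuted (default 10,000 draws, or exhaustive
enumeration when requested), the null is the distribution of the maximum
|t| over nodes, and a node's adjusted p is the fraction of the null
reaching its observed |t| (add-one corrected for sampled permutations).
Bonferroni is the conservative alternative. Adjusted p-values are floored
at the raw p so the monotonicity invariant holds exactly. Significance is
α = 0.05 on adjusted p.

Summary tables report, per (group, tract, metric), the mean ± SD across
subjects of each subject's all-node tract mean, and star a metric when
significance holds in more than `min_sig_nodes = 10` nodes — sustained
spatial extent rather than isolated nodes. The tract mean averages all
100 nodes; the star rule is the only place the 10-node threshold enters.

## The synthetic phantom

What it emulates: the acquisition (3 b0 + 64 electrostatically optimized
directions at b = 1,000 s/mm², 1.5 mm isotropic voxels), magnitude-MRI
Rician noise (magnitude of a complex Gaussian perturbation, σ = S₀/SNR,
default SNR 30), an SLF-like geometry (per hemisphere a dorsal and a
ventral sagittal arc threading a common posterior plane and separate
anterior boxes), white-matter-like tensors inside bundles
(λ = (1.2, 0.45, 0.45)×10⁻³ mm²/s, FA ≈ 0.55, MD = 0.7×10⁻³ — chosen once
to sit near typical adult SLF values), isotropic background
(0.7×10⁻³ mm²/s, FA 0), per-subject rigid geometric jitter (translation
SD 0.5 mm), and two-group cohorts of 15 + 15 subjects with node-localized
effects injected on the eigenvalues (AD scales λ₁, RD scales λ₂ and λ₃,
MD scales all three, FA scales the deviations about the mean preserving
MD), so the four metrics stay mutually consistent and the true per-node
values are recorded in a ledger.

What it does not emulate: anatomically realistic geometry, crossing
fibers, partial-volume heterogeneity beyond tube edges, susceptibility or
eddy distortions, motion, or spatially varying noise. Passing the
phantom-based tests therefore establishes the *correctness of the
computational chain* under the stated model — not the anatomical validity
of the default ROI boxes, nor robustness to acquisition artifacts that
preprocessing is assumed to have removed.

Probability maps are kernel-smoothed (Gaussian, 2 mm) bundle occupancy
masks normalized to [0, 1] — synthetic stand-ins for a published fiber
probability atlas. Lesion masks are planted spheres: one on a left bundle
(probability > 0.5, screened "affected") and one in background.

A profile-level generator (`simulate_profile_cohort`) draws subject node
curves directly — shared mean, per-subject offset, node-wise noise
smoothed along nodes — and is used where only the statistical machinery is
under test (null calibration at volume), because it is orders of magnitude
cheaper than simulating and fitting DWI volumes.

## Validation experiments and problem sizes

The end-to-end experiments run on a reduced 30×36×20 grid at 1.5 mm
(the default scene is 60×72×60): large enough for ~50 mm arcs, 100-node
profiles and ~350 streamlines per hemisphere, small enough that a full
subject (simulate → fit → track → dissect → profile) takes well under a
second. Null calibration uses 500 profile-level replicate cohorts
(n = 15/group, 500 permutations); effect recovery uses 20 full-pipeline
replicate cohorts (SNR 30, n = 15/group, AD ×1.1 on nodes 30–70 of the
right dorsal bundle, 2,000 permutations). Recovery is scored with the
star rule; ground-truth-affected (tract, metric) pairs are derived from
the cohort ledger — note that an AD effect also shifts MD and FA, and the
whole-SLF tract contains the affected streamlines, so those pairs count
as affected, not as false alarms.

## Known limitations

- Single-tensor model: crossing-fiber regions bias FA downward and can
  misdirect FACT; the dissection inherits this.
- OLS on log signals is mildly biased at low SNR; use the WLS flag there.
- Default ROI boxes are placeholders; anatomical use requires
  study-specific extents and a real MNI→native transform.
- The phantom's inter-subject variability is a rigid jitter; real
  cohorts vary in geometry and microstructure far more richly, so
  phantom-based power estimates are optimistic.
- The permutation max-T assumes exchangeability under the null; strong
  group-wise variance differences call for the Welch flag, which makes
  the permutation approximate.
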