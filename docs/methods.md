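# Methods

## Statistical model

The analysis unit is a voxel of a common coordinate system holding, across
`n` subjects, an image-derived value `x_i(s)` (e.g. a Jacobian determinant).
Association with a per-subject scalar covariate `c(s)` is measured by the
Pearson correlation `r_i` at each voxel. Both correlation signs are of
interest, so every correction operates on `|r|` (two-sided tests throughout).
Exact p-values use the t transform `t = r·sqrt((n-2)/(1-r^2))` with `n-2`
degrees of freedom; the Gaussianized maps needed by random-field theory use
the Fisher transform `z = atanh(r)·sqrt(n-3)`. Voxels with a constant subject
series have no defined correlation and are removed from the analysis mask
with a logged count — silently zeroing them would bias max-type statistics.

The corrections control the familywise error rate (FWER) at level α:

* **Bonferroni / Holm** on the voxelwise p-values (Holm's step-down
  uniformly dominates Bonferroni; both stay valid under arbitrary
  dependence). Holm is delegated to `statsmodels.multipletests`.
* **RFT voxel level:** the threshold `u` solves `E[EC](u) = α/2` (two tails),
  where the expected Euler characteristic uses the four Gaussian EC
  densities with resel counts; the volume term comes from the true mask
  volume divided by the FWHM product, the edge/face terms from the mask's
  bounding box. Smoothness is estimated from normalized residual spatial
  derivatives: `FWHM_axis = voxel_size_axis · sqrt(4·ln2 / var(diff))`. On
  white noise this estimator yields ≈1.18 voxels — of the order of the voxel
  size, its standard behavior.
* **RFT cluster level:** supra-threshold clusters of `|z| ≥ primary_z` get
  the stationary-Gaussian extent p-value `1 - exp(-E[m]·exp(-β·k^(2/3)))`
  with `E[m]` the expected cluster count at the primary threshold, doubled
  for two-sidedness. The RFT route deliberately reproduces the vanilla
  stationary procedure, including its fragility on anisotropic, marginally
  smooth whole-body data — that behavior is part of what the evaluation
  protocols are meant to expose.
* **Permutation corrections:** the covariate is permuted across subjects (the
  cheapest action equivalent to permuting subjects for a correlation
  analysis); per permutation the |r| map is recomputed and a max-type
  statistic recorded — max |r| (voxel level), k-th largest |r| (k-FWER), max
  supra-threshold cluster extent at the primary threshold, or max TFCE
  score. Corrected p = #{null ≥ observed}/n_perm with the identity
  permutation always included, so p ≥ 1/n_perm and validity holds by
  construction. For k > 1 an observed voxel can exceed every permutation's
  k-th max; its p is floored at 1/n_perm to stay in (0, 1].
* **TFCE:** per voxel, the Riemann sum over thresholds `t = t0+dt, ...` up to
  the map maximum of `e(t)^E · t^H · dt`, where `e(t)` is the extent of the
  supra-`t` component containing the voxel. Negative signal is handled by a
  second pass over the negated map; the two passes have disjoint support and
  merge by maximum. Thresholds are compared with a relative tolerance of
  1e-9 so a voxel of height `h` is included at the accumulated threshold
  `t = k·dt == h`.
* **CBA:** the image is prepartitioned by linking each voxel to the neighbour
  with the highest pilot-series correlation divided by the physical
  inter-centre distance (penalizing edge/vertex neighbours on an anisotropic
  grid); clusters are connected components of the undirected link graph, and
  score ties break toward the lowest linear voxel index so runs are
  reproducible. Cluster signals are the means of member voxel statistics;
  the inner correction is either Holm (the mean r converted to p through the
  same t transform as single voxels — an approximation, since a mean of
  correlations is not itself a correlation, exact in the all-singleton case)
  or the max-statistic permutation test on recomputed cluster means. The
  pilot stack must be data excluded from the subsequent analysis; a single
  reference image does not define inter-voxel correlations, so a pilot
  *stack* (≥3 samples) is required.

## Anatomy-aware corrections

Given a segmentation with structures `C_k` of extents `e_X` (largest:
`e_max`), four extensions:

* **Per-organ weighted statistic.**
  `S_k = (1/|U_k|) · Σ_{i∈U_k} x_i·a_k(i)` over the support `U_k`, dividing
  by the support size, not the weight sum — down-weighted border voxels
  dilute rather than renormalize the mean. Accuracy `a_k` comes from
  annotator agreement (`a_k(i) = n_i/N`) or from border down-weighting
  (interior weight 1, the 1-voxel outermost layer 0.1 by default). Each
  organ's |S_k| is tested against its own permutation distribution — a
  cross-organ max statistic would need signals normalized to be comparable
  across organs of very different size and label confidence — and the K
  per-organ p-values are Holm-adjusted. Organs whose support retains no
  testable voxel (e.g. all-constant series) are skipped with a warning.
* **Anatomy-scaled TFCE.** Identical to plain TFCE except components are
  computed within each structure's support and extents are scaled by
  `e_max/e_X` before the E exponent; a cluster of 3 voxels in a 9-voxel
  organ with `e_max = 45` scores like a 15-voxel cluster in the 45-voxel
  organ. With one whole-mask structure the transform equals plain TFCE
  bitwise (same accumulation path, scale factor 1.0).
* **Organ-constrained scaled cluster extent.** The cluster-extent permutation
  test with clusters confined to structures and the statistic
  `extent·e_max/e_X`; the null records the maximal scaled extent per
  permutation. Multiple clusters within one organ are tested separately by
  default (`join_within_organ=True` pools them); the resulting p-values
  refer to clusters spanning a given fraction of *some* organ, not to whole
  organs.
* **Anatomy-restricted CBA** drops cross-label links during clustering, and
  **k-FWER** can take `k` = (a fraction of) the smallest organ extent, so
  the allowed false positives can never swamp the smallest organ's
  inference.

Background (label 0) voxels are excluded from anatomy-aware corrections by
default; `strict=True` raises instead for pipelines that require a complete
labelling.

## Default parameters

| parameter | default | meaning |
|---|---|---|
| α | 0.05 | FWER target |
| primary p | 0.001 | two-sided cluster-defining threshold, converted to an r threshold at the analysis n |
| TFCE H, E, dt, t0 | 2, 0.5, 0.1, 0 | height/extent exponents, integration step and lower bound (upper bound: map max) |
| inner / border weight | 1.0 / 0.1 | border down-weighted accuracy |
| connectivity | 26 | 3D neighbourhood (6/18/26 configurable) |
| n_perm | 1000 | permutation count; p resolution 1/n_perm matches the primary-threshold scale |

## The phantom

The synthetic generator emulates the statistical structure the corrections
assume: an anisotropic grid (default voxel size 2×8×2 mm, matching the coarse
slice spacing of whole-body protocols), a deterministic segmentation whose
label 1 is always a large "fat shell" (solid block when `n_organs = 1`,
hollow outermost body layer otherwise) with interior box organs whose
cross-sections shrink to guarantee at least a 2× extent ratio, Gaussian
subject noise smoothed by a configurable FWHM (globally rescaled back to
`noise_sd`), and per-label linear effects: voxel value =
`effect·covariate + noise`, so the population correlation in a structure with
effect `a` is `a/sqrt(a² + noise_sd²)` and a noiseless nonzero effect gives
r = ±1 exactly. One master seed drives deterministic per-stage substreams.

It does **not** emulate registration error, intensity inhomogeneity,
non-Gaussian noise, spatially varying smoothness, or realistic organ shapes.
Passing calibration and power checks on the phantom therefore demonstrates
correctness of the procedures under their stated assumptions, not performance
on real cohorts.

## Evaluation protocols

* **Null calibration:** one fixed phantom stack; per run a fresh
  standard-normal covariate; the nominal FWER of a method is the fraction of
  runs with any significance after correction. On synthetic noise the global
  null is true by construction; on real data a random correlate does not
  guarantee the null at every voxel, so the rate is reported as an
  approximation. A k-FWER procedure controls P(≥ k false positives), so its
  calibration is assessed on the fraction of runs with ≥ k significant
  voxels, not ≥ 1. Permutation methods accept a reduced n_perm here (the
  cost hotspot is runs × permutations); the report records both knobs.
* **Activity retention:** counts of significant voxels inside/outside a
  truth mask, optionally excluding the truth's outer boundary layer from both
  counts to absorb registration/segmentation uncertainty at organ borders.

Problem sizes used by the shipped checks: the calibration studies run on 24³
(50 subjects, 200 runs, step-down corrections) and 16³ (20 subjects, 100
runs, n_perm = 200, permutation corrections) phantoms; the power study uses a
16³ phantom with 50 subjects and n_perm = 1000. These sizes exercise every
code path at full statistical fidelity while keeping the default suite quick
to run.

## Numerical choices and degenerate inputs

* Corrected p-values never reach 0 (identity permutation included; RFT and
  parametric p clipped to the smallest positive float before capping at 1).
* `|r| = 1` maps to the smallest positive p with a logged warning.
* Empty supra-threshold sets yield empty cluster results, not errors.
* CBA voxels with constant pilot series become logged singleton clusters.
* TFCE threshold comparison tolerance 1e-9 (relative); anatomy/plain TFCE
  agreement tolerance 1e-12 in tests.
* Exhaustive permutation enumeration is refused beyond 50 000 orderings.

## Known limitations

* RFT assumes stationary Gaussian fields; the implementation intentionally
  does not correct for non-stationarity or estimate Gaussianization error.
* The CBA inner-Holm route treats cluster mean correlations as correlations
  for the p conversion (exact only for singleton clusters).
* FDR/FDP-controlling procedures and the Hochberg step-up are out of scope:
  the package targets strict FWER-style guarantees per experiment.
* The anatomy-scaled statistics assume activity relates to whole structures;
  small partial activations inside large organs lose power by design.
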