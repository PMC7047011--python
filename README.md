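# anatcorr

Anatomy-aware multiple-comparison correction for whole-body MRI voxelwise
correlation analyses.

## The problem

Whole-body MR studies correlate a per-subject scalar (bioimpedance fat mass,
triglycerides, ...) with an image-derived value (e.g. the Jacobian determinant
of a deformable registration) at every voxel of a common coordinate system.
With hundreds of thousands of simultaneous tests, uncorrected thresholding of
the voxelwise p-values all but guarantees false "activations", so the
familywise error rate (FWER) — the probability of *any* false positive in the
map — has to be controlled. Most corrections were developed and validated on
neuroimaging data; whole-body volumes are strongly anisotropic, contain organs
of wildly different sizes, and come with reference segmentations that the
classical corrections ignore.

`anatcorr` implements, for researchers running such analyses:

* **Classical FWER corrections** — Bonferroni, Holm step-down, random-field
  theory (RFT) at voxel and cluster level on Fisher-z maps, permutation
  max-statistic corrections (voxel |r|, cluster extent, k-th max for k-FWER),
  TFCE, and cluster-based analysis (CBA) on a correlation-derived
  prepartition.
* **Anatomy-aware extensions** that inject an organ segmentation into the
  correction:
  * a per-organ weighted statistic
    `S_k = (1/|U_k|) · Σ_{i∈U_k} x_i·a_k(i)` with voxel accuracy weights
    `a_k(i)` (annotator agreement `n_i/N`, or border down-weighting), tested
    per organ by permutation and Holm-adjusted across the K organs;
  * anatomy-scaled TFCE,
    `TFCE(x) = Σ_t (e(t)·e_max/e_X)^E · t^H · dt`, where cluster support
    `e(t)` grows only inside the organ X and is rescaled by the largest organ
    extent `e_max`, so a small activation filling a small organ scores like a
    proportionally larger one in the largest organ;
  * organ-constrained cluster-extent permutation testing with the same
    `e·e_max/e_X` scaling;
  * anatomy-restricted CBA clustering (merges never cross organ boundaries);
  * an anatomy-informed bound for k in k-FWER control (the smallest organ
    extent).
* **Evaluation protocols** — nominal FWER estimation over repeated analyses
  against a fresh standard-normal null covariate, and activity-retention
  counting against a known-truth mask — driven by a **synthetic body
  phantom** (anisotropic grid, labelled structures of varied sizes including
  a fat-shell, smooth subject noise, controllable effects).

Everything operates on NIfTI-1 volumes (4D subject stacks, subject axis last),
CSV covariates, and TSV label tables; a `click` CLI (`anatcorr`) wraps the
pipeline.

## Worked example

Simulate a 16³ phantom (voxel size 2×8×2 mm) with three structures where only
organ 3 (180 voxels) carries signal, then compare corrections at α = 0.05:

```python
import numpy as np
from anatcorr.phantom import (PhantomConfig, make_segmentation,
                              make_null_covariate, simulate_subjects)
from anatcorr.statmap import voxelwise_correlation
from anatcorr.evaluation import standard_method_suite, activity_retention

cfg = PhantomConfig(shape=(16, 16, 16), voxel_size=(2.0, 8.0, 2.0), n_organs=3,
                    n_subjects=50, noise_sd=1.0, smooth_fwhm=6.0,
                    effect_by_label={3: 0.8}, seed=0)
seg = make_segmentation(cfg)
cov = make_null_covariate(cfg.n_subjects, seed=42)
stack = simulate_subjects(seg, cov, cfg)

rmap = voxelwise_correlation(stack, cov, seg.body_mask)
truth = seg.labels == 3
for name in ["holm", "perm-voxel", "tfce", "anat-tfce", "organ"]:
    suite = standard_method_suite([name], alpha=0.05, n_perm=1000)
    res = suite[name](stack, cov, seg.body_mask, seg, 7)
    rep = activity_retention(res, truth)
    print(f"{name:>10}: {res.n_significant_voxels:4d} significant voxels "
          f"({rep.retained_true}/{rep.truth_size} in the active organ, "
          f"{rep.detected_outside} outside)")
```

Output:

```
      holm:  180 significant voxels (180/180 in the active organ, 0 outside)
perm-voxel:  180 significant voxels (180/180 in the active organ, 0 outside)
      tfce:  181 significant voxels (180/180 in the active organ, 1 outside)
 anat-tfce:  180 significant voxels (180/180 in the active organ, 0 outside)
     organ:  180 significant voxels (180/180 in the active organ, 0 outside)
```

Every method recovers the full active organ; plain TFCE lets one spurious
voxel through while its anatomy-scaled variant, confined to organ supports,
does not. The same pipeline runs from the shell:

```bash
anatcorr simulate --shape 16,16,16 --n-organs 3 --n-subjects 50 \
    --effect 3=0.8 --seed 0 --out-dir phantom/
anatcorr correct --method anat-tfce --stack phantom/stack.nii.gz \
    --covariate phantom/covariate.csv --segmentation phantom/segmentation.nii.gz \
    --labels phantom/labels.tsv --n-perm 1000 --seed 7 --out-dir results/
anatcorr evaluate-null --config phantom.yaml --methods bonferroni,holm \
    --n-runs 200 --seed 0 --out report.tsv
```

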