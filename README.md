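# renalseg

Automated 3D kidney segmentation for dynamic (multi-phase contrast)
abdominal CT-like volumes. The package is aimed at medical-image-analysis
researchers who need a fully scripted, reproducible voxel-classification
pipeline — and a synthetic phantom cohort to exercise it end to end when no
clinical data is at hand.

## Method

Each voxel **p** of a grayscale volume `g` is assigned a label
`m_p ∈ {KT, OT}` (kidney / other tissue) by a bagged random forest over a
9-dimensional descriptor built from three channels:

1. **Appearance** — the local Hounsfield-like value, min–max normalized per
   volume.
2. **Adaptive shape prior** `P_s:p(KT)` — after two-step co-alignment
   (12-DOF affine, then B-spline free-form deformation) of the test scan to
   an atlas of co-registered training scans, the `N` most NCC-similar atlas
   scans are selected and, at each voxel, atlas voxels `ρ` inside a search
   cube `C_p` with `|g_{i:ρ} − g_{t:p}| ≤ τ` are collected:
   `P_s:p(KT) = Σ_i Σ_{ρ∈v_i:p} δ(KT − m_{i:ρ}) / v_p` — the KT fraction of
   the intensity-matched neighborhood, pooled over the selected atlases.
3. **Higher-order spatial model** `P_G:p(KT)` — a Potts Markov–Gibbs random
   field on the 18-connectivity neighborhood with pairwise, collinear-triple
   and planar-quad clique families, whose potentials are estimated
   analytically from an initial shape-and-intensity labeling
   (`V_a = K²/(K−1)·(f_eq − K^{1−n})`, `K = 2`), followed by one sweep of
   Gibbs conditional probabilities.

Each channel contributes its local value, its 26-neighbor cube mean and its
8-neighbor in-plane mean. The forest (default 400 trees) votes per voxel;
`P(KT) ≥ 0.5` labels kidney, and a 3D median filter smooths the result,
which is finally mapped back to the scan's native grid. Evaluation uses the
Dice coefficient (DC, %), percentage volume difference (PVD, %), the
bidirectional 95th-percentile Hausdorff distance (BHD95, mm) and ROC/AUC.
See `docs/methods.md` for the full model description and design rationale.

## Worked example

```python
import renalseg as rs

# a reproducible 6-subject synthetic cohort: 3 contrast phases per subject,
# 64^3 voxels at 0.64 x 0.64 x 0.9 mm, with noise, bias and distractors
cohort = rs.generate_cohort(rs.PhantomSpec(), n_subjects=6, master_seed=7)

config = rs.PipelineConfig(
    n_atlas=15,   # protocol N = 19, truncated to the 15 scans a fold offers
    n_trees=400,
    seed=7,
    max_train_voxels_per_class_per_volume=1500,
)
result = rs.loso_evaluate(cohort, config)   # leave-one-subject-out, 18 scans
print({k: round(v, 3) for k, v in result.summary.items()})
```

which prints (about 11 minutes on one CPU):

```
{'mean_dc': 94.816, 'sd_dc': 2.352, 'mean_abs_pvd': 6.032, 'sd_abs_pvd': 5.329,
 'mean_bhd95_mm': 2.294, 'sd_bhd95_mm': 2.28, 'mean_auc': 1.0, 'sd_auc': 0.001,
 'pooled_auc': 0.999, 'n_scans': 18}
```

i.e. on the moderate-difficulty phantom the pipeline overlaps the ground
truth by a mean Dice of ~95 %, misestimates kidney volume by ~6 % on
average, keeps 95 % of surface error within ~2.3 mm on average, and ranks
kidney above background voxels almost perfectly (pooled AUC ≈ 1.0).
Per-scan reports are in `result.reports`, keyed by (subject, phase).

The same pipeline is scriptable from the shell:

```bash
renalseg phantom --subjects 6 --seed 7 --out cohort/
renalseg loso --subjects 6 --seed 7 --out results/
renalseg evaluate --truth G.nii.gz --seg S.nii.gz --prob P.nii.gz --out report.json
```

plus `register`, `shape-prior`, `mgrf-prob` and `segment` subcommands for
the individual stages (`renalseg --help`).

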