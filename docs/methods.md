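# Methods

`renalseg` segments the kidney (label KT) from 3D dynamic abdominal CT-like
volumes against background (OT) by voxel-wise random-forest classification
over three feature channels: first-order appearance, an adaptive
appearance-conditioned atlas shape prior, and higher-order Potts
Markov–Gibbs spatial probabilities. This note records the model, its
assumptions, the tunable parameters, and the design decisions taken where
the problem was genuinely open.

## Lattice and data model

Volumes live on the 3D arithmetic lattice `R = {(x, y, z) : 0 ≤ x < X, …}`
with anisotropic physical spacing in mm (default 0.64 × 0.64 × 0.9). A scan
is a grayscale map `g : R → Q` of Hounsfield-like values; a segmentation is
a label map `m : R → {KT, OT}`, encoded on disk as 1/0 in NIfTI. Grids are
*compatible* when dims match and spacings agree to a relative 1e-6; no
operation mixes incompatible grids. Any finite scalar intensity range is
accepted — the framework never assumes a calibrated HU window.

## Two-step co-alignment

All scans are brought into a common atlas space anchored by one reference
scan (the first training subject's postcontrast scan; for a standalone
segmentation, the mean atlas image is the registration target). Alignment
is a 12-DOF affine (3 translations, rotations, scales, shears) followed by
a 3D B-spline free-form deformation, both maximizing normalized cross
correlation (NCC):

* **Affine** — multi-resolution (shrink 4/2/1), regular-step gradient
  descent, 100 iterations per level, metric evaluated on a seeded random
  25 % voxel subset. Parameter scales are set from physical shifts so mm
  and radians are commensurate.
* **B-spline** — control knots every 8 voxels, L-BFGS-B for 15 iterations
  at half resolution on a 10 % voxel subset. A smooth field has no
  finest-scale content worth the ~100× cost of a full-resolution solve at
  these volume sizes. The step is guarded: if the optimized field lowers
  NCC relative to the affine alone, a zero field is returned, so the chain
  objective is monotone by construction.

Transforms follow the resampling convention (fixed-space point → moving-
space point). Label maps are propagated with nearest-neighbor
interpolation only — no new labels can appear. Final outputs are mapped
back to the test scan's native grid through the exact affine inverse
composed with a fixed-point numerical inversion of the B-spline
displacement field, so evaluation happens in the subject's own geometry.

## NCC atlas selection and the adaptive shape prior

For a co-aligned test scan the `N` most NCC-similar atlas scans are
selected (default `N = 19`, the protocol value; ties break
deterministically by subject/phase). Selection pools all contrast phases.

The shape prior is appearance-conditioned. At voxel `p`, each selected
atlas image `i` contributes the voxels `ρ` inside a search cube `C_p`
whose intensity matches the test voxel within a fixed signal range `τ`:
`|g_{i:ρ} − g_{t:p}| ≤ τ`. Then

    P_s:p(KT) = (# matched voxels labeled KT) / (# matched voxels),

pooled over the selected atlases with equal weight. `P_s:p(OT) = 1 −
P_s:p(KT)` by construction.

Parameters and degenerate cases:

* `τ = 50` intensity units by default — wide enough to match within-class
  variation under moderate noise and bias, narrow enough to keep cortex
  and background separate in the enhanced phases. It is a plain config
  field (`ShapePriorParams.tau`).
* The cube starts at half-width 1 (3×3×3) and, for voxels with *no* match,
  grows one step at a time up to half-width 5 (11×11×11). The count is
  undefined when nothing matches; progressive growth keeps the prior as
  local as possible, and voxels that never match fall back to the
  uninformative 0.5. The initial cube is evaluated for the whole volume
  vectorized; only the (typically few hundred) unmatched voxels grow their
  cubes individually.

## Higher-order Potts spatial model

Label interactions are modeled with 21 translation-invariant clique
families built from 18-connectivity steps: 9 pairwise families (one per
unique direction: 3 axis, 6 edge-diagonal), 9 collinear triples
`{p−d, p, p+d}`, and 3 planar 2×2 quads — the minimal translation-invariant
triple/quad geometries consistent with the 18-neighborhood. Each family
`a` of order `n` has one scalar potential applied as `+V_a` when all
clique labels coincide and `−V_a` otherwise (Potts form).

Potentials are estimated analytically from the empirical all-equal clique
rate `f_eq(a)`:

    V_a = K²/(K−1) · (f_eq(a) − K^(1−n)),   K = 2,

the closed-form maximum-likelihood estimate for the pairwise two-label
Potts model, extended uniformly to orders 3 and 4. The estimate centers
`f_eq` at its expectation under independent uniform labels, so iid labels
give `V ≈ 0`, a constant map gives `V = 2` (pairwise), and a checkerboard
gives `V = −2` along the alternating axes.

The model is self-calibrated per volume: an initial labeling `m⁰` is the
voxel-wise MAP of (shape prior × Gaussian class likelihood), with the
per-label intensity means/sds pooled from the selected atlas (sds floored
at 1e-3; ties label OT). Potentials are estimated from `m⁰`, and a single
sweep of Gibbs conditionals produces `P_G:p(KT)` — the softmax over both
label hypotheses of the signed potential sums over every clique containing
`p`. Cliques extending outside the lattice are skipped (free boundary) in
both estimation and the conditionals. There is no iterated inference: the
map is a feature channel for the classifier, not a standalone segmenter.

## Features and classification

Each voxel gets 9 features: for each channel (normalized appearance, P_s,
P_G) the local value, the mean over the 26-neighbor cube, and the mean over
the 8 in-plane neighbors. Means exclude the center voxel and truncate at
volume borders (no padding values are invented). Appearance is min–max
normalized to [0, 1] per volume so no channel dominates; a constant
appearance channel maps to zeros with a warning.

The classifier is a bagged random forest, default 400 trees, 3 features
(√9) considered per split, trees grown to standard library stopping rules.
Output probability is the fraction of trees voting KT (with fully grown,
near-pure leaves the library's averaged leaf posteriors coincide with the
vote fraction); the label rule is `P ≥ 0.5 → KT`. A 3D median (binary
majority) filter over a 3×3×3 cube (radius 1 by default, exact ties → OT)
smooths the voted labels.

**Training-set construction.** The forest is retrained per test scan on
the `N` selected atlas scans. Two choices here are the package's own:

* *Training scans are featurized exactly like test scans.* A training
  scan's shape prior and spatial channel are computed against the fold
  database with **all scans of its own subject excluded** (then NCC
  top-N selected), mirroring the leave-one-subject-out condition the test
  scan experiences. Excluding only the identical scan would leak the
  sibling contrast phases — which share the subject's exact anatomy —
  into its prior, and train the classifier on a feature distribution the
  test scan never sees. In cohorts where a fold contains a single
  subject this is impossible and the identical-entry exclusion is the
  fallback.
* *Stratified voxel subsampling with hard negatives.* To keep desk-scale
  runtimes, each training volume contributes at most a capped number of
  voxels per class (default 2000). All kidney voxels are eligible; the
  background budget is split between a uniform draw and *hard negatives* —
  background voxels whose intensity falls inside the kidney intensity
  range — so rare confusable structures (adjacent organs with kidney-like
  enhancement) survive subsampling. Sampling is seeded; `None` disables
  the cap.

## Evaluation

For ground truth `G` and segmentation `S` (KT voxel sets):

* `DC = 100 · 2|G∩S| / (|G| + |S|)` (percent),
* `PVD = 100 · (|G| − |S|) / |G|`, reported signed and as |PVD| (cohort
  summaries use the absolute value; per-scan signs are retained),
* `BHD95` — symmetric 95th-percentile Hausdorff distance between the two
  KT surfaces in mm. Surfaces are KT voxels with a 6-connected face
  neighbor that is OT or outside the volume; distances are between voxel
  centers with anisotropic spacing respected; percentiles use the
  nearest-rank convention, so percentile 1.0 is the classical maximum.
* ROC/AUC — threshold sweep over the distinct probability values,
  trapezoidal area; equals the normalized Mann–Whitney U statistic.

Degenerate inputs raise: Dice with both sets empty, PVD with empty truth,
Hausdorff with an empty surface, ROC with single-class truth, NCC of a
constant volume, forest training with a single class.

## Synthetic phantom cohort

No public cohort exists for this protocol, so the package ships a seeded
generator that emulates the targeted data regime: per subject, three 3D
scans (noncontrast, postcontrast, late) sharing one anatomy on the
anisotropic default grid. The kidney is a bean shape — an ellipsoid
(half-axes 11 × 8 × 17 mm) minus a spherical hilum notch (depth fraction
0.3) — with three interior medullary lobes. Default per-phase
(background, medulla, cortex) means:

| phase        | background | medulla | cortex |
|--------------|-----------:|--------:|-------:|
| noncontrast  |         40 |      55 |     65 |
| postcontrast |         45 |     110 |    190 |
| late         |         45 |     120 |    140 |

so noncontrast has weak kidney/background separation, postcontrast strong
cortical enhancement with cortex ≫ medulla, and late an intermediate,
partially enhanced medulla. Each scan carries a smooth multiplicative bias
field (random quadratic polynomial, amplitude 0.15), additive Gaussian
noise (sd 8), and two distractor ellipsoids at 95 % of cortex intensity
(adjacent-organ confusion). Subjects differ by a smooth random
displacement field (sd 1.5 mm on a 5³ control grid, magnitude parameter
3 mm) plus a small affine jitter scaled with the deformation magnitude.
Everything is a pure function of (spec, seeds).

These defaults define the *moderate difficulty* condition used by the
acceptance run. What the phantom does **not** emulate: beam hardening,
partial-volume effects, perfusion pharmacokinetics, organ-specific texture,
or realistic abdominal anatomy — passing tests demonstrate the pipeline's
mechanics and its robustness ordering (clean ≥ moderate ≥ hard), not
clinical-grade accuracy on real CT.

## Leave-one-subject-out protocol and problem sizes

The cohort evaluation co-registers every scan once into atlas space, then
for each subject removes **all** of its scans from the fold's database,
segments each of its three scans, and scores them against the subject
truth in native space. Summaries report mean ± SD of DC, |PVD| and BHD95
per scan, per-scan AUC, pooled AUC over all voxels of all scans, and a
per-subject aggregation. Fold hygiene is audited: the scans used by every
fold are recorded and asserted disjoint from the test subject.

The packaged acceptance run uses 6 subjects (18 scans) at 64³ with 400
trees and `n_atlas = min(19, 15) = 15` — the protocol's selection size
truncated to the candidates a fold offers. Truncation rather than a
smaller proportional subset matters here: NCC is contrast-invariant, so
for a noncontrast test scan an aggressive subset can consist entirely of
enhanced-phase scans, starving the prior and the intensity model of the
test scan's contrast regime (observed as a 45 % Dice collapse on one scan
with a 9-of-15 selection, restored to ~89 % by using all 15). The
clinical-scale grid (512 × 512 × 232–366) is supported but not the
default.

## Known limitations

* The Potts potential estimator applies the pairwise closed form uniformly
  to triple/quad families; it is consistent (centered, correctly signed)
  but not the exact higher-order MLE.
* The B-spline inverse is numerical (fixed-point displacement inversion);
  round-trip error is sub-voxel for the smooth fields produced here but
  not identically zero.
* One Gibbs sweep only; no MAP-MRF inference (graph cuts, BP) is
  attempted, by design.
* With 2-subject cohorts a fold contains one subject and the
  subject-exclusion rule for training features degrades to entry
  exclusion; expect weaker distractor rejection there (see the training
  feature discussion above).
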