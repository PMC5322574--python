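"""End-to-end segmentation and leave-one-subject-out (LOSO) evaluation.

Per test volume the pipeline runs, in order: (1) two-step registration into
the common atlas space; (2) NCC ranking and top-N atlas selection; (3) the
adaptive shape prior, the atlas intensity model, the initial shape+intensity
labeling, analytic Potts potentials, and the Gibbs spatial probabilities;
(4) 9-feature extraction for the selected training scans and the test scan,
random-forest training on the selected scans, voxel-wise prediction, and 3D
median postprocessing. Outputs are inverse-mapped to the test scan's native
grid so evaluation happens in the subject's own geometry.

In LOSO evaluation every scan of the test subject is withheld from atlas
selection, the shape prior, the intensity model, and RF training of its own
fold; the scans actually used are recorded per fold for auditing.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .core import (
    IntensityVolume,
    LabelMap,
    Phase,
    ProbabilityMap,
    SubjectRecord,
    VoxelGrid,
)
from .errors import CohortSizeError
from .features import (
    FeatureTable,
    extract_features,
    normalize_appearance,
    postprocess_median,
    predict,
    train_rf,
)
from .metrics import EvalReport, evaluate_pair
from .mgrf import estimate_intensity_model, spatial_probability
from .phantom import PhantomSubject
from .registration import (
    TransformChain,
    apply_inverse_transform,
    apply_transform,
    register_affine,
    register_bspline,
)
from .shape_prior import (
    AtlasDatabase,
    AtlasEntry,
    ShapePriorParams,
    compute_shape_prior,
    select_top,
)

logger = logging.getLogger("renalseg")


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults follow the framework's protocol."""

    n_atlas: int = 19
    n_trees: int = 400
    prior_params: ShapePriorParams = field(default_factory=ShapePriorParams)
    median_radius: int = 1
    seed: int = 0
    max_train_voxels_per_class_per_volume: Optional[int] = 2000
    use_bspline: bool = True
    knot_spacing_voxels: int = 8
    affine_iterations: int = 100
    bspline_iterations: int = 15


@dataclass
class LosoResult:
    """Per-scan reports plus cohort summaries of a LOSO run."""

    reports: dict[tuple[str, str], EvalReport]
    summary: dict[str, float]
    per_subject: dict[str, dict[str, float]]
    used_atlas: dict[tuple[str, str], list[str]]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (sid, phase), rep in self.reports.items():
            row = {"subject": sid, "phase": phase}
            row.update(rep.to_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        payload = {
            "summary": self.summary,
            "per_subject": self.per_subject,
            "per_scan": [
                {"subject": sid, "phase": phase, **rep.to_dict()}
                for (sid, phase), rep in self.reports.items()
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


# ---------------------------------------------------------------------------
# Atlas construction
# ---------------------------------------------------------------------------


@dataclass
class CoalignedCohort:
    """All cohort scans registered into one common (atlas) space."""

    atlas: AtlasDatabase
    chains: dict[tuple[str, str], TransformChain]
    aligned_volumes: dict[tuple[str, str], IntensityVolume]
    native_records: dict[tuple[str, str], SubjectRecord]


def _register_to_reference(
    reference: IntensityVolume, record: SubjectRecord, config: PipelineConfig
) -> TransformChain:
    affine = register_affine(reference, record.volume, iterations=config.affine_iterations)
    deformation = None
    if config.use_bspline:
        deformation = register_bspline(
            reference,
            record.volume,
            affine,
            knot_spacing_voxels=config.knot_spacing_voxels,
            iterations=config.bspline_iterations,
        )
    return TransformChain(affine=affine, deformation=deformation)


def coalign_cohort(
    subjects: list[PhantomSubject], config: PipelineConfig
) -> CoalignedCohort:
    """Register every scan onto the first subject's postcontrast scan.

    The reference scan anchors the common atlas space and gets an identity
    chain; every other scan is aligned with the two-step registration and
    its truth propagated with nearest-neighbor interpolation.
    """
    reference = subjects[0].records[Phase.POSTCONTRAST].volume
    entries: list[AtlasEntry] = []
    chains: dict[tuple[str, str], TransformChain] = {}
    aligned: dict[tuple[str, str], IntensityVolume] = {}
    natives: dict[tuple[str, str], SubjectRecord] = {}
    for subject in subjects:
        for phase, record in subject.records.items():
            key = (subject.subject_id, phase.value)
            t0 = time.perf_counter()
            if record.volume is reference:
                chain = TransformChain.identity()
            else:
                chain = _register_to_reference(reference, record, config)
            vol_aligned = apply_transform(record.volume, chain, mode="linear")
            lab_aligned = apply_transform(record.truth, chain, mode="nearest")
            entries.append(
                AtlasEntry(
                    subject_id=subject.subject_id,
                    phase=phase,
                    volume=vol_aligned,
                    labelmap=lab_aligned,
                )
            )
            chains[key] = chain
            aligned[key] = vol_aligned
            natives[key] = record
            logger.info("coaligned %s/%s in %.1fs", key[0], key[1], time.perf_counter() - t0)
    return CoalignedCohort(
        atlas=AtlasDatabase(entries=entries),
        chains=chains,
        aligned_volumes=aligned,
        native_records=natives,
    )


# ---------------------------------------------------------------------------
# Per-volume segmentation
# ---------------------------------------------------------------------------


def _training_features(
    entry: AtlasEntry,
    db: AtlasDatabase,
    config: PipelineConfig,
    cache: Optional[dict] = None,
) -> FeatureTable:
    """Feature table of one training scan, built exactly like a test scan's.

    The scan's prior conditions on its NCC-top-ranked peers in the fold
    database with its own subject's scans excluded — mirroring the
    leave-one-subject-out condition the test scan experiences, so the
    feature distributions of training and test voxels match. Results are
    cached per fold so the three phases of a fold share the work.
    """
    key = entry.key
    if cache is not None and key in cache:
        return cache[key]
    remaining = [e for e in db.entries if e.subject_id != entry.subject_id]
    if remaining:
        db_minus = AtlasDatabase(entries=remaining)
    else:
        # minimal cohorts: the fold holds a single subject, so only the
        # identical entry can be excluded
        db_minus = db.without_entry(entry.subject_id, entry.phase)
    n = min(config.n_atlas, len(db_minus.entries))
    selected = select_top(entry.volume, db_minus, n)
    prior = compute_shape_prior(entry.volume, selected, config.prior_params)
    intensity = estimate_intensity_model(AtlasDatabase(entries=selected))
    spatial, _, _ = spatial_probability(entry.volume, prior, intensity)
    table = normalize_appearance(extract_features(entry.volume, prior, spatial))
    if cache is not None:
        cache[key] = table
    return table


def _segment_aligned(
    test_aligned: IntensityVolume,
    chain: TransformChain,
    native_grid: VoxelGrid,
    atlas: AtlasDatabase,
    config: PipelineConfig,
    exclude_subject: Optional[str] = None,
    cache: Optional[dict] = None,
) -> tuple[LabelMap, ProbabilityMap, list[str]]:
    selected = select_top(test_aligned, atlas, config.n_atlas, exclude_subject)
    used = [f"{e.subject_id}/{e.phase.value}" for e in selected]

    prior = compute_shape_prior(test_aligned, selected, config.prior_params)
    intensity = estimate_intensity_model(AtlasDatabase(entries=selected))
    spatial, potts, _ = spatial_probability(test_aligned, prior, intensity)
    logger.info("fitted potentials: %s", potts.as_dict())
    test_table = normalize_appearance(extract_features(test_aligned, prior, spatial))

    train_db = atlas if exclude_subject is None else atlas.without_subject(exclude_subject)
    tables = [_training_features(e, train_db, config, cache) for e in selected]
    truths = [e.labelmap for e in selected]
    forest = train_rf(
        tables,
        truths,
        n_trees=config.n_trees,
        seed=config.seed,
        max_voxels_per_class_per_volume=config.max_train_voxels_per_class_per_volume,
    )
    out = predict(forest, test_table, test_aligned.grid)
    smoothed = postprocess_median(out.labels, radius=config.median_radius)

    labels_native = apply_inverse_transform(smoothed, chain, native_grid, mode="nearest")
    prob_vol = IntensityVolume(grid=out.probability.grid, values=out.probability.p_kt)
    prob_back = apply_inverse_transform(prob_vol, chain, native_grid, mode="linear")
    prob_native = ProbabilityMap(
        grid=native_grid, p_kt=np.clip(np.asarray(prob_back.values), 0.0, 1.0)
    )
    return labels_native, prob_native, used


def segment_volume(
    test: IntensityVolume,
    atlas: AtlasDatabase,
    config: PipelineConfig,
    exclude_subject: Optional[str] = None,
) -> tuple[LabelMap, ProbabilityMap]:
    """Segment one native-space volume against a co-aligned atlas database.

    The test volume is registered onto the atlas space (mean atlas image as
    the fixed target), segmented there, and the label/probability outputs
    are inverse-mapped to the test's native grid.
    """
    mean_img = IntensityVolume(
        grid=atlas.grid,
        values=np.mean([np.asarray(e.volume.values) for e in atlas.entries], axis=0),
    )
    record = SubjectRecord(subject_id="__test__", phase=Phase.POSTCONTRAST, volume=test)
    chain = _register_to_reference(mean_img, record, config)
    test_aligned = apply_transform(test, chain, mode="linear")
    labels, prob, _ = _segment_aligned(
        test_aligned, chain, test.grid, atlas, config, exclude_subject
    )
    return labels, prob


# ---------------------------------------------------------------------------
# Leave-one-subject-out evaluation
# ---------------------------------------------------------------------------


def _mean_sd(values: list[float]) -> tuple[float, float]:
    arr = np.asarray(values, dtype=float)
    return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0


def loso_evaluate(
    subjects: list[PhantomSubject],
    config: PipelineConfig,
    coaligned: Optional[CoalignedCohort] = None,
) -> LosoResult:
    """Leave-one-subject-out evaluation over a cohort with ground truth."""
    if len(subjects) < 2:
        raise CohortSizeError("LOSO needs at least 2 subjects")
    available = 3 * (len(subjects) - 1)
    if available < config.n_atlas:
        raise CohortSizeError(
            f"n_atlas={config.n_atlas} exceeds the {available} scans available per fold"
        )
    if coaligned is None:
        coaligned = coalign_cohort(subjects, config)

    reports: dict[tuple[str, str], EvalReport] = {}
    used_atlas: dict[tuple[str, str], list[str]] = {}
    pooled_y: list[np.ndarray] = []
    pooled_s: list[np.ndarray] = []

    for subject in subjects:
        fold_db = coaligned.atlas.without_subject(subject.subject_id)
        cache: dict = {}
        for phase in Phase:
            key = (subject.subject_id, phase.value)
            record = coaligned.native_records[key]
            t0 = time.perf_counter()
            labels, prob, used = _segment_aligned(
                coaligned.aligned_volumes[key],
                coaligned.chains[key],
                record.volume.grid,
                fold_db,
                config,
                exclude_subject=subject.subject_id,
                cache=cache,
            )
            assert all(not u.startswith(f"{subject.subject_id}/") for u in used)
            reports[key] = evaluate_pair(record.truth, labels, prob)
            used_atlas[key] = used
            pooled_y.append(record.truth.kt_mask.ravel())
            pooled_s.append(prob.p_kt.ravel().astype(np.float32))
            logger.info(
                "fold %s/%s: DC=%.2f%% |PVD|=%.2f%% BHD95=%.2fmm AUC=%.4f (%.1fs)",
                key[0],
                key[1],
                reports[key].dc,
                reports[key].abs_pvd,
                reports[key].bhd95,
                reports[key].auc,
                time.perf_counter() - t0,
            )

    # pooled ROC over every voxel of every scan
    from sklearn.metrics import roc_curve as _roc_curve

    y_all = np.concatenate(pooled_y)
    s_all = np.concatenate(pooled_s)
    fpr, tpr, _ = _roc_curve(y_all, s_all, drop_intermediate=True)
    pooled_auc = float(np.trapezoid(tpr, fpr))

    dcs = [r.dc for r in reports.values()]
    apvds = [r.abs_pvd for r in reports.values()]
    bhds = [r.bhd95 for r in reports.values()]
    aucs = [r.auc for r in reports.values()]
    summary = {}
    for name, vals in (("dc", dcs), ("abs_pvd", apvds), ("bhd95_mm", bhds), ("auc", aucs)):
        mean, sd = _mean_sd(vals)
        summary[f"mean_{name}"] = mean
        summary[f"sd_{name}"] = sd
    summary["pooled_auc"] = pooled_auc
    summary["n_scans"] = len(reports)

    per_subject: dict[str, dict[str, float]] = {}
    for subject in subjects:
        subset = [r for (sid, _), r in reports.items() if sid == subject.subject_id]
        per_subject[subject.subject_id] = {
            "mean_dc": float(np.mean([r.dc for r in subset])),
            "mean_abs_pvd": float(np.mean([r.abs_pvd for r in subset])),
            "mean_bhd95_mm": float(np.mean([r.bhd95 for r in subset])),
            "mean_auc": float(np.mean([r.auc for r in subset])),
        }

    return LosoResult(
        reports=reports, summary=summary, per_subject=per_subject, used_atlas=used_atlas
    )
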