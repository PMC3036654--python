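"""End-to-end orchestration: superimpose, evaluate, reproduce the study design.

A "superimposition" chains the stages of the semi-automated workflow:
bone-threshold model construction, registration-zone ROI selection, rough
landmark alignment, and MI-driven rigid registration.  An "evaluation"
extracts the bone iso-surfaces of both models, applies the estimated
transform to the follow-up model, computes exact closest-point distances,
and summarizes them over the four anatomic evaluation regions.

``run_study`` repeats this design over a synthetic cohort: per case, several
superimpositions per registration zone with independently perturbed rough
alignments (emulating the operator redoing the manual steps), producing the
per-case regional distances that feed the reproducibility tables.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import phantom as ph
from .registration import (
    RegistrationConfig,
    RegistrationDiagnostics,
    RigidTransform,
    register,
    rough_align,
    zone_roi,
)
from .segmentation import SegmentationConfig
from .surface_distance import (
    DistanceSummary,
    SurfaceMesh,
    extract_surface,
    label_regions,
)
from .volume_io import BinaryMask, Volume


@dataclass
class SuperimpositionResult:
    transform: RigidTransform
    diagnostics: RegistrationDiagnostics
    rough_transform: RigidTransform
    rough_rms_mm: float


def run_superimposition(
    fixed: Volume,
    moving: Volume,
    roi: BinaryMask,
    fixed_landmarks: np.ndarray | None = None,
    moving_landmarks: np.ndarray | None = None,
    init: RigidTransform | None = None,
    config: RegistrationConfig | None = None,
) -> SuperimpositionResult:
    """Rough alignment (landmarks or explicit init) followed by MI registration."""
    if init is None:
        if fixed_landmarks is None or moving_landmarks is None:
            raise ValueError("provide either an initial transform or paired landmarks")
        init, rms = rough_align(fixed_landmarks, moving_landmarks)
    else:
        rms = float("nan")
    transform, diag = register(fixed, moving, roi, init, config)
    return SuperimpositionResult(transform, diag, init, rms)


def extract_model_meshes(
    fixed: Volume,
    moving: Volume,
    seg_config: SegmentationConfig | None = None,
    smooth_sigma_voxels: float = 0.8,
) -> tuple[SurfaceMesh, SurfaceMesh]:
    """Bone iso-surfaces of both volumes at the segmentation threshold.

    Before extraction both volumes are regularized with a small Gaussian
    (``smooth_sigma_voxels``, in voxels; 0 disables), the standard pre-meshing
    step that suppresses scan noise and voxelization artifacts in the
    iso-surface position.  The moving mesh is returned in the moving frame.
    """
    seg_config = seg_config or SegmentationConfig()
    level = seg_config.lower_hu

    def prep(vol: Volume) -> Volume:
        if smooth_sigma_voxels <= 0:
            return vol
        from scipy import ndimage

        return Volume(
            ndimage.gaussian_filter(np.asarray(vol.data, dtype=np.float32), smooth_sigma_voxels),
            vol.spacing, vol.origin, vol.axes,
        )

    return extract_surface(prep(fixed), iso_level=level), extract_surface(prep(moving), iso_level=level)


def evaluate_transform(
    baseline: SurfaceMesh,
    moving_mesh: SurfaceMesh,
    transform: RigidTransform,
    region_masks: dict[str, BinaryMask],
    max_vertices_per_region: int | None = 20000,
    seed: int = 0,
    baseline_index=None,
) -> tuple[DistanceSummary, SurfaceMesh]:
    """Regional distances of the transformed follow-up mesh to the baseline.

    The follow-up mesh is mapped through the estimated transform, labeled by
    the region masks (fixed frame), and queried against the baseline mesh —
    distances live on the follow-up mesh.  Vertices outside every region are
    not queried; regions larger than ``max_vertices_per_region`` are
    subsampled deterministically.  ``baseline_index`` may carry a prebuilt
    triangle index for the baseline mesh (reused across repeats).
    """
    from .surface_distance import _TriangleIndex, summarize_regions

    followup = moving_mesh.transformed(transform)
    followup = label_regions(followup, region_masks)

    keep = followup.region_labels != ""
    if max_vertices_per_region is not None:
        rng = np.random.default_rng(seed)
        for name in set(followup.region_labels[keep]):
            sel = np.flatnonzero(followup.region_labels == name)
            if len(sel) > max_vertices_per_region:
                drop = rng.choice(sel, size=len(sel) - max_vertices_per_region, replace=False)
                keep[drop] = False

    index = baseline_index or _TriangleIndex(baseline)
    dist, closest, tri_id = index.query(followup.vertices[keep])
    normals = baseline.face_normals()[tri_id]
    sign = np.sign(np.einsum("ij,ij->i", followup.vertices[keep] - closest, normals))
    sign[sign == 0] = 1.0

    followup.absolute_distance_mm = np.full(followup.n_vertices, np.nan)
    followup.signed_distance_mm = np.full(followup.n_vertices, np.nan)
    followup.absolute_distance_mm[keep] = dist
    followup.signed_distance_mm[keep] = sign * dist

    sub = SurfaceMesh(
        followup.vertices[keep], np.empty((0, 3), dtype=np.int64),
        region_labels=followup.region_labels[keep],
    )
    sub.absolute_distance_mm = dist
    sub.signed_distance_mm = sign * dist
    return summarize_regions(sub), followup


def evaluate_superimposition(
    fixed: Volume,
    moving: Volume,
    transform: RigidTransform,
    region_masks: dict[str, BinaryMask],
    seg_config: SegmentationConfig | None = None,
    max_vertices_per_region: int | None = 20000,
    smooth_sigma_voxels: float = 0.8,
    seed: int = 0,
) -> tuple[DistanceSummary, SurfaceMesh]:
    """Regional surface distances between the superimposed pair (one-shot).

    Convenience wrapper over :func:`extract_model_meshes` and
    :func:`evaluate_transform`.
    """
    baseline, moving_mesh = extract_model_meshes(fixed, moving, seg_config, smooth_sigma_voxels)
    return evaluate_transform(
        baseline, moving_mesh, transform, region_masks,
        max_vertices_per_region=max_vertices_per_region, seed=seed,
    )


# ---------------------------------------------------------------------------
# Study design
# ---------------------------------------------------------------------------


@dataclass
class StudyConfig:
    """The repeated-superimposition study on a synthetic cohort.

    Per case, ``cb_repeats`` superimpositions registered on the anterior
    cranial base and ``zl_repeats`` on the left zygomatic arch, each with an
    independently perturbed rough-alignment initialization (the repeat-to-
    repeat variation of redoing the manual steps).  The master seed fully
    determines the run.
    """

    n_cases: int = 16
    cb_repeats: int = 3
    zl_repeats: int = 2
    phantom: ph.PhantomSpec = field(default_factory=ph.PhantomSpec)
    registration: RegistrationConfig = field(default_factory=RegistrationConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    max_translation_mm: float = 10.0
    max_rotation_deg: float = 10.0
    noise_sd: float = 50.0
    landmark_noise_mm: float = 1.0
    init_perturb_translation_mm: float = 1.0
    init_perturb_rotation_deg: float = 1.0
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.cb_repeats < 1 or self.zl_repeats < 0:
            raise ValueError("repeats must be >= 1 for CB and >= 0 for ZL")
        if self.n_cases < 1:
            raise ValueError("n_cases must be >= 1")


@dataclass
class StudyRunRecord:
    case: int
    repeat: str
    zone: str
    recovery: ph.RecoveryReport
    summary: DistanceSummary
    diagnostics: RegistrationDiagnostics


def _perturbed_init(
    base: RigidTransform,
    rng: np.random.Generator,
    sigma_t: float,
    sigma_r: float,
) -> RigidTransform:
    wobble = RigidTransform.from_euler(
        rng.normal(0.0, sigma_r, 3), rng.normal(0.0, sigma_t, 3), base.center
    )
    return wobble.compose(base)


def run_study(config: StudyConfig, progress=None) -> tuple[pd.DataFrame, list[StudyRunRecord]]:
    """Run the full synthetic study; returns the per-case distance frame.

    The distance frame has one row per case × repeat × region (columns case,
    repeat, zone, region, mean, sd, se, n) plus ground-truth recovery columns,
    and feeds :func:`voxelreg.stats.build_study_table` directly.
    """
    rng = np.random.default_rng(config.master_seed)
    case_seeds = rng.integers(0, 2**31 - 1, size=config.n_cases)
    rows = []
    records: list[StudyRunRecord] = []

    plan = [("S%d" % (i + 1), "anterior-cranial-base") for i in range(config.cb_repeats)]
    plan += [
        ("S%d" % (config.cb_repeats + i + 1), "left-zygomatic-arch")
        for i in range(config.zl_repeats)
    ]

    for case in range(config.n_cases):
        spec = ph.random_case_spec(
            int(case_seeds[case]),
            base=config.phantom,
            max_translation_mm=config.max_translation_mm,
            max_rotation_deg=config.max_rotation_deg,
            noise_sd=config.noise_sd,
        )
        fixed, moving, truth = ph.generate_phantom_pair(spec)
        landmarks = ph.default_landmarks(spec)
        probes = ph.structure_centroids(truth)
        case_rng = np.random.default_rng(int(case_seeds[case]) + 1)
        baseline_mesh = moving_mesh = baseline_index = None  # built lazily, shared by repeats

        for repeat, zone in plan:
            try:
                roi = zone_roi(truth.structure_masks, zone)
                moving_lm = truth.true_transform.inverse().apply(landmarks)
                moving_lm = moving_lm + case_rng.normal(0.0, config.landmark_noise_mm, moving_lm.shape)
                init, _ = rough_align(landmarks, moving_lm)
                init = _perturbed_init(
                    init, case_rng,
                    config.init_perturb_translation_mm, config.init_perturb_rotation_deg,
                )
                reg_cfg = replace(config.registration, seed=int(case_rng.integers(0, 2**31 - 1)))
                transform, diag = register(fixed, moving, roi, init, reg_cfg)
                recovery = ph.evaluate_recovery(truth, transform, probes)
                if baseline_mesh is None:
                    baseline_mesh, moving_mesh = extract_model_meshes(
                        fixed, moving, config.segmentation
                    )
                    from .surface_distance import _TriangleIndex

                    baseline_index = _TriangleIndex(baseline_mesh)
                summary, _mesh = evaluate_transform(
                    baseline_mesh, moving_mesh, transform, truth.evaluation_masks(),
                    seed=int(case_seeds[case]), baseline_index=baseline_index,
                )
            except Exception as exc:  # a failed stage aborts the case run, not the study
                rows.append(
                    {"case": case, "repeat": repeat, "zone": zone, "region": None,
                     "mean": np.nan, "sd": np.nan, "se": np.nan, "n": 0,
                     "error": f"{type(exc).__name__}: {exc}"}
                )
                continue
            records.append(StudyRunRecord(case, repeat, zone, recovery, summary, diag))
            for _, r in summary.per_region.iterrows():
                rows.append(
                    {"case": case, "repeat": repeat, "zone": zone, "region": r.region,
                     "mean": r["mean"], "sd": r.sd, "se": r.se, "n": int(r.n),
                     "tre_mm": recovery.tre_mm,
                     "translation_error_mm": recovery.translation_error_mm,
                     "rotation_error_deg": recovery.rotation_error_deg,
                     "error": ""}
                )
            if progress is not None:
                progress(case, repeat, zone)
    return pd.DataFrame(rows), records


# ---------------------------------------------------------------------------
# JSON config files (shared by the CLI and scripts)
# ---------------------------------------------------------------------------


def _dataclass_from_dict(cls, payload: dict):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in payload:
            continue
        value = payload[f.name]
        if dataclasses.is_dataclass(f.type) if isinstance(f.type, type) else False:
            value = _dataclass_from_dict(f.type, value)
        kwargs[f.name] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


def load_study_config(path) -> StudyConfig:
    """Read a StudyConfig from a JSON file with nested section objects."""
    payload = json.loads(Path(path).read_text())
    for key, cls in (
        ("phantom", ph.PhantomSpec),
        ("registration", RegistrationConfig),
        ("segmentation", SegmentationConfig),
    ):
        if key in payload and isinstance(payload[key], dict):
            payload[key] = _dataclass_from_dict(cls, payload[key])
    return _dataclass_from_dict(StudyConfig, payload)


def load_phantom_spec(path) -> ph.PhantomSpec:
    return _dataclass_from_dict(ph.PhantomSpec, json.loads(Path(path).read_text()))
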