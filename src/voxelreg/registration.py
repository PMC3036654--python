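"""ROI-restricted rigid registration by mutual-information maximization.

The similarity metric is Shannon mutual information of the joint grey-value
histogram of the two volumes, sampled voxel by voxel inside a registration
region of interest (ROI).  The moving volume is interpolated trilinearly, the
joint histogram uses hard binning on a clamped HU range, and the transform is
optimized coarse-to-fine over an image pyramid with a derivative-free
direction-set (Powell) search.  Rough alignment from paired landmarks
(orthogonal Procrustes) provides the initialization, mirroring the manual
pre-alignment step of semi-automated superimposition workflows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage, optimize
from scipy.spatial.transform import Rotation

from .volume_io import BinaryMask, Volume, voxel_to_world, world_to_voxel


class RegistrationError(RuntimeError):
    """Raised for hopeless inputs (empty ROI, no overlap, degenerate landmarks)."""


# ---------------------------------------------------------------------------
# Rigid transforms
# ---------------------------------------------------------------------------


@dataclass
class RigidTransform:
    """Rotation + translation about a stated center of rotation.

    Maps moving-volume world coordinates onto fixed-volume world coordinates:

        y = R @ (x - center) + center + translation

    Angles, where exposed, are Z-Y-X intrinsic Euler angles in degrees.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        self.center = np.asarray(self.center, dtype=float).reshape(3)
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation matrix must be orthonormal")
        if np.linalg.det(self.rotation) < 0:
            raise ValueError("rotation matrix must have determinant +1 (no reflections)")

    # -- constructors -------------------------------------------------------

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls()

    @classmethod
    def from_euler(
        cls,
        angles_zyx_deg: np.ndarray,
        translation_mm: np.ndarray = (0.0, 0.0, 0.0),
        center_mm: np.ndarray = (0.0, 0.0, 0.0),
    ) -> "RigidTransform":
        rot = Rotation.from_euler("ZYX", np.asarray(angles_zyx_deg, dtype=float), degrees=True)
        return cls(rot.as_matrix(), np.asarray(translation_mm, dtype=float), np.asarray(center_mm, dtype=float))

    # -- views --------------------------------------------------------------

    @property
    def euler_zyx_deg(self) -> np.ndarray:
        return Rotation.from_matrix(self.rotation).as_euler("ZYX", degrees=True)

    @property
    def offset(self) -> np.ndarray:
        """Translation of the equivalent center-free map y = R x + offset."""
        return self.center + self.translation - self.rotation @ self.center

    def rotation_angle_deg(self) -> float:
        """Magnitude of the rotation (angle-axis angle)."""
        return float(np.degrees(Rotation.from_matrix(self.rotation).magnitude()))

    def with_center(self, center_mm: np.ndarray) -> "RigidTransform":
        """Re-express the same map about a different rotation center."""
        c = np.asarray(center_mm, dtype=float).reshape(3)
        t = self.offset + self.rotation @ c - c
        return RigidTransform(self.rotation.copy(), t, c)

    # -- group operations ---------------------------------------------------

    def apply(self, points_mm: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        out = (self.rotation @ (pts - self.center).T).T + self.center + self.translation
        return out[0] if np.asarray(points_mm).ndim == 1 else out

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return self ∘ other (apply ``other`` first), centered at self.center."""
        rot = self.rotation @ other.rotation
        offset = self.rotation @ other.offset + self.offset
        t = offset + rot @ self.center - self.center
        return RigidTransform(rot, t, self.center.copy())

    def inverse(self) -> "RigidTransform":
        rot = self.rotation.T
        offset = -rot @ self.offset
        t = offset + rot @ self.center - self.center
        return RigidTransform(rot, t, self.center.copy())

    # -- plain-text persistence --------------------------------------------

    def save(self, path) -> None:
        a = self.euler_zyx_deg
        lines = [
            "# rigid transform: y = R(zyx angles)·(x − center) + center + translation",
            f"angles_zyx_deg: {a[0]:.12g} {a[1]:.12g} {a[2]:.12g}",
            f"translation_mm: {self.translation[0]:.12g} {self.translation[1]:.12g} {self.translation[2]:.12g}",
            f"center_mm: {self.center[0]:.12g} {self.center[1]:.12g} {self.center[2]:.12g}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path) -> "RigidTransform":
        fields = {}
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, rest = line.partition(":")
            fields[key.strip()] = np.array([float(v) for v in rest.split()])
        try:
            return cls.from_euler(fields["angles_zyx_deg"], fields["translation_mm"], fields["center_mm"])
        except KeyError as exc:
            raise RegistrationError(f"transform file {path} is missing field {exc}") from exc


def load_landmarks(path) -> np.ndarray:
    """Read an N×3 landmark file: whitespace-separated x y z per line, mm."""
    pts = np.loadtxt(path, comments="#", ndmin=2)
    if pts.shape[1] != 3:
        raise RegistrationError(f"landmark file {path} must have 3 columns, got {pts.shape[1]}")
    return pts


# ---------------------------------------------------------------------------
# Rough alignment (orthogonal Procrustes on paired landmarks)
# ---------------------------------------------------------------------------


def rough_align(fixed_landmarks: np.ndarray, moving_landmarks: np.ndarray) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit mapping moving landmarks onto fixed landmarks.

    Kabsch/orthogonal-Procrustes solution with reflections excluded.  Returns
    the transform and the RMS residual (mm).  Requires >= 3 non-collinear pairs.
    """
    f = np.asarray(fixed_landmarks, dtype=float)
    m = np.asarray(moving_landmarks, dtype=float)
    if f.shape != m.shape or f.ndim != 2 or f.shape[1] != 3:
        raise RegistrationError("landmark sets must be matching N×3 arrays")
    if f.shape[0] < 3:
        raise RegistrationError("at least 3 landmark pairs are required")
    cf, cm = f.mean(axis=0), m.mean(axis=0)
    h = (m - cm).T @ (f - cf)
    u, s, vt = np.linalg.svd(h)
    if s[1] < 1e-9 * max(s[0], 1e-300):
        raise RegistrationError("landmarks are collinear or degenerate; rotation is not determined")
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    transform = RigidTransform(rot, cf - cm, cm)
    resid = transform.apply(m) - f
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return transform, rms


# ---------------------------------------------------------------------------
# Resampling
# ---------------------------------------------------------------------------


def resample_trilinear(
    moving: Volume,
    transform: RigidTransform,
    target: Volume | BinaryMask,
    fill_value: float = -1000.0,
) -> tuple[Volume, BinaryMask]:
    """Resample ``moving`` onto the grid of ``target`` under ``transform``.

    Each target voxel center p is sampled from the moving volume at
    transform⁻¹(p) by trilinear interpolation.  Out-of-grid samples receive
    ``fill_value`` and are flagged False in the returned validity mask.
    """
    shape = target.data.shape
    ii, jj, kk = np.meshgrid(*(np.arange(n, dtype=float) for n in shape), indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    world = voxel_to_world(target, idx)
    src_idx = world_to_voxel(moving, transform.inverse().apply(world))
    hi = np.asarray(moving.data.shape) - 1
    valid = np.all((src_idx >= 0) & (src_idx <= hi), axis=1)
    values = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float), src_idx.T, order=1, mode="nearest"
    )
    values[~valid] = fill_value
    out = Volume(values.reshape(shape), target.spacing, target.origin, target.axes)
    return out, BinaryMask(valid.reshape(shape), target.spacing, target.origin, target.axes)


# ---------------------------------------------------------------------------
# Joint histogram and mutual information
# ---------------------------------------------------------------------------


@dataclass
class RegistrationConfig:
    """Settings for MI-based rigid registration."""

    bins: int = 64
    clamp_hu: tuple[float, float] = (-1000.0, 2000.0)
    pyramid_levels: int = 3
    downsample_factor: int = 2
    mi_tolerance: float = 1e-5
    max_iterations: int = 200
    max_samples: int = 40000
    min_level_samples: int = 500  # skip coarse pyramid levels with fewer ROI voxels
    step_deg: float = 1.0
    step_mm: float = 1.0
    xtol: float = 1e-3
    polish: bool = True  # restart Powell at the finest level with 0.1x steps
    jitter_sampling: bool = True  # sample at random intra-voxel offsets (see below)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.pyramid_levels < 1:
            raise ValueError("pyramid_levels must be >= 1")
        if self.mi_tolerance <= 0:
            raise ValueError("mi_tolerance must be > 0")
        if self.clamp_hu[1] <= self.clamp_hu[0]:
            raise ValueError("clamp range must be increasing")


@dataclass
class JointHistogram:
    """2D grey-value count matrix of fixed vs transformed moving intensities."""

    counts: np.ndarray
    fixed_edges: np.ndarray
    moving_edges: np.ndarray

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def _bin_indices(values: np.ndarray, lo: float, hi: float, bins: int) -> np.ndarray:
    clipped = np.clip(values, lo, hi)
    idx = ((clipped - lo) / (hi - lo) * bins).astype(np.intp)
    return np.minimum(idx, bins - 1)


def _histogram_from_samples(
    fixed_values: np.ndarray, moving_values: np.ndarray, config: RegistrationConfig
) -> JointHistogram:
    lo, hi = config.clamp_hu
    b = config.bins
    fi = _bin_indices(fixed_values, lo, hi, b)
    mi_ = _bin_indices(moving_values, lo, hi, b)
    counts = np.bincount(fi * b + mi_, minlength=b * b).reshape(b, b)
    edges = np.linspace(lo, hi, b + 1)
    return JointHistogram(counts, edges, edges.copy())


def joint_histogram(
    fixed: Volume,
    moving: Volume,
    transform: RigidTransform,
    roi: BinaryMask,
    config: RegistrationConfig | None = None,
) -> JointHistogram:
    """Joint grey-value histogram over ROI voxels with valid moving samples.

    Samples are the fixed-grid voxel centers inside ``roi`` whose
    transform-mapped position lands inside the moving grid; both intensities
    are clamped to ``config.clamp_hu`` and binned on uniform edges.
    """
    config = config or RegistrationConfig()
    idx = np.argwhere(roi.data)
    if idx.shape[0] == 0:
        raise RegistrationError("registration ROI is empty")
    world = voxel_to_world(roi, idx.astype(float))
    fixed_values = fixed.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
    src = world_to_voxel(moving, transform.inverse().apply(world))
    hi_idx = np.asarray(moving.data.shape) - 1
    inside = np.all((src >= 0) & (src <= hi_idx), axis=1)
    if not inside.any():
        raise RegistrationError("no overlap between ROI and the moving volume under this transform")
    moving_values = ndimage.map_coordinates(
        np.asarray(moving.data, dtype=float), src[inside].T, order=1
    )
    return _histogram_from_samples(fixed_values[inside], moving_values, config)


def mutual_information(h: JointHistogram) -> float:
    """Shannon mutual information of a joint histogram, in bits.

    MI = Σ p(a,b) log2[p(a,b) / (p(a) p(b))] with 0·log 0 := 0; always >= 0.
    """
    total = h.counts.sum()
    if total <= 0:
        raise RegistrationError("empty joint histogram")
    p = h.counts.astype(float) / total
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    denom = np.outer(pa, pb)
    return float(np.sum(p[nz] * np.log2(p[nz] / denom[nz])))


# ---------------------------------------------------------------------------
# Registration driver
# ---------------------------------------------------------------------------


@dataclass
class RegistrationDiagnostics:
    mi_trace: list[np.ndarray]
    sample_counts: list[int]
    initial_mi: float
    final_mi: float
    converged: bool
    message: str = ""


def _block_reduce_mean(data: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by local block averaging (edge-padded to a multiple of factor)."""
    if factor == 1:
        return data
    pad = [(0, (-s) % factor) for s in data.shape]
    padded = np.pad(data, pad, mode="edge")
    sx, sy, sz = (s // factor for s in padded.shape)
    return (
        padded.reshape(sx, factor, sy, factor, sz, factor)
        .mean(axis=(1, 3, 5))
    )


def _downsample_volume(volume: Volume, factor: int) -> Volume:
    if factor == 1:
        return volume
    data = _block_reduce_mean(np.asarray(volume.data, dtype=float), factor)
    spacing = volume.spacing * factor
    # Block centers sit (factor-1)/2 voxels beyond the original first center.
    shift = volume.axes @ (volume.spacing * (factor - 1) / 2.0)
    return Volume(data, spacing, volume.origin + shift, volume.axes)


def _downsample_mask(mask: BinaryMask, factor: int) -> BinaryMask:
    if factor == 1:
        return mask
    pad = [(0, (-s) % factor) for s in mask.data.shape]
    padded = np.pad(mask.data, pad, mode="constant")
    sx, sy, sz = (s // factor for s in padded.shape)
    data = padded.reshape(sx, factor, sy, factor, sz, factor).any(axis=(1, 3, 5))
    spacing = mask.spacing * factor
    shift = mask.axes @ (mask.spacing * (factor - 1) / 2.0)
    return BinaryMask(data, spacing, mask.origin + shift, mask.axes)


def roi_centroid(roi: BinaryMask) -> np.ndarray:
    idx = np.argwhere(roi.data)
    if idx.shape[0] == 0:
        raise RegistrationError("registration ROI is empty")
    return voxel_to_world(roi, idx.mean(axis=0))


class _MISampler:
    """Cached fixed-side samples for fast MI evaluation at one pyramid level.

    Sample positions are ROI voxel centers, optionally jittered by a seeded
    uniform intra-voxel offset with the fixed intensity interpolated
    trilinearly.  Jittering matters on near-noise-free data with few distinct
    grey values: at voxel centers the moving-bin partition can refine the
    fixed-bin partition over a finite neighborhood of transforms, which makes
    MI exactly constant there (H(A|B) = 0); continuous off-lattice fixed
    values break that degeneracy and restore a sharp optimum.
    """

    def __init__(
        self,
        fixed: Volume,
        moving: Volume,
        roi: BinaryMask,
        config: RegistrationConfig,
        rng: np.random.Generator,
    ) -> None:
        idx = np.argwhere(roi.data)
        if idx.shape[0] == 0:
            raise RegistrationError("registration ROI is empty at this pyramid level")
        if idx.shape[0] > config.max_samples:
            sel = rng.choice(idx.shape[0], size=config.max_samples, replace=False)
            idx = idx[np.sort(sel)]
        self.n_samples = idx.shape[0]
        pos = idx.astype(float)
        if config.jitter_sampling:
            pos = pos + rng.uniform(-0.5, 0.5, size=pos.shape)
            hi_f = np.asarray(fixed.data.shape, dtype=float) - 1.0
            pos = np.clip(pos, 0.0, hi_f)
            self.fixed_values = ndimage.map_coordinates(
                np.asarray(fixed.data, dtype=float), pos.T, order=1
            )
        else:
            self.fixed_values = fixed.data[idx[:, 0], idx[:, 1], idx[:, 2]].astype(float)
        self.world = voxel_to_world(roi, pos)
        self.moving_data = np.asarray(moving.data, dtype=float)
        self.inv_spacing = 1.0 / moving.spacing
        self.moving_origin = moving.origin
        self.moving_axes_t = moving.axes.T
        self.hi = np.asarray(moving.data.shape, dtype=float) - 1.0
        self.config = config

    def mi(self, transform: RigidTransform) -> float:
        src_world = transform.inverse().apply(self.world)
        src = ((self.moving_axes_t @ (src_world - self.moving_origin).T).T) * self.inv_spacing
        inside = np.all((src >= 0) & (src <= self.hi), axis=1)
        if inside.sum() < max(16, 0.01 * self.n_samples):
            return 0.0  # essentially no overlap: worst possible similarity
        vals = ndimage.map_coordinates(self.moving_data, src[inside].T, order=1)
        h = _histogram_from_samples(self.fixed_values[inside], vals, self.config)
        return mutual_information(h)


def register(
    fixed: Volume,
    moving: Volume,
    roi: BinaryMask,
    init: RigidTransform | None = None,
    config: RegistrationConfig | None = None,
) -> tuple[RigidTransform, RegistrationDiagnostics]:
    """Find the rigid transform maximizing MI over the ROI, coarse to fine.

    Parameters are three intrinsic Z-Y-X Euler angles (deg) and a translation
    (mm) about the ROI centroid.  Each pyramid level runs a Powell
    direction-set search on the negated MI; the finest-level result is
    guaranteed not to score below the initialization.
    """
    config = config or RegistrationConfig()
    if config.bins < 8:
        raise RegistrationError("registration needs at least 8 histogram bins")
    init = init or RigidTransform.identity()
    center = roi_centroid(roi)
    rng = np.random.default_rng(config.seed)

    current = init.with_center(center)
    traces: list[np.ndarray] = []
    sample_counts: list[int] = []
    converged = True
    message = ""
    finest_sampler: _MISampler | None = None

    for level in range(config.pyramid_levels - 1, -1, -1):
        factor = config.downsample_factor**level
        roi_l = _downsample_mask(roi, factor)
        if level > 0 and int(roi_l.data.sum()) < config.min_level_samples:
            continue  # too few ROI voxels at this scale for a reliable histogram
        f_l = _downsample_volume(fixed, factor)
        m_l = _downsample_volume(moving, factor)
        sampler = _MISampler(f_l, m_l, roi_l, config, rng)
        if level == 0:
            finest_sampler = sampler
        sample_counts.append(sampler.n_samples)

        scale = np.array([config.step_deg] * 3 + [config.step_mm] * 3)
        x0 = np.concatenate([current.euler_zyx_deg, current.translation]) / scale

        def neg_mi(x: np.ndarray) -> float:
            t = RigidTransform.from_euler(x[:3] * scale[:3], x[3:] * scale[3:], center)
            return -sampler.mi(t)

        trace: list[float] = []

        def cb(xk: np.ndarray) -> None:
            trace.append(-neg_mi(xk))

        passes = [(x0, np.eye(6))]
        if config.polish and level == 0:
            passes.append((None, 0.1 * np.eye(6)))  # restart with fresh, finer directions
        x = x0
        for start, direc in passes:
            res = optimize.minimize(
                neg_mi,
                x if start is None else start,
                method="Powell",
                callback=cb,
                options={
                    "xtol": config.xtol,
                    "ftol": config.mi_tolerance,
                    "maxiter": config.max_iterations,
                    "direc": direc,
                    "disp": False,
                },
            )
            if not res.success and res.status != 1:  # status 1 = maxiter reached
                converged = False
                message = str(res.message)
            if res.status == 1:
                converged = False
                message = f"level {level}: maximum iterations reached; best-so-far returned"
            x = res.x
        current = RigidTransform.from_euler(x[:3] * scale[:3], x[3:] * scale[3:], center)
        traces.append(np.asarray(trace))

    assert finest_sampler is not None
    initial_mi = finest_sampler.mi(init.with_center(center))
    final_mi = finest_sampler.mi(current)
    if final_mi < initial_mi:  # never return a transform that scores below the start
        current = init.with_center(center)
        final_mi = initial_mi
        converged = False
        message = "optimizer failed to improve on the initialization; returned the start"

    diag = RegistrationDiagnostics(
        mi_trace=traces,
        sample_counts=sample_counts,
        initial_mi=initial_mi,
        final_mi=final_mi,
        converged=converged,
        message=message,
    )
    return current, diag


# ---------------------------------------------------------------------------
# Registration zones
# ---------------------------------------------------------------------------

ZONES = ("anterior-cranial-base", "left-zygomatic-arch")
_ZONE_TO_STRUCTURE = {"anterior-cranial-base": "CB", "left-zygomatic-arch": "ZL"}


def zone_roi(
    structure_masks: dict[str, BinaryMask],
    zone: str,
    margin_voxels: int = 2,
) -> BinaryMask:
    """Build the registration-zone ROI from a structure mask.

    The stored structure mask (anterior cranial base, or left zygomatic arch =
    zygomatic bone + zygomatic process of the temporal bone) is dilated by
    ``margin_voxels`` (26-connectivity) so the ROI includes adjacent
    grey-value context on both sides of the bone surface.
    """
    if zone not in _ZONE_TO_STRUCTURE:
        raise RegistrationError(f"unknown registration zone {zone!r}; expected one of {ZONES}")
    key = _ZONE_TO_STRUCTURE[zone]
    if key not in structure_masks:
        raise RegistrationError(f"structure mask {key!r} is not available")
    mask = structure_masks[key]
    if not mask.data.any():
        raise RegistrationError(f"structure mask {key!r} is empty")
    if margin_voxels == 0:
        data = mask.data.copy()
    else:
        data = ndimage.binary_dilation(
            mask.data, structure=np.ones((3, 3, 3), bool), iterations=margin_voxels
        )
    return BinaryMask(data, mask.spacing, mask.origin, mask.axes)
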