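"""Synthetic skull phantom: paired "pre/post" volumes with known ground truth.

The phantom emulates the anatomy relevant to voxel-based superimposition of
serial CBCT scans: a cranial vault shell (whose basal belt stands in for the
anterior cranial base and whose anterior patch for the forehead), two
zygomatic-arch tori, and a jaw block that moves between timepoints (the
treatment change), all embedded in a soft-tissue ellipsoid surrounded by air.
Intensities are on the HU scale (air -1000, soft tissue ~40, bone 1200).

Both volumes of a pair are rendered analytically: the fixed volume samples
the scene at rest, the moving volume samples the jaw-shifted scene at the
world point mapped by the known rigid transform, so the transform relating
the two grids is exact by construction and registration accuracy becomes a
ground-truth parameter-recovery experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .registration import RigidTransform
from .volume_io import BinaryMask, Volume, voxel_to_world

STRUCTURES = ("CB", "FH", "ZL", "ZR")


class PhantomError(ValueError):
    """Raised when a phantom specification cannot be rendered."""


@dataclass
class PhantomSpec:
    """Geometry, intensities and acquisition settings of a phantom pair.

    All geometric parameters are in mm in the fixed volume's world frame
    (origin at the grid corner).  The default grid, 220×220×160 voxels at
    0.4 mm, is a scaled-down skull that keeps registration fast; the
    ``fullsize`` preset reproduces a 22×16 cm field of view.
    """

    shape: tuple[int, int, int] = (220, 220, 160)
    spacing: float = 0.4
    hu_bone: float = 1200.0
    hu_soft: float = 40.0
    hu_air: float = -1000.0
    noise_sd: float = 0.0
    supersample: int = 2
    seed: int = 0

    # structures (mm, world frame of the fixed volume)
    head_center: tuple[float, float, float] = (44.0, 44.0, 34.0)
    head_radii: tuple[float, float, float] = (38.0, 40.0, 27.0)
    vault_center: tuple[float, float, float] = (44.0, 44.0, 38.0)
    vault_outer_radii: tuple[float, float, float] = (28.0, 34.0, 20.0)
    vault_thickness: float = 2.0
    cb_band_z: tuple[float, float] = (-10.0, -2.0)  # relative to vault center
    fh_band_z: tuple[float, float] = (-2.0, 14.0)
    fh_y_fraction: float = 0.55  # anterior patch: y < c_y - frac * outer_radius_y
    # cranial-base ridges (crista-galli-like cylinders): break the rotational
    # symmetry of the basal belt the way real skull-base anatomy does
    ridge_radius: float = 2.2
    ridge_sag_y: tuple[float, float] = (18.0, 52.0)
    ridge_trans_x: tuple[float, float] = (30.0, 58.0)
    ridge_z_center: float = 30.5
    arch_major_radius: float = 8.0
    arch_tube_radius: float = 2.4
    arch_gap_deg: float = 120.0  # posterior angular gap: arches are arcs, not rings
    arch_gap_center_deg: float = 90.0  # gap faces +y
    # zygomatic body: the bulkier bone at the anterior end of each arch
    # (the registration zone is zygomatic bone + zygomatic process)
    zygoma_body_radii: tuple[float, float, float] = (4.0, 5.0, 4.0)
    zygoma_body_offset: tuple[float, float, float] = (0.0, -8.0, 1.0)  # from arch center
    arch_left_center: tuple[float, float, float] = (18.0, 38.0, 26.0)
    arch_right_center: tuple[float, float, float] = (70.0, 38.0, 26.0)
    jaw_min: tuple[float, float, float] = (30.0, 14.0, 6.0)
    jaw_max: tuple[float, float, float] = (58.0, 40.0, 16.0)

    # treatment change and inter-scan motion
    jaw_displacement: tuple[float, float, float] = (2.0, 3.0, -1.5)
    true_angles_zyx_deg: tuple[float, float, float] = (0.0, 0.0, 0.0)
    true_translation_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    fov_crop_height_mm: float | None = None

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise PhantomError("spacing must be positive")
        if self.vault_thickness <= 0 or self.arch_tube_radius <= 0:
            raise PhantomError("all radii and thicknesses must be positive")
        if min(self.vault_outer_radii) <= self.vault_thickness:
            raise PhantomError("vault shell thickness exceeds an outer radius")
        if self.supersample < 1:
            raise PhantomError("supersample must be >= 1")

    @property
    def extent_mm(self) -> np.ndarray:
        return np.asarray(self.shape) * self.spacing

    @property
    def true_transform(self) -> RigidTransform:
        """The known rigid transform mapping moving world onto fixed world."""
        return RigidTransform.from_euler(
            self.true_angles_zyx_deg, self.true_translation_mm, self.head_center
        )

    @classmethod
    def coarse(cls, **overrides) -> "PhantomSpec":
        """Half-resolution preset (0.8 mm voxels, same physical extent)."""
        return cls(shape=(110, 110, 80), spacing=0.8, **overrides)

    @classmethod
    def fullsize(cls, **overrides) -> "PhantomSpec":
        """22×22×16 cm field of view at 0.4 mm voxels (i-CAT-like extent)."""
        spec = cls(shape=(550, 550, 400), spacing=0.4, **overrides)
        s = 2.5  # scale structure geometry up to the full head
        return replace(
            spec,
            head_center=tuple(np.asarray(spec.head_center) * s),
            head_radii=tuple(np.asarray(spec.head_radii) * s),
            vault_center=tuple(np.asarray(spec.vault_center) * s),
            vault_outer_radii=tuple(np.asarray(spec.vault_outer_radii) * s),
            vault_thickness=spec.vault_thickness * s,
            cb_band_z=tuple(np.asarray(spec.cb_band_z) * s),
            fh_band_z=tuple(np.asarray(spec.fh_band_z) * s),
            ridge_radius=spec.ridge_radius * s,
            ridge_sag_y=tuple(np.asarray(spec.ridge_sag_y) * s),
            ridge_trans_x=tuple(np.asarray(spec.ridge_trans_x) * s),
            ridge_z_center=spec.ridge_z_center * s,
            arch_major_radius=spec.arch_major_radius * s,
            arch_tube_radius=spec.arch_tube_radius * s,
            zygoma_body_radii=tuple(np.asarray(spec.zygoma_body_radii) * s),
            zygoma_body_offset=tuple(np.asarray(spec.zygoma_body_offset) * s),
            arch_left_center=tuple(np.asarray(spec.arch_left_center) * s),
            arch_right_center=tuple(np.asarray(spec.arch_right_center) * s),
            jaw_min=tuple(np.asarray(spec.jaw_min) * s),
            jaw_max=tuple(np.asarray(spec.jaw_max) * s),
        )


@dataclass
class GroundTruth:
    """Everything needed to score a registration against the phantom."""

    true_transform: RigidTransform
    structure_masks: dict[str, BinaryMask]  # CB, FH, ZL, ZR, jaw (fixed frame)
    jaw_displacement: np.ndarray

    def evaluation_masks(self, margin_voxels: int = 2) -> dict[str, BinaryMask]:
        """Region masks for surface labeling, dilated to cover the surface band.

        The stored structure masks are solid-interior voxel sets; the bone
        iso-surface lies on (slightly outside) the solid boundary, so each
        mask is dilated by ``margin_voxels`` before labeling.  Disjointness
        is preserved by the fixed priority CB > FH > ZL > ZR.
        """
        from scipy import ndimage

        if margin_voxels == 0:
            return {k: self.structure_masks[k] for k in STRUCTURES}
        out: dict[str, BinaryMask] = {}
        taken: np.ndarray | None = None
        struct = np.ones((3, 3, 3), bool)
        for name in STRUCTURES:
            mask = self.structure_masks[name]
            data = ndimage.binary_dilation(mask.data, struct, iterations=margin_voxels)
            if taken is not None:
                data &= ~taken
            taken = data if taken is None else (taken | data)
            out[name] = BinaryMask(data, mask.spacing, mask.origin, mask.axes)
        return out


# ---------------------------------------------------------------------------
# Analytic solids
# ---------------------------------------------------------------------------


def _in_ellipsoid(p: np.ndarray, center, radii) -> np.ndarray:
    q = (p - np.asarray(center)) / np.asarray(radii)
    return np.einsum("ij,ij->i", q, q) <= 1.0


def _in_shell(p: np.ndarray, center, outer, thickness) -> np.ndarray:
    inner = np.asarray(outer) - thickness
    qo = (p - np.asarray(center)) / np.asarray(outer)
    qi = (p - np.asarray(center)) / inner
    ro = np.einsum("ij,ij->i", qo, qo)
    ri = np.einsum("ij,ij->i", qi, qi)
    return (ro <= 1.0) & (ri >= 1.0)


def _in_arch(p: np.ndarray, center, major, tube, gap_deg, gap_center_deg) -> np.ndarray:
    """Partial torus (axis z): a zygomatic-arch-like arc with an angular gap."""
    d = p - np.asarray(center)
    q = np.hypot(d[:, 0], d[:, 1])
    in_tube = (q - major) ** 2 + d[:, 2] ** 2 <= tube * tube
    if gap_deg <= 0:
        return in_tube
    phi0 = np.radians(gap_center_deg)
    with np.errstate(invalid="ignore", divide="ignore"):
        cos_dist = (d[:, 0] * np.cos(phi0) + d[:, 1] * np.sin(phi0)) / np.where(q > 0, q, 1.0)
    on_arc = cos_dist < np.cos(np.radians(gap_deg / 2.0))
    return in_tube & on_arc


def _in_box(p: np.ndarray, lo, hi) -> np.ndarray:
    return np.all((p >= np.asarray(lo)) & (p <= np.asarray(hi)), axis=1)


def _in_ridges(spec: PhantomSpec, p: np.ndarray) -> np.ndarray:
    cx, cy = spec.vault_center[0], spec.vault_center[1]
    r2 = spec.ridge_radius**2
    zc = spec.ridge_z_center
    sag = (
        ((p[:, 0] - cx) ** 2 + (p[:, 2] - zc) ** 2 <= r2)
        & (p[:, 1] >= spec.ridge_sag_y[0])
        & (p[:, 1] <= spec.ridge_sag_y[1])
    )
    trans = (
        ((p[:, 1] - cy) ** 2 + (p[:, 2] - zc) ** 2 <= r2)
        & (p[:, 0] >= spec.ridge_trans_x[0])
        & (p[:, 0] <= spec.ridge_trans_x[1])
    )
    return sag | trans


def _in_zygoma(spec: PhantomSpec, p: np.ndarray, side_center) -> np.ndarray:
    """Arc plus zygomatic-body ellipsoid at its anterior end."""
    arc = _in_arch(
        p, side_center, spec.arch_major_radius, spec.arch_tube_radius,
        spec.arch_gap_deg, spec.arch_gap_center_deg,
    )
    body_center = np.asarray(side_center) + spec.zygoma_body_offset
    return arc | _in_ellipsoid(p, body_center, spec.zygoma_body_radii)


def _bone_mask_at(spec: PhantomSpec, p: np.ndarray, jaw_shift: np.ndarray) -> np.ndarray:
    bone = _in_shell(p, spec.vault_center, spec.vault_outer_radii, spec.vault_thickness)
    bone |= _in_ridges(spec, p)
    bone |= _in_zygoma(spec, p, spec.arch_left_center)
    bone |= _in_zygoma(spec, p, spec.arch_right_center)
    bone |= _in_box(p, np.asarray(spec.jaw_min) + jaw_shift, np.asarray(spec.jaw_max) + jaw_shift)
    return bone


def scene_hu(spec: PhantomSpec, points_mm: np.ndarray, jaw_shift=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Evaluate the analytic phantom scene (HU) at world points (N,3).

    Solid-inclusion tests run only on points inside each solid's bounding
    box (a pure speed optimization; results are identical).
    """
    p = np.asarray(points_mm, dtype=float)
    jaw_shift = np.asarray(jaw_shift, dtype=float)
    hu = np.full(p.shape[0], spec.hu_air)
    hu[_in_ellipsoid(p, spec.head_center, spec.head_radii)] = spec.hu_soft

    bone = np.zeros(p.shape[0], dtype=bool)

    def add(lo, hi, test):
        cand = np.flatnonzero(_in_box(p, lo, hi) & ~bone)
        if cand.size:
            bone[cand[test(p[cand])]] = True

    vc = np.asarray(spec.vault_center)
    vr = np.asarray(spec.vault_outer_radii)
    add(vc - vr, vc + vr,
        lambda q: _in_shell(q, spec.vault_center, spec.vault_outer_radii, spec.vault_thickness))
    ridge_lo = np.array([min(spec.ridge_trans_x[0], vc[0] - spec.ridge_radius),
                         min(spec.ridge_sag_y[0], vc[1] - spec.ridge_radius),
                         spec.ridge_z_center - spec.ridge_radius])
    ridge_hi = np.array([max(spec.ridge_trans_x[1], vc[0] + spec.ridge_radius),
                         max(spec.ridge_sag_y[1], vc[1] + spec.ridge_radius),
                         spec.ridge_z_center + spec.ridge_radius])
    add(ridge_lo, ridge_hi, lambda q: _in_ridges(spec, q))
    he = _arch_halfextent(spec)
    for center in (spec.arch_left_center, spec.arch_right_center):
        c = np.asarray(center)
        add(c - he, c + he, lambda q, c=center: _in_zygoma(spec, q, c))
    add(np.asarray(spec.jaw_min) + jaw_shift, np.asarray(spec.jaw_max) + jaw_shift,
        lambda q: _in_box(q, np.asarray(spec.jaw_min) + jaw_shift, np.asarray(spec.jaw_max) + jaw_shift))

    hu[bone] = spec.hu_bone
    return hu


def _arch_halfextent(spec: PhantomSpec) -> np.ndarray:
    r = spec.arch_major_radius + spec.arch_tube_radius
    arc = np.array([r, r, spec.arch_tube_radius])
    body = np.abs(np.asarray(spec.zygoma_body_offset)) + np.asarray(spec.zygoma_body_radii)
    return np.maximum(arc, body)


def _check_structures_fit(spec: PhantomSpec) -> None:
    extent = spec.extent_mm
    boxes = {
        "cranial vault": (
            np.asarray(spec.vault_center) - spec.vault_outer_radii,
            np.asarray(spec.vault_center) + spec.vault_outer_radii,
        ),
        "left zygomatic arch": (
            np.asarray(spec.arch_left_center) - _arch_halfextent(spec),
            np.asarray(spec.arch_left_center) + _arch_halfextent(spec),
        ),
        "right zygomatic arch": (
            np.asarray(spec.arch_right_center) - _arch_halfextent(spec),
            np.asarray(spec.arch_right_center) + _arch_halfextent(spec),
        ),
        "jaw block": (np.asarray(spec.jaw_min), np.asarray(spec.jaw_max)),
        "displaced jaw block": (
            np.asarray(spec.jaw_min) + spec.jaw_displacement,
            np.asarray(spec.jaw_max) + spec.jaw_displacement,
        ),
    }
    for name, (lo, hi) in boxes.items():
        if np.any(lo < 0) or np.any(hi > extent):
            raise PhantomError(f"structure exceeds the grid: {name} (bounds {lo}..{hi}, extent {extent})")
    # The moving jaw must never touch the four evaluation structures.
    jl = np.asarray(spec.jaw_min) + np.minimum(spec.jaw_displacement, 0)
    jh = np.asarray(spec.jaw_max) + np.maximum(spec.jaw_displacement, 0)
    for name, (lo, hi) in list(boxes.items())[:3]:
        if np.all(jh >= lo) and np.all(jl <= hi):
            # bounding boxes overlap; check conservatively against z separation
            if jh[2] >= lo[2]:
                raise PhantomError(
                    f"displaced jaw block may intersect evaluation structure: {name}"
                )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _render(spec: PhantomSpec, jaw_shift: np.ndarray, world_map=None) -> np.ndarray:
    """Render the scene on the grid with supersampled edge antialiasing.

    ``world_map`` optionally maps grid-frame world points to scene points
    (used to render the moving volume through the true transform).

    Supersampling is applied only near material interfaces: a voxel whose
    3³ neighborhood (dilated once for safety) is uniform receives its center
    value, which equals the supersampled average exactly on constant regions.
    """
    from scipy import ndimage

    nx, ny, nz = spec.shape
    out = np.empty(spec.shape, dtype=np.float32)
    # pass 1: voxel centers, slab-wise
    slab = max(1, int(4e6 // (nx * ny)))
    for k0 in range(0, nz, slab):
        k1 = min(nz, k0 + slab)
        ii, jj, kk = np.meshgrid(
            np.arange(nx, dtype=np.float64),
            np.arange(ny, dtype=np.float64),
            np.arange(k0, k1, dtype=np.float64),
            indexing="ij",
        )
        pts = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) * spec.spacing
        if world_map is not None:
            pts = world_map(pts)
        out[:, :, k0:k1] = scene_hu(spec, pts, jaw_shift).reshape(nx, ny, k1 - k0)

    s = spec.supersample
    if s <= 1:
        return out
    # pass 2: supersample voxels whose neighborhood is not uniform
    lo = ndimage.minimum_filter(out, size=3, mode="nearest")
    hi = ndimage.maximum_filter(out, size=3, mode="nearest")
    edge = ndimage.binary_dilation(hi > lo, np.ones((3, 3, 3), bool))
    idx = np.argwhere(edge).astype(np.float64)
    sub = (np.arange(s) + 0.5) / s - 0.5
    offsets = np.array([[ox, oy, oz] for ox in sub for oy in sub for oz in sub])
    acc = np.zeros(len(idx))
    chunk = max(1, int(4e6 // len(offsets)))
    for c0 in range(0, len(idx), chunk):
        c1 = min(len(idx), c0 + chunk)
        pts = (idx[c0:c1, None, :] + offsets[None, :, :]).reshape(-1, 3) * spec.spacing
        if world_map is not None:
            pts = world_map(pts)
        hu = scene_hu(spec, pts, jaw_shift).reshape(c1 - c0, len(offsets))
        acc[c0:c1] = hu.mean(axis=1)
    ij = idx.astype(np.intp)
    out[ij[:, 0], ij[:, 1], ij[:, 2]] = acc.astype(np.float32)
    return out


def _structure_masks(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Per-structure masks by voxel-center inclusion tests, fixed frame."""
    nx, ny, nz = spec.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nz, dtype=np.float64),
        indexing="ij",
    )
    p = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) * spec.spacing
    vc = np.asarray(spec.vault_center)
    shell = _in_shell(p, vc, spec.vault_outer_radii, spec.vault_thickness)
    z_rel = p[:, 2] - vc[2]
    cb = (shell & (z_rel >= spec.cb_band_z[0]) & (z_rel < spec.cb_band_z[1])) | _in_ridges(spec, p)
    fh = (
        shell
        & (z_rel >= spec.fh_band_z[0])
        & (z_rel < spec.fh_band_z[1])
        & (p[:, 1] < vc[1] - spec.fh_y_fraction * spec.vault_outer_radii[1])
    )
    fh &= ~cb
    zl = _in_zygoma(spec, p, spec.arch_left_center) & ~cb & ~fh
    zr = _in_zygoma(spec, p, spec.arch_right_center) & ~cb & ~fh
    jaw = _in_box(p, spec.jaw_min, spec.jaw_max) & ~cb & ~fh & ~zl & ~zr
    shape = (nx, ny, nz)
    return {
        "CB": cb.reshape(shape),
        "FH": fh.reshape(shape),
        "ZL": zl.reshape(shape),
        "ZR": zr.reshape(shape),
        "jaw": jaw.reshape(shape),
    }


def analytic_bone_mask(spec: PhantomSpec, jaw_shift=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Voxel-center inclusion test of the full bone solid set (oracle helper)."""
    nx, ny, nz = spec.shape
    ii, jj, kk = np.meshgrid(
        np.arange(nx, dtype=np.float64),
        np.arange(ny, dtype=np.float64),
        np.arange(nz, dtype=np.float64),
        indexing="ij",
    )
    p = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1) * spec.spacing
    return _bone_mask_at(spec, p, np.asarray(jaw_shift, dtype=float)).reshape(nx, ny, nz)


def vault_shell_volume_mm3(spec: PhantomSpec) -> float:
    """Analytic volume of the cranial-vault shell (mm³)."""
    outer = np.asarray(spec.vault_outer_radii)
    inner = outer - spec.vault_thickness
    return float(4.0 / 3.0 * np.pi * (np.prod(outer) - np.prod(inner)))


def generate_phantom_pair(spec: PhantomSpec) -> tuple[Volume, Volume, GroundTruth]:
    """Render the fixed/moving pair and the ground truth for one case.

    The fixed volume shows the structures at rest.  The moving volume shows
    the same scene with the jaw translated by the displacement vector,
    sampled at T(x) where T is the true rigid transform (moving world →
    fixed world); identical seeds reproduce identical volumes bit-exactly.
    """
    _check_structures_fit(spec)
    geometry = dict(spacing=np.full(3, spec.spacing), origin=np.zeros(3), axes=np.eye(3))
    truth_t = spec.true_transform
    jaw_shift = np.asarray(spec.jaw_displacement, dtype=float)

    fixed_data = _render(spec, np.zeros(3))
    moving_data = _render(spec, jaw_shift, world_map=truth_t.apply)

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd > 0:
        fixed_data = fixed_data + rng.normal(0.0, spec.noise_sd, fixed_data.shape).astype(np.float32)
        moving_data = moving_data + rng.normal(0.0, spec.noise_sd, moving_data.shape).astype(np.float32)

    fixed = Volume(fixed_data, **geometry)
    moving = Volume(moving_data, **geometry)
    masks = {
        name: BinaryMask(data, **geometry) for name, data in _structure_masks(spec).items()
    }
    truth = GroundTruth(truth_t, masks, jaw_shift)

    if spec.fov_crop_height_mm is not None:
        fixed = crop_fov(fixed, spec.fov_crop_height_mm)
        moving = crop_fov(moving, spec.fov_crop_height_mm)
    return fixed, moving, truth


def crop_fov(volume: Volume, height_mm: float) -> Volume:
    """Keep the inferior-most slab of the stated height (reduced scan height).

    Retained voxels keep their world coordinates; the superior part of the
    grid (cranial vault / cranial base in a head-oriented phantom) is removed.
    """
    if height_mm <= 0:
        raise PhantomError("crop height must be positive")
    nz = volume.data.shape[2]
    dz = volume.spacing[2]
    if height_mm > nz * dz + 1e-9:
        raise PhantomError(f"crop height {height_mm} mm exceeds volume height {nz * dz} mm")
    keep = min(nz, max(1, int(round(height_mm / dz))))
    return Volume(volume.data[:, :, :keep].copy(), volume.spacing, volume.origin, volume.axes)


# ---------------------------------------------------------------------------
# Ground-truth scoring and landmarks
# ---------------------------------------------------------------------------


@dataclass
class RecoveryReport:
    translation_error_mm: float
    rotation_error_deg: float
    tre_mm: float
    per_probe_mm: np.ndarray


def evaluate_recovery(
    truth: GroundTruth | RigidTransform,
    estimate: RigidTransform,
    probe_points_mm: np.ndarray,
) -> RecoveryReport:
    """Score an estimated transform against the known truth.

    The residual map Δ = estimate ∘ truth⁻¹ acts on fixed-frame points;
    rotation error is the angle of Δ's rotation, translation error the
    displacement of the truth's rotation center under Δ, and the target
    registration error (TRE) the mean displacement over the probe points.
    """
    true_t = truth.true_transform if isinstance(truth, GroundTruth) else truth
    residual = estimate.compose(true_t.inverse())
    probes = np.atleast_2d(np.asarray(probe_points_mm, dtype=float))
    disp = np.linalg.norm(residual.apply(probes) - probes, axis=1)
    ref = true_t.center
    return RecoveryReport(
        translation_error_mm=float(np.linalg.norm(residual.apply(ref) - ref)),
        rotation_error_deg=residual.rotation_angle_deg(),
        tre_mm=float(disp.mean()),
        per_probe_mm=disp,
    )


def structure_centroids(truth: GroundTruth) -> np.ndarray:
    """World centroids of the four evaluation structures (TRE probe points)."""
    pts = []
    for name in STRUCTURES:
        mask = truth.structure_masks[name]
        idx = np.argwhere(mask.data)
        pts.append(voxel_to_world(mask, idx.mean(axis=0)))
    return np.asarray(pts)


def default_landmarks(spec: PhantomSpec) -> np.ndarray:
    """Well-spread fixed-frame anatomical points for rough alignment."""
    vc = np.asarray(spec.vault_center)
    a, b, c = spec.vault_outer_radii
    return np.asarray(
        [
            np.asarray(spec.arch_left_center) + [-spec.arch_major_radius, 0.0, 0.0],
            np.asarray(spec.arch_right_center) + [spec.arch_major_radius, 0.0, 0.0],
            vc + np.array([0.0, 0.0, c - spec.vault_thickness / 2]),
            vc + np.array([0.0, -(b - spec.vault_thickness / 2), 0.0]),
            vc + np.array([a - spec.vault_thickness / 2, 0.0, -4.0]),
            vc + np.array([-(a - spec.vault_thickness / 2), 0.0, -4.0]),
        ]
    )


def random_case_spec(
    seed: int,
    base: PhantomSpec | None = None,
    max_translation_mm: float = 10.0,
    max_rotation_deg: float = 10.0,
    noise_sd: float = 0.0,
) -> PhantomSpec:
    """Draw a per-case spec with a random true transform (seeded).

    Translation direction is uniform on the sphere with magnitude uniform in
    [0, max]; rotation axis uniform with angle uniform in [0, max].
    """
    base = base or PhantomSpec()
    rng = np.random.default_rng(seed)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    translation = direction * rng.uniform(0.0, max_translation_mm)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, max_rotation_deg))
    angles_zyx = Rotation.from_rotvec(axis * angle).as_euler("ZYX", degrees=True)
    return replace(
        base,
        seed=seed,
        noise_sd=noise_sd,
        true_angles_zyx_deg=tuple(angles_zyx),
        true_translation_mm=tuple(translation),
    )
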