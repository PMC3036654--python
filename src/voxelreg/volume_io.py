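"""Volume containers and file I/O for CT/CBCT-like grids.

World-coordinate convention used throughout the package:

    world(i, j, k) = origin + axes @ (spacing * (i, j, k))

with 0-based indices located at voxel centers, ``spacing`` in mm/voxel and
``axes`` an orthonormal direction matrix (identity for axis-aligned volumes).
Intensities are signed floating values on the Hounsfield scale: air is about
-1000 HU, soft tissue 0-100 HU, bone above roughly 250 HU.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class VolumeIOError(RuntimeError):
    """Raised when a volume file cannot be read or written consistently."""


@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing (mm), origin (mm) and axes.

    ``data`` is indexed ``[i, j, k]`` so that index axis 0 maps to world x
    under the default identity ``axes``.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise ValueError("every volume dimension must be >= 1")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)
        if not np.allclose(self.axes @ self.axes.T, np.eye(3), atol=1e-6):
            raise ValueError("axes must be orthonormal")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the grid (mm) along each axis (voxel-center span + 1 voxel)."""
        return self.spacing * np.asarray(self.data.shape)

    def same_geometry_as(self, other: "Volume", atol: float = 1e-9) -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.spacing, other.spacing, atol=atol)
            and np.allclose(self.origin, other.origin, atol=atol)
            and np.allclose(self.axes, other.axes, atol=atol)
        )

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.spacing.copy(), self.origin.copy(), self.axes.copy())


@dataclass
class BinaryMask:
    """A boolean grid sharing the geometry of its parent :class:`Volume`."""

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    axes: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3D")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.axes = np.asarray(self.axes, dtype=float).reshape(3, 3)

    @classmethod
    def like(cls, volume: Volume, data: np.ndarray) -> "BinaryMask":
        if data.shape != volume.data.shape:
            raise ValueError(f"mask shape {data.shape} != volume shape {volume.data.shape}")
        return cls(data, volume.spacing, volume.origin, volume.axes)

    def as_volume(self) -> Volume:
        return Volume(self.data.astype(np.uint8), self.spacing, self.origin, self.axes)

    @property
    def count(self) -> int:
        return int(self.data.sum())


def voxel_to_world(volume: Volume | BinaryMask, index: np.ndarray) -> np.ndarray:
    """Map continuous voxel indices (N,3) or (3,) to world mm."""
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    pts = volume.origin + (volume.axes @ (volume.spacing * idx).T).T
    return pts[0] if np.asarray(index).ndim == 1 else pts


def world_to_voxel(volume: Volume | BinaryMask, point_mm: np.ndarray) -> np.ndarray:
    """Map world points (N,3) or (3,) to continuous voxel indices.

    Exact inverse of :func:`voxel_to_world`; out-of-grid points simply yield
    indices outside ``[0, shape-1]`` (use :func:`indices_in_grid` to flag them).
    """
    pts = np.atleast_2d(np.asarray(point_mm, dtype=float))
    idx = (volume.axes.T @ (pts - volume.origin).T).T / volume.spacing
    return idx[0] if np.asarray(point_mm).ndim == 1 else idx


def indices_in_grid(volume: Volume | BinaryMask, index: np.ndarray) -> np.ndarray:
    """Boolean flags: True where a continuous index lies inside the voxel-center grid."""
    idx = np.atleast_2d(np.asarray(index, dtype=float))
    hi = np.asarray(volume.data.shape) - 1
    return np.all((idx >= 0) & (idx <= hi), axis=1)


def _detect_format(path: str | os.PathLike) -> str:
    p = Path(path)
    name = p.name.lower()
    if p.is_dir():
        return "dicom-series"
    if name.endswith((".nii", ".nii.gz")):
        return "nifti"
    if name.endswith((".mhd", ".mha")):
        return "mhd"
    raise VolumeIOError(f"cannot infer volume format from path {path!r}")


def read_volume(path: str | os.PathLike, format: str | None = None) -> Volume:
    """Read a volume from NIfTI, MHD/MHA or a DICOM series directory.

    Spacing/origin/axes are taken from the file header; DICOM intensities are
    rescaled to HU when rescale slope/intercept are present.
    """
    path = Path(path)
    if not path.exists():
        raise VolumeIOError(f"no such file or directory: {path}")
    fmt = format or _detect_format(path)
    if fmt == "nifti":
        return _read_nifti(path)
    if fmt == "mhd":
        return _read_mhd(path)
    if fmt == "dicom-series":
        return _read_dicom_series(path)
    raise VolumeIOError(f"unsupported format {fmt!r}")


def write_volume(volume: Volume, path: str | os.PathLike, format: str | None = None) -> None:
    """Write a volume to NIfTI or MHD; the file round-trips bit-exactly."""
    path = Path(path)
    fmt = format
    if fmt is None:
        name = path.name.lower()
        if name.endswith((".nii", ".nii.gz")):
            fmt = "nifti"
        elif name.endswith((".mhd", ".mha")):
            fmt = "mhd"
        else:
            raise VolumeIOError(f"cannot infer output format from {path!r}")
    if not path.parent.is_dir():
        raise VolumeIOError(f"output directory does not exist: {path.parent}")
    if fmt == "nifti":
        _write_nifti(volume, path)
    elif fmt == "mhd":
        _write_mhd(volume, path)
    else:
        raise VolumeIOError(f"unsupported output format {fmt!r}")


def _read_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise VolumeIOError(f"expected a 3D NIfTI volume, got shape {data.shape}")
    affine = img.affine
    linear = affine[:3, :3]
    spacing = np.linalg.norm(linear, axis=0)
    if np.any(spacing <= 0):
        raise VolumeIOError("degenerate NIfTI affine (zero column norm)")
    axes = linear / spacing
    return Volume(data, spacing, affine[:3, 3], axes)


def _write_nifti(volume: Volume, path: Path) -> None:
    import nibabel as nib

    affine = np.eye(4)
    affine[:3, :3] = volume.axes @ np.diag(volume.spacing)
    affine[:3, 3] = volume.origin
    img = nib.Nifti1Image(np.asarray(volume.data), affine)
    nib.save(img, str(path))


def _read_mhd(path: Path) -> Volume:
    import SimpleITK as sitk

    img = sitk.ReadImage(str(path))
    # SimpleITK arrays are indexed [z, y, x]; transpose to [x, y, z].
    data = np.transpose(sitk.GetArrayFromImage(img), (2, 1, 0))
    axes = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    return Volume(data, np.asarray(img.GetSpacing()), np.asarray(img.GetOrigin()), axes)


def _write_mhd(volume: Volume, path: Path) -> None:
    import SimpleITK as sitk

    img = sitk.GetImageFromArray(np.ascontiguousarray(np.transpose(volume.data, (2, 1, 0))))
    img.SetSpacing(tuple(volume.spacing))
    img.SetOrigin(tuple(volume.origin))
    img.SetDirection(tuple(volume.axes.ravel()))
    sitk.WriteImage(img, str(path))


def _read_dicom_series(path: Path) -> Volume:
    """Read a single-series axial DICOM directory with uniform slice spacing."""
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file() and p.suffix.lower() in {".dcm", ""})
    datasets = []
    for f in files:
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:  # non-DICOM clutter is skipped, not fatal
            continue
    if not datasets:
        raise VolumeIOError(f"no DICOM slices found in {path}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise VolumeIOError(f"mixed DICOM series in {path}: found {len(uids)} SeriesInstanceUIDs")

    orients = np.array([np.asarray(ds.ImageOrientationPatient, dtype=float) for ds in datasets])
    if not np.allclose(orients, orients[0], atol=1e-6):
        raise VolumeIOError("DICOM slices do not share a common orientation")
    row = orients[0][:3]
    col = orients[0][3:]
    normal = np.cross(row, col)

    positions = np.array([np.asarray(ds.ImagePositionPatient, dtype=float) for ds in datasets])
    order = np.argsort(positions @ normal)
    datasets = [datasets[i] for i in order]
    positions = positions[order]
    z = positions @ normal
    if len(z) > 1:
        dz = np.diff(z)
        if np.any(dz <= 0):
            raise VolumeIOError("duplicate or non-monotonic DICOM slice positions")
        if np.ptp(dz) > 1e-3 * np.mean(dz) + 1e-6:
            raise VolumeIOError(
                f"non-uniform DICOM slice spacing: min {dz.min():.6g} mm, max {dz.max():.6g} mm"
            )
        slice_spacing = float(np.mean(dz))
    else:
        slice_spacing = float(getattr(datasets[0], "SliceThickness", 1.0))

    ps = np.asarray(datasets[0].PixelSpacing, dtype=float)  # (row, col) mm
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    stack = np.stack(slices, axis=0)  # [slice, row, col]

    # Package order [i, j, k]: i along image columns (row direction cosine),
    # j along image rows (column direction cosine), k along the slice normal.
    data = np.transpose(stack, (2, 1, 0))
    axes = np.column_stack([row, col, normal])
    spacing = np.array([ps[1], ps[0], slice_spacing])
    return Volume(data, spacing, positions[0], axes)
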