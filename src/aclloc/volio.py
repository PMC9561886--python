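"""Volumetric image I/O and voxel <-> physical coordinate geometry.

All physical coordinates in the package are expressed in millimetres in the
LPS frame (the DICOM patient coordinate convention).  NIfTI headers, which
are RAS by definition, are converted on read and write so that a single
internal frame is used everywhere.

Voxel indices are 0-based and may be fractional; crop boxes are inclusive on
both ends.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Geometry",
    "Volume",
    "LabelMap",
    "LandmarkGT",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
    "crop_patch",
    "resample_in_plane",
    "read_landmarks",
    "write_landmarks",
]

# RAS <-> LPS: flip the sign of the first two physical axes (involution).
_RAS2LPS = np.diag([-1.0, -1.0, 1.0, 1.0])


@dataclass(frozen=True)
class Geometry:
    """Mapping between voxel indices and physical mm coordinates.

    ``physical = origin + orientation @ (spacing * index)``

    Parameters
    ----------
    spacing : (3,) array
        mm per voxel along each axis; all components > 0.
    origin : (3,) array
        Physical mm coordinate of voxel (0, 0, 0).
    orientation : (3, 3) array
        Direction matrix whose *columns* are the unit direction vectors of
        the three voxel axes; orthonormal (|det| = 1 within 1e-6).
    """

    spacing: np.ndarray
    origin: np.ndarray
    orientation: np.ndarray = field(default_factory=lambda: np.eye(3))

    def __post_init__(self):
        object.__setattr__(self, "spacing", np.asarray(self.spacing, dtype=float))
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        object.__setattr__(self, "orientation", np.asarray(self.orientation, dtype=float))
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise ValueError(f"spacing must be 3 positive components, got {self.spacing}")
        if self.origin.shape != (3,) or not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be a finite 3-vector")
        if self.orientation.shape != (3, 3):
            raise ValueError("orientation must be 3x3")
        if abs(abs(np.linalg.det(self.orientation)) - 1.0) > 1e-6:
            raise ValueError("orientation must be orthonormal (|det| = 1)")

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel -> physical (LPS) affine."""
        a = np.eye(4)
        a[:3, :3] = self.orientation * self.spacing[None, :]
        a[:3, 3] = self.origin
        return a

    def voxel_to_physical(self, index) -> np.ndarray:
        index = np.asarray(index, dtype=float)
        return self.origin + (self.orientation * self.spacing[None, :]) @ index

    def physical_to_voxel(self, point) -> np.ndarray:
        point = np.asarray(point, dtype=float)
        return (self.orientation.T @ (point - self.origin)) / self.spacing


def voxel_to_physical(geometry: Geometry, index) -> np.ndarray:
    """Map a (possibly fractional) voxel index to physical mm."""
    return geometry.voxel_to_physical(index)


def physical_to_voxel(geometry: Geometry, point) -> np.ndarray:
    """Exact inverse of :func:`voxel_to_physical`."""
    return geometry.physical_to_voxel(point)


@dataclass
class Volume:
    """A 3D scalar intensity grid plus its geometry."""

    data: np.ndarray
    geometry: Geometry

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("Volume data must be a non-empty 3D grid")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume intensities must be finite")

    @property
    def shape(self):
        return self.data.shape


@dataclass
class LabelMap:
    """Integer label grid (0 = background) sharing a Volume's geometry."""

    data: np.ndarray
    geometry: Geometry
    label_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("LabelMap data must be 3D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError("LabelMap data must be integer")
        if self.data.min() < 0:
            raise ValueError("labels must be non-negative")


@dataclass
class LandmarkGT:
    """Ground truth for one case: rupture point, footprint centers, side class.

    All coordinates are physical mm (LPS).  ``side`` is one of
    ``{"femoral", "middle", "tibial"}``.
    """

    rupture_point: np.ndarray
    femoral_center: np.ndarray
    tibial_center: np.ndarray
    side: str

    def __post_init__(self):
        self.rupture_point = np.asarray(self.rupture_point, dtype=float)
        self.femoral_center = np.asarray(self.femoral_center, dtype=float)
        self.tibial_center = np.asarray(self.tibial_center, dtype=float)
        for v in (self.rupture_point, self.femoral_center, self.tibial_center):
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError("landmarks must be finite 3-vectors")
        if np.linalg.norm(self.femoral_center - self.tibial_center) <= 0:
            raise ValueError("femoral and tibial centers must be distinct")
        if self.side not in ("femoral", "middle", "tibial"):
            raise ValueError(f"unknown side {self.side!r}")


# ---------------------------------------------------------------------------
# NIfTI / DICOM I/O
# ---------------------------------------------------------------------------


def _geometry_from_lps_affine(affine: np.ndarray) -> Geometry:
    m = affine[:3, :3]
    spacing = np.linalg.norm(m, axis=0)
    orientation = m / spacing[None, :]
    return Geometry(spacing=spacing, origin=affine[:3, 3], orientation=orientation)


def write_volume(volume: Volume, path) -> None:
    """Write a Volume (or LabelMap data + geometry) to NIfTI-1.

    The internal LPS affine is converted to the RAS affine NIfTI requires.
    """
    affine_ras = _RAS2LPS @ volume.geometry.affine  # LPS -> RAS (involution)
    img = nib.Nifti1Image(np.asanyarray(volume.data), affine_ras)
    img.header.set_zooms(tuple(volume.geometry.spacing))
    nib.save(img, str(path))


def read_volume(path) -> Volume:
    """Read a volume from a NIfTI file or a directory holding one DICOM series.

    DICOM slices are sorted by their projected position along the slice
    normal, never by filename.  A directory mixing series UIDs, or a series
    whose slice spacing is non-uniform beyond 1e-3 mm, raises ``ValueError``.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.is_dir():
        from aclloc import _dicom

        data, geometry = _dicom.read_series(p)
        return Volume(data=data, geometry=geometry)
    img = nib.load(str(p))
    affine_lps = _RAS2LPS @ np.asarray(img.affine)
    data = np.asanyarray(img.dataobj)
    return Volume(data=data, geometry=_geometry_from_lps_affine(affine_lps))


def write_labelmap(labels: LabelMap, path) -> None:
    write_volume(Volume(data=labels.data.astype(np.int16), geometry=labels.geometry), path)


def read_labelmap(path, label_names: dict[int, str] | None = None) -> LabelMap:
    vol = read_volume(path)
    data = np.asarray(vol.data)
    if not np.issubdtype(data.dtype, np.integer):
        rounded = np.rint(data)
        if not np.allclose(data, rounded, atol=1e-6):
            raise ValueError("label file does not contain integer labels")
        data = rounded.astype(np.int32)
    return LabelMap(data=data, geometry=vol.geometry, label_names=dict(label_names or {}))


# ---------------------------------------------------------------------------
# Cropping and resampling
# ---------------------------------------------------------------------------


def crop_patch(volume: Volume, box) -> Volume:
    """Crop to an inclusive per-axis voxel box, preserving physical positions.

    ``box`` is ``((i0, i1), (j0, j1), (k0, k1))`` with ``min <= max`` per axis.
    The returned Volume's origin is moved so every retained voxel maps to the
    same physical point as before cropping.
    """
    box = np.asarray(box, dtype=int)
    if box.shape != (3, 2):
        raise ValueError("box must be 3 pairs of inclusive bounds")
    shape = volume.data.shape
    for ax in range(3):
        lo, hi = box[ax]
        if lo > hi:
            raise ValueError(f"box min > max on axis {ax}")
        if lo < 0 or hi >= shape[ax]:
            raise ValueError(f"box out of bounds on axis {ax}: {(lo, hi)} vs {shape[ax]}")
    sl = tuple(slice(lo, hi + 1) for lo, hi in box)
    new_origin = volume.geometry.voxel_to_physical(box[:, 0])
    geom = Geometry(
        spacing=volume.geometry.spacing,
        origin=new_origin,
        orientation=volume.geometry.orientation,
    )
    return Volume(data=volume.data[sl].copy(), geometry=geom)


def resample_in_plane(volume: Volume, target_spacing, *, order: int = 1) -> Volume:
    """Resample the two in-plane axes to ``target_spacing`` (mm pair).

    Slice count and slice spacing are untouched.  Linear interpolation for
    intensities (``order=1``); pass ``order=0`` for label maps.  The grid
    origin is kept, so the physical extent is preserved within one voxel.
    """
    target = np.asarray(target_spacing, dtype=float)
    if target.shape != (2,) or np.any(target <= 0):
        raise ValueError("target_spacing must be two positive mm values")
    sp = volume.geometry.spacing
    n0, n1, n2 = volume.data.shape
    new_n0 = max(1, int(np.ceil(n0 * sp[0] / target[0])))
    new_n1 = max(1, int(np.ceil(n1 * sp[1] / target[1])))
    if target[0] == sp[0] and target[1] == sp[1]:
        return Volume(data=volume.data.copy(), geometry=volume.geometry)
    ii = np.arange(new_n0) * (target[0] / sp[0])
    jj = np.arange(new_n1) * (target[1] / sp[1])
    kk = np.arange(n2, dtype=float)
    grid = np.meshgrid(ii, jj, kk, indexing="ij")
    coords = np.stack([g.ravel() for g in grid])
    out = ndimage.map_coordinates(
        volume.data.astype(float), coords, order=order, mode="nearest"
    ).reshape(new_n0, new_n1, n2)
    geom = Geometry(
        spacing=np.array([target[0], target[1], sp[2]]),
        origin=volume.geometry.origin,
        orientation=volume.geometry.orientation,
    )
    return Volume(data=out, geometry=geom)


# ---------------------------------------------------------------------------
# Landmark annotations (TSV, scanner physical mm)
# ---------------------------------------------------------------------------

_LANDMARK_FIELDS = ["case_id", "x_mm", "y_mm", "z_mm", "side"]


def write_landmarks(rows, path) -> None:
    """Write landmark annotations as TSV.

    ``rows`` is an iterable of ``(case_id, point, side_or_None)``.  Points are
    scanner physical mm (LPS) — never patch-local coordinates.
    """
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_LANDMARK_FIELDS)
        for case_id, point, side in rows:
            point = np.asarray(point, dtype=float)
            w.writerow(
                [case_id, repr(float(point[0])), repr(float(point[1])), repr(float(point[2])), side or ""]
            )


def read_landmarks(path):
    """Read a landmark TSV; returns list of (case_id, point ndarray, side|None)."""
    out = []
    with open(path, newline="") as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r)
        if header[:4] != _LANDMARK_FIELDS[:4]:
            raise ValueError(f"unexpected landmark TSV header: {header}")
        for row in r:
            if not row:
                continue
            point = np.array([float(row[1]), float(row[2]), float(row[3])])
            side = row[4] if len(row) > 4 and row[4] else None
            out.append((row[0], point, side))
    return out
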