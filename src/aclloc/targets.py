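"""Training targets: Gaussian heatmaps with a false-positive suppression band,
one-hot segmentation targets, straddle-slice labels, box targets, and the
rotation / flip / elastic augmentations.

The heatmap target is a 3D Gaussian centered at the annotated rupture
position, rescaled so the maximum over the grid is exactly 1; voxels beyond
a truncation radius are background (0), and a thin shell immediately outside
the Gaussian support is flagged *invalid* — excluded from the training loss
— so the network is not punished for hedging just outside the landmark
region (false-positive suppression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from aclloc.volio import Geometry

__all__ = [
    "HeatmapTarget",
    "SliceTarget",
    "BoxTarget",
    "gaussian_heatmap",
    "seg_target",
    "slice_target",
    "box_target",
    "augment",
    "flip",
    "rotate_inplane",
    "elastic",
]


@dataclass
class HeatmapTarget:
    """Per-voxel target in [0, 1] plus the invalid (loss-excluded) mask."""

    values: np.ndarray
    invalid_mask: np.ndarray
    landmark_index: np.ndarray  # fractional voxel index of the center

    def __post_init__(self):
        if self.values.shape != self.invalid_mask.shape:
            raise ValueError("values and invalid_mask must share a shape")
        if np.any(self.values[self.invalid_mask] != 0):
            raise ValueError("invalid voxels must carry no target value")


@dataclass(frozen=True)
class SliceTarget:
    """The two slices straddling the fractional slice coordinate, plus weights."""

    straddle: tuple
    target_vector: np.ndarray

    def __post_init__(self):
        lo, hi = self.straddle
        if hi - lo not in (0, 1):
            raise ValueError("straddle indices must be equal or consecutive")
        v = self.target_vector
        if np.any(v < 0) or abs(float(v.sum()) - 1.0) > 1e-9:
            raise ValueError("target_vector must be a probability vector")


@dataclass(frozen=True)
class BoxTarget:
    """In-plane box (pixel units); the keypoint is the box center."""

    center: np.ndarray
    size: np.ndarray

    def __post_init__(self):
        if np.any(np.asarray(self.size) <= 0):
            raise ValueError("box size must be positive")


def gaussian_heatmap(
    geometry: Geometry,
    shape,
    landmark,
    sigma: float = 3.0,
    support_radius: float | None = None,
    suppression_band: float = 2.0,
) -> HeatmapTarget:
    """Build a Gaussian heatmap target around a physical landmark.

    ``value(v) = exp(-||p(v) - landmark||^2 / (2 sigma^2))``, rescaled so the
    maximum over the grid is exactly 1 (attained at the voxel containing the
    landmark).  Voxels with physical distance <= ``support_radius`` (default
    3 sigma) are the landmark voxels; the shell
    ``support_radius < d <= support_radius + suppression_band`` is flagged
    invalid; everything farther is 0.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if support_radius is None:
        support_radius = 3.0 * sigma
    if support_radius < sigma:
        raise ValueError("support_radius must be >= sigma")
    if suppression_band < 0:
        raise ValueError("suppression_band must be >= 0")
    landmark = np.asarray(landmark, dtype=float)
    idx = geometry.physical_to_voxel(landmark)
    if np.any(idx < -0.5) or np.any(idx > np.asarray(shape) - 0.5):
        raise ValueError(f"landmark {landmark} (voxel {idx}) outside grid {shape}")

    axes = [np.arange(n, dtype=float) for n in shape]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"))  # voxel indices
    # physical offset of each voxel center from the landmark
    m = geometry.orientation * geometry.spacing[None, :]
    phys = np.einsum("ab,bxyz->axyz", m, grid) + geometry.origin.reshape(3, 1, 1, 1)
    dist = np.linalg.norm(phys - landmark.reshape(3, 1, 1, 1), axis=0)

    values = np.exp(-(dist**2) / (2.0 * sigma**2))
    inside = dist <= support_radius
    values[~inside] = 0.0
    peak = values.max()
    if peak <= 0:
        raise ValueError("no voxel inside the Gaussian support")
    values /= peak
    invalid = (dist > support_radius) & (dist <= support_radius + suppression_band)
    return HeatmapTarget(
        values=values.astype(np.float32), invalid_mask=invalid, landmark_index=idx
    )


def seg_target(labels) -> np.ndarray:
    """One-hot (n_classes, *grid) target from a LabelMap."""
    data = np.asarray(labels.data)
    names = getattr(labels, "label_names", None) or {}
    n_classes = len(names) if names else int(data.max()) + 1
    if data.max() >= n_classes:
        missing = sorted(set(np.unique(data)) - set(names))
        raise ValueError(f"label values without a name: {missing}")
    onehot = np.zeros((n_classes, *data.shape), dtype=np.float32)
    for c in range(n_classes):
        onehot[c] = data == c
    return onehot


def slice_target(geometry: Geometry, landmark, n_slices: int) -> SliceTarget:
    """Straddle-slice supervision for the slice-selection network.

    The landmark's (usually fractional) slice coordinate z selects the two
    integer slices on either side; the target vector splits the weight
    linearly as (1 - frac, frac).
    """
    z = float(geometry.physical_to_voxel(landmark)[2])
    if z < 0 or z > n_slices - 1:
        raise ValueError(f"landmark slice coordinate {z} outside [0, {n_slices - 1}]")
    lo = int(np.floor(z))
    hi = int(np.ceil(z))
    frac = z - lo
    vec = np.zeros(n_slices)
    if hi == lo:
        vec[lo] = 1.0
    else:
        vec[lo] = 1.0 - frac
        vec[hi] = frac
    return SliceTarget(straddle=(lo, hi), target_vector=vec)


def box_target(center_px, size_px) -> BoxTarget:
    return BoxTarget(center=np.asarray(center_px, dtype=float), size=np.asarray(size_px, dtype=float))


# ---------------------------------------------------------------------------
# Augmentation primitives.  All transforms are expressed in voxel index space
# and applied identically to the image, any paired target grids, and the
# landmark coordinates.
# ---------------------------------------------------------------------------


def flip(array: np.ndarray, axis: int, landmark=None):
    """Mirror along one axis; landmark index i -> (n - 1) - i on that axis."""
    out = np.flip(array, axis=axis).copy()
    if landmark is None:
        return out
    lm = np.asarray(landmark, dtype=float).copy()
    lm[axis] = (array.shape[axis] - 1) - lm[axis]
    return out, lm


def _rot_matrix(angle_deg: float) -> np.ndarray:
    a = np.deg2rad(angle_deg)
    return np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])


def rotate_inplane(array: np.ndarray, angle_deg: float, landmark=None, order: int = 1):
    """Rotate about the center of the first two (in-plane) axes.

    The image is resampled by the inverse map; landmark coordinates are
    transformed forward, so image content and landmark stay aligned.
    """
    shape = array.shape
    c = (np.array(shape[:2], dtype=float) - 1) / 2.0
    rot = _rot_matrix(angle_deg)
    inv = rot.T
    idx0, idx1 = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    pts = np.stack([idx0.ravel() - c[0], idx1.ravel() - c[1]])
    src = inv @ pts + c[:, None]
    if array.ndim == 3:
        coords = np.stack(
            [
                np.repeat(src[0], shape[2]),
                np.repeat(src[1], shape[2]),
                np.tile(np.arange(shape[2]), src.shape[1]),
            ]
        )
    else:
        coords = src
    out = ndimage.map_coordinates(array.astype(float), coords, order=order, mode="nearest")
    out = out.reshape(shape)
    if landmark is None:
        return out
    lm = np.asarray(landmark, dtype=float).copy()
    lm[:2] = rot @ (lm[:2] - c) + c
    return out, lm


def _elastic_field(shape, seed: int, control_spacing: int, max_disp: float):
    rng = np.random.default_rng(seed)
    coarse = [max(2, int(np.ceil(n / control_spacing)) + 1) for n in shape]
    field = []
    for _ in range(len(shape)):
        grid = rng.uniform(-max_disp, max_disp, coarse)
        zoom = [n / g for n, g in zip(shape, coarse)]
        field.append(ndimage.zoom(grid, zoom, order=1, mode="nearest"))
    return np.stack(field)


def elastic(
    array: np.ndarray,
    seed: int,
    control_spacing: int = 8,
    max_disp: float = 2.0,
    landmark=None,
    order: int = 1,
):
    """Seeded elastic deformation from a coarse displacement grid.

    The image is warped by backward mapping ``out(x) = in(x + d(x))``.  The
    landmark is moved to the point x' whose backward lookup lands on it,
    found by fixed-point iteration of ``x' = landmark - d(x')``.
    """
    shape = array.shape
    disp = _elastic_field(shape, seed, control_spacing, max_disp)
    base = np.stack(np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij"))
    coords = (base + disp).reshape(len(shape), -1)
    out = ndimage.map_coordinates(array.astype(float), coords, order=order, mode="nearest")
    out = out.reshape(shape)
    if landmark is None:
        return out
    lm = np.asarray(landmark, dtype=float)
    x = lm.copy()
    for _ in range(20):
        d = np.array(
            [
                ndimage.map_coordinates(disp[a], x[:, None], order=1, mode="nearest")[0]
                for a in range(len(shape))
            ]
        )
        x_new = lm - d
        if np.max(np.abs(x_new - x)) < 1e-6:
            x = x_new
            break
        x = x_new
    return out, x


def augment(image: np.ndarray, targets: dict | None, ops, seed: int):
    """Apply a seeded random combination of {rotate, flip, elastic}.

    ``targets`` may hold ``"heatmap"`` (warped linearly), ``"labels"``
    (nearest-neighbour) and ``"landmark"`` (a voxel-index vector transformed
    consistently with the grids).  Returns ``(image, targets)``; an empty op
    set is the identity.
    """
    ops = set(ops)
    unknown = ops - {"rotate", "flip", "elastic"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    targets = dict(targets or {})
    rng = np.random.default_rng(seed)
    angle = float(rng.uniform(-15.0, 15.0))
    do_flip = [bool(rng.random() < 0.5), bool(rng.random() < 0.5)]
    elastic_seed = int(rng.integers(2**31))

    image = np.asarray(image, dtype=float).copy()
    lm = targets.get("landmark")
    lm = None if lm is None else np.asarray(lm, dtype=float).copy()
    grids = {k: np.asarray(v, dtype=float).copy() for k, v in targets.items() if k != "landmark"}

    def grid_order(key):
        return 0 if key == "labels" else 1

    if "flip" in ops:
        for axis in (0, 1):
            if do_flip[axis]:
                image = np.flip(image, axis=axis).copy()
                for k in grids:
                    grids[k] = np.flip(grids[k], axis=axis).copy()
                if lm is not None:
                    lm[axis] = (image.shape[axis] - 1) - lm[axis]
    if "rotate" in ops:
        if lm is not None:
            image, lm = rotate_inplane(image, angle, landmark=lm)
        else:
            image = rotate_inplane(image, angle)
        for k in grids:
            grids[k] = rotate_inplane(grids[k], angle, order=grid_order(k))
    if "elastic" in ops:
        if lm is not None:
            image, lm = elastic(image, elastic_seed, landmark=lm)
        else:
            image = elastic(image, elastic_seed)
        for k in grids:
            grids[k] = elastic(grids[k], elastic_seed, order=grid_order(k))

    out_targets = grids
    if lm is not None:
        out_targets["landmark"] = lm
    if "labels" in out_targets:
        out_targets["labels"] = np.rint(out_targets["labels"]).astype(int)
    return image, out_targets
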