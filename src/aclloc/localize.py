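"""From trained models to physical rupture coordinates.

The cascade: segmentation scores -> ROI around the footprints -> crop (and,
for the 2D route, 0.25 mm in-plane resampling) -> localization network ->
decoding back to scanner physical mm.  Decoding of the 3D heatmap thresholds
at probability 0.5 and takes the centroid of the surviving region; if no
voxel reaches the threshold the global maximum is used and flagged, so
failure statistics stay honest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from aclloc.volio import Geometry, Volume, crop_patch, resample_in_plane

__all__ = [
    "RoiBox",
    "LocalizationResult",
    "SegmentationFailure",
    "roi_from_segmentation",
    "fixed_roi_box",
    "decode_heatmap",
    "decode_2d",
    "localize_case",
    "PipelineConfig",
]

FOOTPRINT_CLASSES = {1: "femoral", 2: "tibial"}
FOREGROUND_CLASSES = (1, 2, 3)  # footprints + ligament


class SegmentationFailure(RuntimeError):
    """An expected segmentation class is empty; the case cannot be localized."""


@dataclass(frozen=True)
class RoiBox:
    """Inclusive voxel bounds per axis, plus the mm margin that produced them."""

    bounds: np.ndarray  # (3, 2) int
    margin_mm: float = 0.0

    def __post_init__(self):
        b = np.asarray(self.bounds, dtype=int)
        object.__setattr__(self, "bounds", b)
        if b.shape != (3, 2) or np.any(b[:, 0] > b[:, 1]):
            raise ValueError("bounds must be 3 ordered inclusive pairs")


@dataclass(frozen=True)
class LocalizationResult:
    point: np.ndarray  # physical mm
    method: str  # "heatmap3d" | "slice2d"
    fallback_used: bool = False
    low_confidence: bool = False

    def __post_init__(self):
        p = np.asarray(self.point, dtype=float)
        object.__setattr__(self, "point", p)
        if p.shape != (3,) or not np.all(np.isfinite(p)):
            raise ValueError("point must be a finite 3-vector")
        if self.method not in ("heatmap3d", "slice2d"):
            raise ValueError(f"unknown method {self.method!r}")


def roi_from_segmentation(
    seg_scores: np.ndarray,
    geometry: Geometry,
    margin_mm: float = 6.0,
    expected_length_mm: float = 38.0,
):
    """ROI box and footprint centroids from per-voxel class scores.

    The box is the bounding box of the foreground classes (both footprints
    and the ligament) dilated by ``margin_mm`` and clipped to the grid.
    Centroids come from one connected component per footprint class: the
    pair of components (femoral, tibial) whose sizes are largest and whose
    separation best matches the ligament's nominal length — stray
    false-positive blobs sit at implausible distances and are rejected.
    Raises :class:`SegmentationFailure` if a footprint class is empty.
    """
    seg_scores = np.asarray(seg_scores)
    if seg_scores.ndim != 4:
        raise ValueError("seg_scores must be (n_classes, nx, ny, nz)")
    labels = np.argmax(seg_scores, axis=0)
    shape = np.array(labels.shape)

    candidates = {}
    for cls, name in FOOTPRINT_CLASSES.items():
        mask = labels == cls
        if not mask.any():
            raise SegmentationFailure(f"empty {name} footprint class in segmentation")
        comp, n_comp = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, comp, index=np.arange(1, n_comp + 1))
        cents = ndimage.center_of_mass(mask, comp, index=np.arange(1, n_comp + 1))
        candidates[name] = [
            (float(s), geometry.voxel_to_physical(c)) for s, c in zip(sizes, cents)
        ]

    best, best_score = None, -np.inf
    for sf, cf in candidates["femoral"]:
        for st_, ct in candidates["tibial"]:
            d = np.linalg.norm(cf - ct)
            score = np.log(sf) + np.log(st_) - ((d - expected_length_mm) / 6.0) ** 2
            if score > best_score:
                best_score, best = score, (cf, ct)
    centroids = {"femoral": best[0], "tibial": best[1]}

    fg = np.argwhere(np.isin(labels, FOREGROUND_CLASSES))
    lo, hi = fg.min(axis=0), fg.max(axis=0)
    dil = np.ceil(margin_mm / geometry.spacing).astype(int)
    bounds = np.stack([np.maximum(lo - dil, 0), np.minimum(hi + dil, shape - 1)], axis=1)
    return RoiBox(bounds=bounds, margin_mm=margin_mm), centroids


def fixed_roi_box(geometry: Geometry, grid_shape, femoral_mm, tibial_mm, box_shape) -> RoiBox:
    """A fixed-size voxel box centered between the footprint centroids.

    Fixed shape keeps the crop compatible with a network's input contract;
    the box is shifted (never shrunk) to stay inside the grid, so
    ``box_shape`` must fit within ``grid_shape``.
    """
    grid_shape = np.asarray(grid_shape)
    box_shape = np.asarray(box_shape)
    if np.any(box_shape > grid_shape):
        raise ValueError(f"box {box_shape} larger than grid {grid_shape}")
    mid = (np.asarray(femoral_mm, dtype=float) + np.asarray(tibial_mm, dtype=float)) / 2.0
    center = geometry.physical_to_voxel(mid)
    lo = np.rint(center - box_shape / 2.0).astype(int)
    lo = np.clip(lo, 0, grid_shape - box_shape)
    return RoiBox(bounds=np.stack([lo, lo + box_shape - 1], axis=1))


def decode_heatmap(
    prob: np.ndarray,
    geometry: Geometry,
    threshold: float = 0.5,
    centroid: str = "weighted",
) -> LocalizationResult:
    """Centroid of the super-threshold region, in physical mm.

    ``centroid="weighted"`` weights voxel positions by their probability;
    ``"binary"`` averages them unweighted.  If no voxel reaches the
    threshold, the global maximum (first in scan order on ties) is returned
    with ``fallback_used=True``.
    """
    prob = np.asarray(prob, dtype=float)
    if prob.ndim == 4 and prob.shape[0] == 1:
        prob = prob[0]
    if prob.min() < -1e-9 or prob.max() > 1 + 1e-9:
        raise ValueError("probabilities must lie in [0, 1]")
    if centroid not in ("weighted", "binary"):
        raise ValueError("centroid must be 'weighted' or 'binary'")
    mask = prob >= threshold
    if not mask.any():
        idx = np.unravel_index(int(np.argmax(prob)), prob.shape)
        return LocalizationResult(
            point=geometry.voxel_to_physical(np.array(idx, dtype=float)),
            method="heatmap3d",
            fallback_used=True,
        )
    idx = np.argwhere(mask).astype(float)
    if centroid == "weighted":
        w = prob[mask]
        center_idx = (idx * w[:, None]).sum(axis=0) / w.sum()
    else:
        center_idx = idx.mean(axis=0)
    return LocalizationResult(
        point=geometry.voxel_to_physical(center_idx), method="heatmap3d", fallback_used=False
    )


def decode_2d(slice_scores: np.ndarray, box_center, roi_geometry: Geometry) -> LocalizationResult:
    """Slice argmax + box center -> physical mm via the ROI geometry.

    The ROI geometry already encodes any cropping/resampling, so the decoded
    point is in scanner physical coordinates.  Ties take the lowest slice
    index; a perfectly uniform score vector is flagged low-confidence.
    """
    scores = np.asarray(slice_scores, dtype=float)
    if scores.ndim != 1 or np.any(scores < -1e-9) or abs(scores.sum() - 1.0) > 1e-6:
        raise ValueError("slice_scores must be a probability vector")
    z = int(np.argmax(scores))
    low_conf = bool(np.allclose(scores, scores[0]))
    center = np.asarray(box_center, dtype=float)
    point = roi_geometry.voxel_to_physical(np.array([center[0], center[1], float(z)]))
    return LocalizationResult(
        point=point, method="slice2d", fallback_used=False, low_confidence=low_conf
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Knobs of the inference cascade."""

    mode: str = "heatmap3d"
    roi_shape: tuple = (48, 48, 16)  # fixed crop fed to the heatmap net
    margin_mm: float = 6.0
    threshold: float = 0.5
    centroid: str = "weighted"
    inplane_mm: float = 0.25  # 2D route resampling
    slice_image: int = 256
    n_slices: int = 6
    manual_axis: tuple | None = None  # (femoral mm, tibial mm) override


def _pad_crop_inplane(volume: Volume, size: int) -> Volume:
    """Center pad (with edge background) or crop the two in-plane axes to ``size``."""
    data = volume.data
    origin_shift = np.zeros(3)
    for ax in (0, 1):
        n = data.shape[ax]
        if n > size:
            start = (n - size) // 2
            sl = [slice(None)] * 3
            sl[ax] = slice(start, start + size)
            data = data[tuple(sl)]
            origin_shift[ax] += start
        elif n < size:
            before = (size - n) // 2
            after = size - n - before
            pads = [(0, 0)] * 3
            pads[ax] = (before, after)
            data = np.pad(data, pads, mode="constant")
            origin_shift[ax] -= before
    geom = volume.geometry
    new_origin = geom.voxel_to_physical(origin_shift)
    return Volume(
        data=data,
        geometry=Geometry(spacing=geom.spacing, origin=new_origin, orientation=geom.orientation),
    )


def _slice_window(volume: Volume, n_slices: int) -> Volume:
    nk = volume.data.shape[2]
    if nk < n_slices:
        raise ValueError(f"ROI has {nk} slices; {n_slices} required")
    k0 = int(np.clip(round((nk - n_slices) / 2), 0, nk - n_slices))
    return crop_patch(
        volume,
        [(0, volume.data.shape[0] - 1), (0, volume.data.shape[1] - 1), (k0, k0 + n_slices - 1)],
    )


def localize_case(
    volume: Volume,
    seg_model,
    loc_model,
    config: PipelineConfig = PipelineConfig(),
):
    """Run the full cascade on one volume.

    Returns ``(LocalizationResult, footprint centroids dict)``; the result is
    in the original scanner physical frame.  Segmentation failures propagate
    as :class:`SegmentationFailure`.
    """
    if config.manual_axis is not None:
        fem, tib = (np.asarray(v, dtype=float) for v in config.manual_axis)
        centroids = {"femoral": fem, "tibial": tib}
    else:
        seg = seg_model.forward(volume.data)
        _, centroids = roi_from_segmentation(seg, volume.geometry, config.margin_mm)

    box = fixed_roi_box(
        volume.geometry,
        volume.data.shape,
        centroids["femoral"],
        centroids["tibial"],
        config.roi_shape,
    )
    roi = crop_patch(volume, box.bounds)

    if config.mode == "heatmap3d":
        prob = loc_model.forward(roi.data)
        result = decode_heatmap(prob, roi.geometry, config.threshold, config.centroid)
    elif config.mode == "slice2d":
        slice_model, det_model = loc_model
        fine = resample_in_plane(roi, (config.inplane_mm, config.inplane_mm))
        fine = _pad_crop_inplane(fine, config.slice_image)
        stack = _slice_window(fine, config.n_slices)
        # slice axis is the network's first dimension
        scores = slice_model.forward(stack.data.transpose(2, 0, 1))
        z = int(np.argmax(scores))
        raw = det_model.forward(stack.data[:, :, z])
        center, _ = det_model.decode(raw, stack.data[:, :, z].shape)
        result = decode_2d(scores, center, stack.geometry)
    else:
        raise ValueError(f"unknown mode {config.mode!r}")
    return result, centroids
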