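"""End-to-end orchestration: training datasets, oracle references, the demo
experiment, and the staged pipeline behind the CLI.

Training mirrors the cascade: the segmentation net sees whole (z-scored)
volumes against one-hot footprint/ligament targets; the heatmap net sees
fixed-size ROI crops — centered between the *reference* footprint centroids,
exactly as the original protocol trained its second stage on patches cropped
around the manually labeled footprints — against Gaussian heatmap targets.
At inference the centroids come from the trained segmentation instead, so
the pipeline stays fully automated.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from aclloc import evaluate as ev
from aclloc import nets
from aclloc.classify import AclAxis, classify_case
from aclloc.localize import (
    PipelineConfig,
    decode_heatmap,
    fixed_roi_box,
    localize_case,
    roi_from_segmentation,
)
from aclloc.phantom import PhantomSpec, make_dataset
from aclloc.targets import gaussian_heatmap, seg_target
from aclloc.volio import crop_patch

__all__ = [
    "zscore",
    "oracle_localize",
    "oracle_fit_predict",
    "seg_training_set",
    "heatmap_training_set",
    "train_seg",
    "train_heatmap",
    "DemoConfig",
    "run_demo",
    "save_overlay",
]

DEFAULT_SIGMA_MM = 3.0
DEFAULT_SUPPRESSION_MM = 2.0


def zscore(x: np.ndarray) -> np.ndarray:
    """Per-volume intensity standardization applied before every network."""
    x = np.asarray(x, dtype=np.float32)
    return (x - x.mean()) / (x.std() + 1e-8)


def _gt_roi(case, roi_shape):
    """Fixed-size ROI crop centered between the reference footprint centers."""
    box = fixed_roi_box(
        case.volume.geometry,
        case.volume.data.shape,
        case.gt.femoral_center,
        case.gt.tibial_center,
        roi_shape,
    )
    return crop_patch(case.volume, box.bounds)


def oracle_localize(case, roi_shape=(48, 48, 16), sigma: float = DEFAULT_SIGMA_MM):
    """Run decoding + geometry with ground-truth segmentation and heatmap.

    Isolates the decoding/coordinate machinery from network quality: the
    segmentation scores are the one-hot labels and the heatmap is the exact
    training target.
    """
    seg = seg_target(case.labels)
    _, centroids = roi_from_segmentation(seg, case.labels.geometry)
    box = fixed_roi_box(
        case.volume.geometry,
        case.volume.data.shape,
        centroids["femoral"],
        centroids["tibial"],
        np.minimum(roi_shape, case.volume.data.shape),  # no net involved; clip freely
    )
    roi = crop_patch(case.volume, box.bounds)
    target = gaussian_heatmap(
        roi.geometry, roi.data.shape, case.gt.rupture_point, sigma=sigma
    )
    prob = target.values.copy()
    prob[target.invalid_mask] = 0.0
    return decode_heatmap(prob, roi.geometry), centroids


def oracle_fit_predict(train_cases, test_cases):
    """``fit_predict`` plug-in for cross_validate using the oracle pipeline."""
    return [oracle_localize(c)[0].point for c in test_cases]


def seg_training_set(cases):
    return [(zscore(c.volume.data), seg_target(c.labels)) for c in cases]


def heatmap_training_set(
    cases,
    roi_shape=(48, 48, 16),
    sigma: float = DEFAULT_SIGMA_MM,
    suppression_band: float = DEFAULT_SUPPRESSION_MM,
):
    out = []
    for c in cases:
        roi = _gt_roi(c, roi_shape)
        target = gaussian_heatmap(
            roi.geometry,
            roi.data.shape,
            c.gt.rupture_point,
            sigma=sigma,
            suppression_band=suppression_band,
        )
        out.append((zscore(roi.data), target))
    return out


def train_seg(cases, net_config=None, train_config=None, seed: int = 0):
    net_config = net_config or nets.NetConfig(
        depth=2, base_channels=4, n_outputs=4, input_shape=cases[0].volume.data.shape
    )
    train_config = train_config or nets.TrainConfig(epochs=20, lr=0.05, seed=seed)
    model = nets.build_seg_net(net_config, seed=seed)
    return nets.train(model, seg_training_set(cases), train_config)


def train_heatmap(
    cases,
    net_config=None,
    train_config=None,
    seed: int = 0,
    roi_shape=(48, 48, 16),
    sigma: float = DEFAULT_SIGMA_MM,
):
    net_config = net_config or nets.NetConfig(depth=3, base_channels=8, input_shape=roi_shape)
    train_config = train_config or nets.TrainConfig(epochs=25, lr=0.05, seed=seed)
    model = nets.build_heatmap_net(net_config, seed=seed)
    dataset = heatmap_training_set(cases, roi_shape=roi_shape, sigma=sigma)
    return nets.train(model, dataset, train_config)


class _ZScoreSeg:
    """Adapter: localize_case feeds raw volumes; networks expect z-scored input."""

    def __init__(self, model):
        self.model = model

    def forward(self, x):
        return self.model.forward(zscore(x))


def predict_case(case, seg_model, heatmap_model, config: PipelineConfig = PipelineConfig()):
    """Localize + classify one case with trained models; returns (result, side)."""
    result, centroids = localize_case(
        case.volume, _ZScoreSeg(seg_model), _ZScoreSeg(heatmap_model), config
    )
    axis = AclAxis(centroids["femoral"], centroids["tibial"])
    side = classify_case(result, axis)
    return result, side


@dataclass
class DemoConfig:
    """The bundled desk-scale experiment: 60 training / 20 held-out phantoms."""

    n_train: int = 60
    n_test: int = 20
    spec: PhantomSpec = field(default_factory=PhantomSpec)
    roi_shape: tuple = (48, 48, 16)
    sigma_mm: float = DEFAULT_SIGMA_MM
    seg_epochs: int = 20
    heatmap_epochs: int = 25
    lr: float = 0.05
    threshold: float = 0.5
    failure_mm: float = ev.FAILURE_THRESHOLD_MM
    overlays: int = 0

    def digest(self) -> str:
        payload = json.dumps(
            {k: str(v) for k, v in sorted(self.__dict__.items())}, sort_keys=True
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_demo(seed: int, out_dir=None, config: DemoConfig | None = None) -> dict:
    """Generate phantoms, train both networks, localize and evaluate.

    Returns the metrics dict (and writes ``metrics.json``, a results TSV and
    optional QC overlays under ``out_dir``).  Deterministic per (config, seed).
    """
    config = config or DemoConfig()
    t0 = time.time()
    log = []

    def stage(name, fn):
        t = time.time()
        result = fn()
        log.append({"stage": name, "seconds": round(time.time() - t, 2)})
        return result

    cases = stage(
        "phantom-gen",
        lambda: make_dataset(config.n_train + config.n_test, config.spec, seed=seed),
    )
    train_cases, test_cases = cases[: config.n_train], cases[config.n_train :]

    seg_model, seg_hist = stage(
        "train-seg",
        lambda: train_seg(
            train_cases,
            train_config=nets.TrainConfig(epochs=config.seg_epochs, lr=0.05, seed=seed),
            seed=seed,
        ),
    )
    hm_config = nets.NetConfig(depth=3, base_channels=8, input_shape=config.roi_shape)
    hm_train = nets.TrainConfig(epochs=config.heatmap_epochs, lr=config.lr, seed=seed)
    heatmap_model, hm_hist = stage(
        "train-loc",
        lambda: train_heatmap(
            train_cases, hm_config, hm_train, seed=seed,
            roi_shape=config.roi_shape, sigma=config.sigma_mm,
        ),
    )

    pcfg = PipelineConfig(roi_shape=config.roi_shape, threshold=config.threshold)
    rows, errors, pred_sides, true_sides, fallbacks = [], [], [], [], 0
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)

    seg_failures = []

    def _evaluate():
        nonlocal fallbacks
        from aclloc.localize import SegmentationFailure

        for i, case in enumerate(test_cases):
            try:
                result, side = predict_case(case, seg_model, heatmap_model, pcfg)
            except SegmentationFailure as exc:
                # no silent fallback: the case is recorded and excluded
                seg_failures.append((case.case_id, str(exc)))
                continue
            err = ev.euclidean_error(result.point, case.gt.rupture_point)
            errors.append(err)
            pred_sides.append(side.value)
            true_sides.append(case.gt.side)
            fallbacks += int(result.fallback_used)
            rows.append((case.case_id, result, err, side))
            if out_dir is not None and i < config.overlays:
                save_overlay(
                    case.volume, result.point, case.gt.rupture_point,
                    out_dir / f"{case.case_id}_overlay.png",
                )

    stage("localize-classify", _evaluate)

    stats = ev.localization_stats(errors, config.failure_mm)
    cm = ev.confusion(pred_sides, true_sides)
    report = ev.class_metrics(cm)
    metrics = {
        "seed": seed,
        "config_hash": config.digest(),
        "n_train": config.n_train,
        "n_test": config.n_test,
        "mean_error_mm": stats.mean,
        "sd_error_mm": stats.sd,
        "failures": stats.failures,
        "error_rate": stats.error_rate,
        "fallbacks": fallbacks,
        "seg_failures": seg_failures,
        "overall_accuracy": report.overall_accuracy,
        "confusion": cm.counts.tolist(),
        "per_class": report.per_class,
        "final_seg_loss": round(seg_hist[-1], 9),
        "final_heatmap_loss": round(hm_hist[-1], 9),
    }
    if out_dir is not None:
        # metrics.json is byte-identical across reruns of the same (config, seed);
        # wall times go to the log instead
        (out_dir / "metrics.json").write_text(json.dumps(metrics, indent=2, sort_keys=True))
        with open(out_dir / "run.log", "w") as fh:
            for entry in log:
                fh.write(f"{entry['stage']}\t{entry['seconds']}s\n")
            fh.write(f"total\t{round(time.time() - t0, 2)}s\n")
        with open(out_dir / "results.tsv", "w") as fh:
            fh.write("case_id\tx_mm\ty_mm\tz_mm\terror_mm\tside\tmethod\tfallback_used\n")
            for cid, result, err, side in rows:
                x, y, z = result.point
                fh.write(
                    f"{cid}\t{x:.3f}\t{y:.3f}\t{z:.3f}\t{err:.3f}\t{side.value}"
                    f"\t{result.method}\t{result.fallback_used}\n"
                )
    metrics["stage_seconds"] = log
    return metrics


def save_overlay(volume, pred_mm, true_mm, path) -> None:
    """QC overlay: the slice through the prediction, predicted point red, truth green."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    geom = volume.geometry
    pred_idx = geom.physical_to_voxel(pred_mm)
    true_idx = geom.physical_to_voxel(true_mm)
    k = int(np.clip(round(pred_idx[2]), 0, volume.data.shape[2] - 1))
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.imshow(volume.data[:, :, k].T, cmap="gray", origin="lower")
    ax.plot(pred_idx[0], pred_idx[1], "o", mfc="none", mec="red", ms=12, mew=2)
    ax.plot(true_idx[0], true_idx[1], "o", mfc="none", mec="green", ms=12, mew=2)
    ax.set_title(f"slice {k}: pred (red) vs true (green)")
    ax.axis("off")
    fig.savefig(path, dpi=100, bbox_inches="tight")
    plt.close(fig)
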