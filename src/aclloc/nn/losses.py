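"""Loss functions returning (value, gradient-w.r.t.-prediction) pairs.

The combined Dice + focal loss is computed over *valid* voxels only: the
false-positive suppression band around a heatmap target is flagged invalid
and contributes exactly nothing to either term or its gradient.
"""

from __future__ import annotations

import numpy as np

_PCLIP = 1e-6


def dice_focal_loss_grad(
    pred: np.ndarray,
    target: np.ndarray,
    invalid_mask: np.ndarray | None = None,
    *,
    dice_weight: float = 1.0,
    focal_weight: float = 1.0,
    focal_gamma: float = 2.0,
    focal_alpha: float = 0.25,
    eps: float = 1e-5,
):
    """Weighted soft-Dice + focal loss over valid voxels.

    ``pred`` holds probabilities in [0, 1] with the same shape as ``target``;
    multi-channel inputs are treated per channel (Dice averaged over
    channels, focal averaged over all valid entries).  Returns
    ``(loss, d loss / d pred)``; the gradient is identically zero on invalid
    voxels.
    """
    pred = np.asarray(pred, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs target {target.shape}")
    if pred.ndim == 3:
        pred, target = pred[None], target[None]
        squeeze = True
    else:
        squeeze = False
    n_ch = pred.shape[0]
    if invalid_mask is None:
        valid = np.ones(pred.shape[1:], dtype=bool)
    else:
        valid = ~np.asarray(invalid_mask, dtype=bool)
    vmask = np.broadcast_to(valid, pred.shape)
    n_valid = max(int(valid.sum()), 1)

    p = np.clip(pred, _PCLIP, 1.0 - _PCLIP)
    t = target
    grad = np.zeros_like(pred)
    loss = 0.0

    if dice_weight > 0:
        for c in range(n_ch):
            pc, tc = p[c][valid], t[c][valid]
            num = 2.0 * np.dot(pc, tc) + eps
            den = pc.sum() + tc.sum() + eps
            loss += dice_weight * (1.0 - num / den) / n_ch
            gd = -(2.0 * tc * den - num) / den**2
            g = np.zeros(pred.shape[1:])
            g[valid] = dice_weight * gd / n_ch
            grad[c] += g

    if focal_weight > 0:
        a, gam = focal_alpha, focal_gamma
        one_m_p = 1.0 - p
        f = -(a * t * one_m_p**gam * np.log(p) + (1 - a) * (1 - t) * p**gam * np.log(one_m_p))
        loss += focal_weight * float(f[vmask].sum()) / (n_valid * n_ch)
        if gam == 0:
            df = -(a * t / p) + (1 - a) * (1 - t) / one_m_p
        else:
            df = -(
                a * t * (-gam * one_m_p ** (gam - 1) * np.log(p) + one_m_p**gam / p)
                + (1 - a) * (1 - t) * (gam * p ** (gam - 1) * np.log(one_m_p) - p**gam / one_m_p)
            )
        df = np.where(vmask, df, 0.0)
        grad += focal_weight * df / (n_valid * n_ch)

    grad = np.where(vmask, grad, 0.0)
    if squeeze:
        grad = grad[0]
    return float(loss), grad.astype(np.float32)


def cross_entropy_grad(probs: np.ndarray, target: np.ndarray):
    """Cross entropy between a probability vector and a target distribution.

    Returns (loss, gradient w.r.t. the probabilities); the softmax Jacobian
    is applied inside the network's backward pass.
    """
    p = np.clip(np.asarray(probs, dtype=np.float64), _PCLIP, 1.0)
    t = np.asarray(target, dtype=np.float64)
    loss = -float(np.dot(t, np.log(p)))
    return loss, (-t / p).astype(np.float32)


def detector_loss_grad(raw: np.ndarray, center_px, stride: int = 8, offset_weight: float = 1.0):
    """Objectness BCE over cells + L2 on the within-cell offset at the true cell.

    ``raw`` is the detector head output (3, 1, h, w); ``center_px`` the true
    keypoint in image pixels.  Returns (loss, gradient w.r.t. raw).
    """
    obj = raw[0, 0].astype(np.float64)
    h, w = obj.shape
    center = np.asarray(center_px, dtype=float)
    cell = np.clip((center // stride).astype(int), 0, [h - 1, w - 1])
    t_off = center / stride - cell

    tmap = np.zeros((h, w))
    tmap[cell[0], cell[1]] = 1.0
    p = 1.0 / (1.0 + np.exp(-obj))
    pc = np.clip(p, _PCLIP, 1 - _PCLIP)
    bce = -(tmap * np.log(pc) + (1 - tmap) * np.log(1 - pc)).mean()
    g_obj = (p - tmap) / (h * w)

    o_raw = raw[1:3, 0, cell[0], cell[1]].astype(np.float64)
    s = 1.0 / (1.0 + np.exp(-o_raw))
    l2 = float(np.sum((s - t_off) ** 2))
    g_off = 2.0 * (s - t_off) * s * (1.0 - s)

    grad = np.zeros_like(raw, dtype=np.float32)
    grad[0, 0] = g_obj
    grad[1:3, 0, cell[0], cell[1]] = offset_weight * g_off
    return float(bce + offset_weight * l2), grad
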