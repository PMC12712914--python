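"""Segmentation (cross-entropy + soft Dice) and GAN (LSGAN/L1) objectives.

Each function returns ``(loss, grad)`` where ``grad`` is the derivative with
respect to the first argument.
"""

from __future__ import annotations

import numpy as np

_EPS = 1e-7


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def _one_hot(target: np.ndarray, n_classes: int) -> np.ndarray:
    # target: (N, H, W) int -> (N, C, H, W)
    oh = np.zeros((target.shape[0], n_classes) + target.shape[1:], dtype=np.float64)
    np.put_along_axis(oh, target[:, None], 1.0, axis=1)
    return oh


def _dice_terms(probs: np.ndarray, onehot: np.ndarray):
    """Soft Dice per class over the whole batch; returns (loss, dL/dprobs)."""
    C = probs.shape[1]
    num = 2.0 * (probs * onehot).sum(axis=(0, 2, 3))
    den = probs.sum(axis=(0, 2, 3)) + onehot.sum(axis=(0, 2, 3))
    dice = (num + _EPS) / (den + _EPS)
    loss = 1.0 - dice.mean()
    # d dice_k / d p_k(i) = (2 t_k(i) (den+eps) - (num+eps)) / (den+eps)^2
    dden = (den + _EPS)
    dprobs = -(2.0 * onehot * dden[None, :, None, None]
               - (num + _EPS)[None, :, None, None]) / (dden ** 2)[None, :, None, None] / C
    return loss, dprobs


def seg_loss(logits: np.ndarray, target: np.ndarray, w_ce: float, w_dice: float):
    """Combined CE + soft-Dice on logits. target: (N,H,W) ints.

    Returns (scalar loss, dloss/dlogits).
    """
    n_classes = logits.shape[1]
    probs = softmax(logits)
    onehot = _one_hot(target, n_classes)
    npix = target.size
    ce = -(onehot * np.log(probs + _EPS)).sum() / npix
    dlogits = w_ce * (probs - onehot) / npix
    dice_l, dprobs = _dice_terms(probs, onehot)
    # chain soft-Dice grad through softmax: dz_c = p_c (g_c - sum_k g_k p_k)
    g = dprobs
    inner = (g * probs).sum(axis=1, keepdims=True)
    dlogits += w_dice * probs * (g - inner)
    return w_ce * ce + w_dice * dice_l, dlogits


def probs_seg_loss(probs: np.ndarray, target: np.ndarray, w_ce: float, w_dice: float) -> float:
    """Combined loss evaluated on already-normalised posteriors (no gradient)."""
    n_classes = probs.shape[1]
    onehot = _one_hot(target, n_classes)
    ce = -(onehot * np.log(probs + _EPS)).sum() / target.size
    dice_l, _ = _dice_terms(probs, onehot)
    return w_ce * ce + w_dice * dice_l


def mse_loss(pred: np.ndarray, target) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float((diff ** 2).mean()), 2.0 * diff / diff.size


def l1_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    diff = pred - target
    return float(np.abs(diff).mean()), np.sign(diff) / diff.size
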