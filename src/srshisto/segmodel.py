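"""Semantic segmentation of the eight lung-tissue classes.

Preprocessing follows the resize-first convention: source patches are resized
to ``resize_edge`` and then cropped to ``train_crop`` (randomly during
training, centered at inference), which preserves whole-tissue context before
cropping. Training minimises a combined cross-entropy + soft-Dice objective
with AdamW and polynomial learning-rate decay; augmentation applies flips and
±15° rotations jointly to image and labels, and brightness jitter plus
Gaussian noise to the image only.

Two backbone scales share one contract: ``toy`` is a small full-resolution
conv net for CPU-scale experiments; ``tiny`` is a hierarchical four-stage
encoder-decoder with (2, 2, 6, 2) residual blocks per stage.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage import transform

from ._nn import Adam, UNet, probs_seg_loss, seg_loss, softmax, tiny_seg_net, toy_seg_net
from .classes import N_CLASSES
from .segmetrics import confusion, class_metrics


@dataclass
class SegConfig:
    n_classes: int = N_CLASSES
    train_crop: int = 512
    resize_edge: int = 600
    source_patch: int = 2048
    backbone_scale: str = "toy"           # "toy" | "tiny"
    backbone_depths: tuple = (2, 2, 6, 2)
    toy_width: int = 16
    loss_weights: tuple = (1.0, 1.0)      # (w_ce, w_dice)
    lr: float = 1e-4
    weight_decay: float = 0.01
    poly_power: float = 0.9
    epochs: int = 30
    batch: int = 4
    seed: int = 0
    val_fraction: float = 0.25
    augment: bool = True
    #: channel normalisation applied after scaling; identity by default
    normalize_mean: tuple = (0.0, 0.0, 0.0)
    normalize_std: tuple = (1.0, 1.0, 1.0)
    input_scale: float = 128.0

    def __post_init__(self):
        if not (self.train_crop <= self.resize_edge <= self.source_patch):
            raise ValueError("require train_crop <= resize_edge <= source_patch")
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if self.backbone_scale not in ("toy", "tiny"):
            raise ValueError("backbone_scale must be 'toy' or 'tiny'")


@dataclass
class SegModelState:
    """Architecture + learned parameters + per-epoch training log."""

    net: object
    cfg: SegConfig
    loss_curve: list = field(default_factory=list)
    val_miou: float = float("nan")


def _build_net(cfg: SegConfig, rng: np.random.Generator):
    if cfg.backbone_scale == "toy":
        return toy_seg_net(3, cfg.n_classes, width=cfg.toy_width, rng=rng)
    return tiny_seg_net(3, cfg.n_classes, rng=rng)


def _resize_pair(image, labels, edge):
    img = transform.resize(image, (edge, edge), order=1, mode="reflect",
                           anti_aliasing=True, preserve_range=True)
    lab = transform.resize(labels.astype(np.float64), (edge, edge), order=0,
                           mode="edge", anti_aliasing=False,
                           preserve_range=True).astype(np.int64)
    return img, lab


def preprocess_patch(image: np.ndarray, labels: np.ndarray, cfg: SegConfig,
                     train: bool = False,
                     rng: np.random.Generator | None = None):
    """Resize-first then crop; joint geometric and image-only photometric
    augmentation when ``train`` is set. Smaller inputs are zero-padded to
    ``source_patch`` (padding labelled background)."""
    image = np.asarray(image, dtype=np.float64)
    labels = np.asarray(labels)
    if image.shape[:2] != labels.shape:
        raise ValueError("image and labels must share spatial shape")
    rng = rng or np.random.default_rng(cfg.seed)
    sp = cfg.source_patch
    h, w = labels.shape
    if h < sp or w < sp:
        ph, pw = max(0, sp - h), max(0, sp - w)
        image = np.pad(image, ((0, ph), (0, pw), (0, 0)))
        labels = np.pad(labels, ((0, ph), (0, pw)))
    elif h > sp or w > sp:
        image, labels = image[:sp, :sp], labels[:sp, :sp]
    if image.shape[0] != cfg.resize_edge:
        image, labels = _resize_pair(image, labels, cfg.resize_edge)
    crop = cfg.train_crop
    margin = cfg.resize_edge - crop
    if train:
        y0 = int(rng.integers(margin + 1))
        x0 = int(rng.integers(margin + 1))
    else:
        y0 = x0 = margin // 2
    image = image[y0:y0 + crop, x0:x0 + crop]
    labels = labels[y0:y0 + crop, x0:x0 + crop]
    if train and cfg.augment:
        if rng.random() < 0.5:
            image, labels = image[::-1], labels[::-1]
        if rng.random() < 0.5:
            image, labels = image[:, ::-1], labels[:, ::-1]
        angle = rng.uniform(-15.0, 15.0)
        image = transform.rotate(image, angle, order=1, mode="constant",
                                 cval=0.0, preserve_range=True)
        labels = transform.rotate(labels.astype(np.float64), angle, order=0,
                                  mode="constant", cval=0.0,
                                  preserve_range=True).astype(np.int64)
        image = image * rng.uniform(0.9, 1.1)
        image = image + rng.standard_normal(image.shape) * 0.02 * cfg.input_scale
    return np.ascontiguousarray(image), np.ascontiguousarray(labels)


def combined_loss(probs: np.ndarray, target: np.ndarray,
                  weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """w_ce * CE + w_dice * (1 - mean soft Dice) on normalised posteriors.

    ``probs``: (H, W, C); ``target``: (H, W) integer labels. Zero iff the
    prediction is exactly the one-hot target.
    """
    probs = np.asarray(probs, dtype=np.float64)
    target = np.asarray(target)
    if probs.shape[:2] != target.shape:
        raise ValueError("probs and target must share spatial shape")
    sums = probs.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-5 or probs.min() < 0:
        raise ValueError("probabilities must be normalised per pixel")
    p = probs.transpose(2, 0, 1)[None]
    return float(probs_seg_loss(p, target[None], weights[0], weights[1]))


def _normalize(img: np.ndarray, cfg: SegConfig) -> np.ndarray:
    x = img / cfg.input_scale
    mean = np.asarray(cfg.normalize_mean)[:, None, None]
    std = np.asarray(cfg.normalize_std)[:, None, None]
    return (x.transpose(2, 0, 1) - mean) / std


def ratio_split(n: int, val_fraction: float, seed: int):
    """Shuffled train/validation index split at a fixed ratio."""
    order = np.random.default_rng(seed).permutation(n)
    n_val = max(1, int(round(val_fraction * n)))
    return order[n_val:], order[:n_val]


def kfold_splits(n: int, k: int, seed: int):
    """k shuffled (train_idx, val_idx) folds."""
    order = np.random.default_rng(seed).permutation(n)
    folds = np.array_split(order, k)
    return [(np.concatenate([f for j, f in enumerate(folds) if j != i]), folds[i])
            for i in range(k)]


def train(dataset: list[tuple[np.ndarray, np.ndarray]], cfg: SegConfig,
          split: tuple | None = None) -> SegModelState:
    """Train on (image HWC, labels HW) pairs; returns state with loss curve
    and validation mIoU. ``split`` overrides the default ratio split."""
    if len(dataset) < 2:
        raise ValueError("need at least 2 samples")
    rng = np.random.default_rng(cfg.seed)
    net = _build_net(cfg, np.random.default_rng(cfg.seed + 1))
    opt = Adam(net.params(), lr=cfg.lr, decoupled_wd=cfg.weight_decay)
    if split is None:
        train_idx, val_idx = ratio_split(len(dataset), cfg.val_fraction, cfg.seed)
    else:
        train_idx, val_idx = (np.asarray(s) for s in split)
    w_ce, w_dice = cfg.loss_weights
    losses = []
    total_steps = max(1, cfg.epochs * -(-len(train_idx) // cfg.batch))
    step = 0
    for _epoch in range(cfg.epochs):
        rng.shuffle(train_idx)
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(train_idx), cfg.batch):
            idx = train_idx[i:i + cfg.batch]
            imgs, tgts = [], []
            for j in idx:
                img, lab = preprocess_patch(dataset[j][0], dataset[j][1], cfg,
                                            train=True, rng=rng)
                imgs.append(_normalize(img, cfg))
                tgts.append(lab)
            x = np.stack(imgs)
            t = np.stack(tgts)
            opt.lr = cfg.lr * (1.0 - step / total_steps) ** cfg.poly_power
            logits, tape = net.forward(x)
            loss, dlogits = seg_loss(logits, t, w_ce, w_dice)
            opt.zero_grad()
            net.backward(dlogits, tape)
            opt.step()
            epoch_loss += loss
            n_batches += 1
            step += 1
        losses.append(epoch_loss / max(n_batches, 1))
    state = SegModelState(net=net, cfg=cfg, loss_curve=losses)
    if len(val_idx):
        ious = []
        for j in val_idx:
            img, lab = preprocess_patch(dataset[j][0], dataset[j][1], cfg, train=False)
            _, pred = predict(state, img)
            ious.append(class_metrics(confusion(pred, lab, cfg.n_classes)).miou)
        state.val_miou = float(np.mean(ious))
    return state


def predict(state: SegModelState, image: np.ndarray):
    """Posterior and arg-max labels at the input resolution.

    The image is resized to the inference size, classified, and posteriors
    are resized back (bilinear, renormalised); arg-max breaks ties toward
    the lowest class id.
    """
    if state.net is None:
        raise ValueError("corrupt state: no network")
    cfg = state.cfg
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected an (H, W, C) image")
    h, w = image.shape[:2]
    size = cfg.train_crop
    resized = image if (h, w) == (size, size) else transform.resize(
        image, (size, size), order=1, mode="reflect", anti_aliasing=True,
        preserve_range=True)
    x = _normalize(resized, cfg)[None]
    if isinstance(state.net, UNet):
        down = 2 ** state.net.L
        ph, pw = (-size) % down, (-size) % down
        if ph or pw:
            x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
    logits, _ = state.net.forward(x)
    probs = softmax(logits)[0, :, :size, :size]
    if (h, w) != (size, size):
        probs = np.stack([transform.resize(p, (h, w), order=1, mode="edge",
                                           preserve_range=True) for p in probs])
        probs = np.clip(probs, 1e-12, None)
        probs /= probs.sum(axis=0, keepdims=True)
    labels = probs.argmax(axis=0)
    return probs.transpose(1, 2, 0), labels


def save_state(state: SegModelState, path: str) -> None:
    """Persist parameters + config (npz with a JSON header)."""
    params = state.net.params()
    arrays = {f"p{i}": p.value for i, p in enumerate(params)}
    cfg_json = json.dumps({k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in vars(state.cfg).items()})
    np.savez(path, _cfg=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
             _losses=np.asarray(state.loss_curve), **arrays)


def load_state(path: str) -> SegModelState:
    data = np.load(path)
    raw = json.loads(bytes(data["_cfg"]).decode())
    for key in ("backbone_depths", "loss_weights", "normalize_mean", "normalize_std"):
        raw[key] = tuple(raw[key])
    cfg = SegConfig(**raw)
    net = _build_net(cfg, np.random.default_rng(cfg.seed + 1))
    for i, p in enumerate(net.params()):
        p.value[...] = data[f"p{i}"]
    return SegModelState(net=net, cfg=cfg, loss_curve=list(data["_losses"]))
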