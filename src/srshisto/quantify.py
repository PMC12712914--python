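"""Segmentation-guided biochemical and cytological quantification.

Chemistry: per-class lipid/protein means and the L/P ratio, computed per
512-px tile over non-black pixels only (masking writes exact zeros, so
"non-black" means any molecular channel > 0). Cytology: a small U-Net
segments nuclei; connected components above a minimum size are counted with
weight 0.5 for components touching the tile border (preventing double
counting across tiles), giving cell density, mean cell area and the
nucleus-to-cytoplasm ratio.

Denominator conventions: mean cell area divides the non-black tissue area by
the weighted nucleus count; cell density divides the weighted count by the
whole class *region* area (tissue plus intra-class signal-free spaces, i.e.
"density in the alveolar space"); N/C divides nuclear by cytoplasmic
(tissue minus nuclei) area.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import measure

from ._nn import Adam, UNet, seg_loss, softmax
from .classes import DEFAULT_PX_PER_UM
from .preproc import MolecularMaps, tile as tile_raster


@dataclass
class QuantConfig:
    tile_size: int = 512
    px_per_um: float = DEFAULT_PX_PER_UM
    #: smallest component counted as a nucleus; 20 px ~ 2.4 um^2 at the
    #: default pixel scale, below any plausible nucleus.
    min_component_px: int = 20
    #: intensity floor separating signal-bearing tissue from empty/noise
    #: pixels when tissue is derived from molecular maps; set 0 for inputs
    #: masked with exact zeros and no noise. 25 a.u. sits several noise
    #: standard deviations above empty pixels yet well below the dimmest
    #: tissue signal.
    black_threshold: float = 25.0
    n_tiles_per_class: int = 1000
    seed: int = 0
    # nuclei U-Net training
    unet_widths: tuple = (8, 16, 24, 32)
    train_epochs: int = 15
    lr: float = 3e-3
    batch: int = 4
    val_fraction: float = 0.2
    input_scale: float = 128.0

    def __post_init__(self):
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")
        if self.min_component_px < 1:
            raise ValueError("min_component_px must be >= 1")


@dataclass
class ClassTileStats:
    class_id: int
    tile_index: int
    lipid_mean: float
    protein_mean: float
    lp_ratio: float
    nonblack_px: int


@dataclass
class CytologyStats:
    weighted_nuclei: float
    mean_cell_area: float  # um^2; NaN when no nuclei
    density: float         # um^-2 over the class region
    nc_ratio: float        # nuclear / cytoplasmic area; NaN when no nuclei


def mask_class(maps: MolecularMaps, labels: np.ndarray, k: int) -> MolecularMaps:
    """Zero all pixels outside class ``k`` ("black"), leaving others untouched."""
    labels = np.asarray(labels)
    if labels.shape != maps.shape:
        raise ValueError("labels and maps must share a shape")
    keep = labels == k
    return MolecularMaps(lipid=np.where(keep, maps.lipid, 0.0),
                         protein=np.where(keep, maps.protein, 0.0),
                         collagen=np.where(keep, maps.collagen, 0.0),
                         px_per_um=maps.px_per_um)


def tile_chem_stats(masked: MolecularMaps, cfg: QuantConfig,
                    class_id: int = -1) -> list[ClassTileStats]:
    """Per-tile lipid/protein means over non-black pixels; empty tiles skipped."""
    lip_tiles, _ = tile_raster(masked.lipid, cfg.tile_size)
    pro_tiles, _ = tile_raster(masked.protein, cfg.tile_size)
    thr = cfg.black_threshold
    out = []
    for idx, (lt, pt) in enumerate(zip(lip_tiles, pro_tiles)):
        nonblack = (lt > thr) | (pt > thr)
        n = int(nonblack.sum())
        if n == 0:
            continue
        lm = float(lt[nonblack].mean())
        pm = float(pt[nonblack].mean())
        lp = lm / pm if pm > 0 else float("nan")
        out.append(ClassTileStats(class_id, idx, lm, pm, lp, n))
    return out


def count_nuclei(mask: np.ndarray, cfg: QuantConfig) -> float:
    """Weighted connected-component count (8-connectivity).

    Components below ``min_component_px`` are ignored; components touching
    any raster border weigh 0.5, interior components 1.0.
    """
    mask = np.asarray(mask).astype(bool)
    lab = measure.label(mask, connectivity=2)
    if lab.max() == 0:
        return 0.0
    sizes = np.bincount(lab.ravel())
    border_ids = np.unique(np.concatenate([
        lab[0], lab[-1], lab[:, 0], lab[:, -1]]))
    on_border = np.zeros(sizes.size, dtype=bool)
    on_border[border_ids] = True
    total = 0.0
    for cid in range(1, sizes.size):
        if sizes[cid] < cfg.min_component_px:
            continue
        total += 0.5 if on_border[cid] else 1.0
    return total


def cytology_stats(nuclei: np.ndarray, tissue: np.ndarray, cfg: QuantConfig,
                   region_px: int | None = None) -> CytologyStats:
    """Cytology of one analysis unit.

    ``region_px`` is the class-region pixel count used as the density
    denominator; it defaults to the non-black tissue count.
    """
    tissue = np.asarray(tissue).astype(bool)
    nuclei = np.asarray(nuclei).astype(bool) & tissue
    t_px = int(tissue.sum())
    if t_px == 0:
        raise ValueError("zero tissue area")
    r_px = t_px if region_px is None else int(region_px)
    ppu2 = cfg.px_per_um ** 2
    weighted = count_nuclei(nuclei, cfg)
    n_px = int(nuclei.sum())
    tissue_um2 = t_px / ppu2
    region_um2 = r_px / ppu2
    if weighted > 0:
        area = tissue_um2 / weighted
        nc = n_px / (t_px - n_px) if t_px > n_px else float("nan")
    else:
        area, nc = float("nan"), float("nan")
    return CytologyStats(weighted_nuclei=weighted, mean_cell_area=area,
                         density=weighted / region_um2, nc_ratio=nc)


def _class_cytology_sums(nuclei, maps, labels, k, cfg):
    """Per-tile cytology of class ``k`` plus raw pooled sums
    (weighted count, tissue px, nuclei px, region px)."""
    masked = mask_class(maps, labels, k)
    region = (np.asarray(labels) == k)
    thr = cfg.black_threshold
    tissue = region & ((masked.lipid > thr) | (masked.protein > thr))
    nuc = np.asarray(nuclei).astype(bool) & tissue
    reg_tiles, _ = tile_raster(region, cfg.tile_size)
    tis_tiles, _ = tile_raster(tissue, cfg.tile_size)
    nuc_tiles, _ = tile_raster(nuc, cfg.tile_size)
    per_tile = []
    sums = np.zeros(4)
    for rt, tt, nt in zip(reg_tiles, tis_tiles, nuc_tiles):
        t_px = int(tt.sum())
        if t_px == 0:
            continue
        st = cytology_stats(nt, tt, cfg, region_px=int(rt.sum()))
        per_tile.append(st)
        sums += (st.weighted_nuclei, t_px, int(nt.sum()), int(rt.sum()))
    return sums, per_tile


def _cytology_from_sums(sums, cfg) -> CytologyStats:
    sum_w, sum_t, sum_n, sum_r = sums
    if sum_t == 0:
        raise ValueError("no tissue pixels")
    ppu2 = cfg.px_per_um ** 2
    return CytologyStats(
        weighted_nuclei=sum_w,
        mean_cell_area=(sum_t / ppu2) / sum_w if sum_w > 0 else float("nan"),
        density=sum_w / (sum_r / ppu2),
        nc_ratio=sum_n / (sum_t - sum_n) if sum_t > sum_n else float("nan"))


def class_cytology(nuclei: np.ndarray, maps: MolecularMaps, labels: np.ndarray,
                   k: int, cfg: QuantConfig) -> tuple[CytologyStats, list[CytologyStats]]:
    """Tile-wise cytology for class ``k`` plus an area-weighted pooled summary."""
    sums, per_tile = _class_cytology_sums(nuclei, maps, labels, k, cfg)
    if sums[1] == 0:
        raise ValueError(f"class {k} has no tissue pixels")
    return _cytology_from_sums(sums, cfg), per_tile


@dataclass
class NucleiModelState:
    """Trained four-level U-Net parameters plus its training log."""

    net: UNet
    cfg: QuantConfig
    loss_curve: list = field(default_factory=list)
    val_dice: float = float("nan")


def _augment(img: np.ndarray, tgt: np.ndarray, rng: np.random.Generator,
             scale: float):
    """Joint geometric (rot90/flip) and image-only intensity jitter."""
    rot = int(rng.integers(4))
    img = np.rot90(img, rot, axes=(0, 1))
    tgt = np.rot90(tgt, rot, axes=(0, 1))
    if rng.random() < 0.5:
        img, tgt = img[::-1], tgt[::-1]
    if rng.random() < 0.5:
        img, tgt = img[:, ::-1], tgt[:, ::-1]
    img = img * rng.uniform(0.9, 1.1) + rng.standard_normal(img.shape) * 0.02 * scale
    return np.ascontiguousarray(img), np.ascontiguousarray(tgt)


def _to_nchw(img: np.ndarray, scale: float) -> np.ndarray:
    return (np.asarray(img, dtype=np.float64) / scale).transpose(2, 0, 1)


def _dice_binary(pred: np.ndarray, truth: np.ndarray) -> float:
    inter = float((pred & truth).sum())
    denom = float(pred.sum() + truth.sum())
    return 1.0 if denom == 0 else 2.0 * inter / denom


def train_nuclei_model(patches: list[tuple[np.ndarray, np.ndarray]],
                       cfg: QuantConfig | None = None) -> NucleiModelState:
    """Train the nuclei U-Net (combined CE + Dice, flips/rotations/jitter).

    ``patches``: (H, W, C) image and (H, W) binary nuclei mask pairs.
    """
    cfg = cfg or QuantConfig()
    if len(patches) < 2:
        raise ValueError("need at least 2 annotated patches")
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * len(patches))))
    order = rng.permutation(len(patches))
    val_idx, train_idx = order[:n_val], order[n_val:]
    in_ch = patches[0][0].shape[2]
    net = UNet(in_ch, 2, widths=cfg.unet_widths, rng=np.random.default_rng(cfg.seed + 1))
    opt = Adam(net.params(), lr=cfg.lr)
    losses = []
    for _epoch in range(cfg.train_epochs):
        rng.shuffle(train_idx)
        epoch_loss, n_batches = 0.0, 0
        for i in range(0, len(train_idx), cfg.batch):
            idx = train_idx[i:i + cfg.batch]
            imgs, tgts = [], []
            for j in idx:
                img, tgt = _augment(patches[j][0], patches[j][1], rng, cfg.input_scale)
                imgs.append(_to_nchw(img, cfg.input_scale))
                tgts.append(tgt.astype(np.int64))
            x = np.stack(imgs)
            t = np.stack(tgts)
            logits, tape = net.forward(x)
            loss, dlogits = seg_loss(logits, t, 1.0, 1.0)
            opt.zero_grad()
            net.backward(dlogits, tape)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        losses.append(epoch_loss / max(n_batches, 1))
    state = NucleiModelState(net=net, cfg=cfg, loss_curve=losses)
    dices = []
    for j in val_idx:
        pred = segment_nuclei(state, patches[j][0])
        dices.append(_dice_binary(pred, patches[j][1].astype(bool)))
    state.val_dice = float(np.mean(dices)) if dices else float("nan")
    return state


def segment_nuclei(state: NucleiModelState, image: np.ndarray) -> np.ndarray:
    """Binary nuclei mask: foreground posterior thresholded at 0.5."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 3:
        raise ValueError("expected an (H, W, C) image")
    x = _to_nchw(image, state.cfg.input_scale)[None]
    down = 2 ** state.net.L
    h, w = x.shape[2], x.shape[3]
    ph, pw = (-h) % down, (-w) % down
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (0, ph), (0, pw)))
    logits, _ = state.net.forward(x)
    probs = softmax(logits)[0, 1, :h, :w]
    return probs > 0.5


def maps_to_image(maps: MolecularMaps) -> np.ndarray:
    """Stack lipid/protein/collagen as an (H, W, 3) network input."""
    return np.stack([maps.lipid, maps.protein, maps.collagen], axis=-1)


def aggregate(stats_by_class: dict[int, list[ClassTileStats]],
              cfg: QuantConfig | None = None) -> pd.DataFrame:
    """Per-class mean/sd/n for each chemistry metric, with a seeded random
    subsample (without replacement) when a class exceeds the tile quota."""
    cfg = cfg or QuantConfig()
    rng = np.random.default_rng(cfg.seed)
    rows = []
    for k in sorted(stats_by_class):
        tiles = stats_by_class[k]
        if not tiles:
            continue
        if len(tiles) > cfg.n_tiles_per_class:
            pick = rng.choice(len(tiles), size=cfg.n_tiles_per_class, replace=False)
            tiles = [tiles[i] for i in pick]
        for metric in ("lipid_mean", "protein_mean", "lp_ratio"):
            vals = np.array([getattr(t, metric) for t in tiles], dtype=np.float64)
            vals = vals[np.isfinite(vals)]
            rows.append({"class_id": k, "metric": metric,
                         "mean": float(vals.mean()) if vals.size else float("nan"),
                         "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                         "n": int(vals.size)})
    return pd.DataFrame(rows)


def profile_slides(slides: list[tuple[MolecularMaps, np.ndarray, np.ndarray]],
                   cfg: QuantConfig | None = None,
                   classes: list[int] | None = None) -> pd.DataFrame:
    """Per-class morpho-chemical summary pooled over one or more slides
    (the analysis design: many representative slides, tiles as units).

    Chemistry is the non-black-pixel-weighted mean over tiles of all slides;
    cytology pools raw counts/areas across slides before forming ratios.
    """
    cfg = cfg or QuantConfig()
    if classes is None:
        present = set()
        for _, labels, _ in slides:
            present |= set(np.unique(np.asarray(labels)))
        classes = sorted(k for k in present if k != 0)
    rows = []
    for k in classes:
        chem_tiles = []
        cyt_sums = np.zeros(4)
        for maps, labels, nuclei in slides:
            chem_tiles += tile_chem_stats(mask_class(maps, labels, k), cfg, k)
            sums, _ = _class_cytology_sums(nuclei, maps, labels, k, cfg)
            cyt_sums += sums
        if not chem_tiles:
            continue
        w = np.array([t.nonblack_px for t in chem_tiles], dtype=np.float64)
        lip = float(np.average([t.lipid_mean for t in chem_tiles], weights=w))
        pro = float(np.average([t.protein_mean for t in chem_tiles], weights=w))
        row = {"class_id": k, "lipid_mean": lip, "protein_mean": pro,
               "lp_ratio": lip / pro if pro > 0 else float("nan"),
               "n_tiles": len(chem_tiles)}
        if cyt_sums[1] > 0:
            pooled = _cytology_from_sums(cyt_sums, cfg)
            row.update({"weighted_nuclei": pooled.weighted_nuclei,
                        "mean_cell_area_um2": pooled.mean_cell_area,
                        "density_per_um2": pooled.density,
                        "nc_ratio": pooled.nc_ratio})
        rows.append(row)
    return pd.DataFrame(rows)


def profile_slide(maps: MolecularMaps, labels: np.ndarray, nuclei: np.ndarray,
                  cfg: QuantConfig | None = None,
                  classes: list[int] | None = None) -> pd.DataFrame:
    """Single-slide convenience wrapper around :func:`profile_slides`."""
    return profile_slides([(maps, np.asarray(labels), nuclei)], cfg, classes)
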