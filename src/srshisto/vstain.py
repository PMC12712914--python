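"""Unpaired SRS -> H&E translation with semantic alpha-mask guidance.

A bidirectional CycleGAN (two generators G1: SRS->H&E, G2: H&E->SRS, two
patch discriminators) is trained with least-squares adversarial, L1
cycle-consistency and L1 identity losses balanced 1 / 10 / 0.5, using Adam
(beta1 = 0.5, beta2 = 0.999, lr = 2e-4, linear decay). Semantic guidance
builds a per-pixel alpha mask from segmentation posteriors (a class-weighted
sum, floored) and multiplies it into the SRS input so the generator
concentrates on structurally informative tissue. Training is two-stage:
unguided pretraining on a source SRS domain, then guided fine-tuning on the
target domain starting from the pretrained parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam, Sequential, l1_loss, make_discriminator, make_generator, mse_loss
from .preproc import stitch as stitch_tiles
from .preproc import tile as tile_raster

VALID_SCORES = (2, 4, 6, 8, 10)


def _default_alpha_weights() -> dict:
    # cellular / tumor classes emphasised; stromal de-emphasised; background low
    return {0: 0.3, 1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0, 5: 1.0, 6: 0.7, 7: 0.7}


@dataclass
class VStainConfig:
    lambda_adv: float = 1.0
    lambda_cyc: float = 10.0
    lambda_idt: float = 0.5
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    lr: float = 2e-4
    #: lr decays linearly to this fraction of the initial value over a stage
    lr_final_fraction: float = 0.5
    class_alpha_weights: dict = field(default_factory=_default_alpha_weights)
    alpha_floor: float = 0.3
    image_size: int = 512
    epochs_pretrain: int = 5
    epochs_finetune: int = 5
    batch: int = 2
    seed: int = 0
    gen_width: int = 8
    disc_width: int = 8
    n_res: int = 2
    fuse_mode: str = "multiply"   # "multiply" | "concat"

    def __post_init__(self):
        if min(self.lambda_adv, self.lambda_cyc, self.lambda_idt) < 0:
            raise ValueError("loss weights must be nonnegative")
        if not 0 < self.alpha_floor <= 1:
            raise ValueError("alpha_floor must lie in (0, 1]")
        for k, w in self.class_alpha_weights.items():
            if not 0 < w <= 1:
                raise ValueError(f"alpha weight for class {k} must lie in (0, 1]")
        if self.fuse_mode not in ("multiply", "concat"):
            raise ValueError("fuse_mode must be 'multiply' or 'concat'")


@dataclass
class TranslationState:
    """Two generators, two discriminators, and per-stage loss traces."""

    g1: Sequential   # SRS -> H&E
    g2: Sequential   # H&E -> SRS
    d1: Sequential   # discriminates H&E
    d2: Sequential   # discriminates SRS
    cfg: VStainConfig
    pretrain_gen_losses: list = field(default_factory=list)
    finetune_gen_losses: list = field(default_factory=list)
    trained: bool = False


def init_state(cfg: VStainConfig | None = None, channels: int = 3) -> TranslationState:
    cfg = cfg or VStainConfig()
    rngs = [np.random.default_rng(cfg.seed + i) for i in range(4)]
    return TranslationState(
        g1=make_generator(channels, cfg.gen_width, cfg.n_res, rngs[0]),
        g2=make_generator(channels, cfg.gen_width, cfg.n_res, rngs[1]),
        d1=make_discriminator(channels, cfg.disc_width, rngs[2]),
        d2=make_discriminator(channels, cfg.disc_width, rngs[3]),
        cfg=cfg)


def alpha_mask(probs: np.ndarray, cfg: VStainConfig) -> np.ndarray:
    """alpha(x) = clamp(sum_k w_k p_k(x), floor, 1) from (H, W, C) posteriors."""
    probs = np.asarray(probs, dtype=np.float64)
    C = probs.shape[-1]
    try:
        w = np.array([cfg.class_alpha_weights[k] for k in range(C)])
    except KeyError as e:
        raise ValueError(f"missing alpha weight for class {e.args[0]}") from e
    return np.clip(probs @ w, cfg.alpha_floor, 1.0)


def fuse(srs: np.ndarray, alpha: np.ndarray, mode: str = "multiply") -> np.ndarray:
    """Structure-aware input: per-channel multiplication by the alpha mask,
    or the mask appended as an extra channel."""
    srs = np.asarray(srs, dtype=np.float64)
    alpha = np.asarray(alpha, dtype=np.float64)
    if alpha.shape != srs.shape[:2]:
        raise ValueError("alpha mask must match the image spatial shape")
    if mode == "multiply":
        return srs * alpha[..., None]
    return np.concatenate([srs, alpha[..., None]], axis=-1)


def _to_pm1(img: np.ndarray) -> np.ndarray:
    """(H, W, C) in [0, 1] -> (C, H, W) in [-1, 1]."""
    return (np.asarray(img, dtype=np.float64).transpose(2, 0, 1) * 2.0 - 1.0)


def _batch(images, idx):
    return np.stack([_to_pm1(images[i]) for i in idx])


def cycle_objective(batchA: np.ndarray, batchB: np.ndarray,
                    state: TranslationState, cfg: VStainConfig | None = None):
    """Evaluate the full objective (no gradients).

    Batches are NCHW in [-1, 1]. Returns (total, components dict).
    """
    cfg = cfg or state.cfg
    fb, _ = state.g1.forward(batchA)
    ra, _ = state.g2.forward(fb)
    fa, _ = state.g2.forward(batchB)
    rb, _ = state.g1.forward(fa)
    ib, _ = state.g1.forward(batchB)
    ia, _ = state.g2.forward(batchA)
    d1f, _ = state.d1.forward(fb)
    d2f, _ = state.d2.forward(fa)
    adv = mse_loss(d1f, 1.0)[0] + mse_loss(d2f, 1.0)[0]
    cyc = l1_loss(ra, batchA)[0] + l1_loss(rb, batchB)[0]
    idt = l1_loss(ib, batchB)[0] + l1_loss(ia, batchA)[0]
    total = cfg.lambda_adv * adv + cfg.lambda_cyc * cyc + cfg.lambda_idt * idt
    return total, {"adversarial": adv, "cycle": cyc, "identity": idt,
                   "total": total}


def _gen_step(state, a, b, cfg, opt_g):
    """One generator update; returns the weighted generator objective."""
    g1, g2, d1, d2 = state.g1, state.g2, state.d1, state.d2
    la, lc, li = cfg.lambda_adv, cfg.lambda_cyc, cfg.lambda_idt
    fb, t_fb = g1.forward(a)
    ra, t_ra = g2.forward(fb)
    fa, t_fa = g2.forward(b)
    rb, t_rb = g1.forward(fa)
    ib, t_ib = g1.forward(b)
    ia, t_ia = g2.forward(a)
    d1f, t_d1 = d1.forward(fb)
    d2f, t_d2 = d2.forward(fa)
    L_adv1, dd1 = mse_loss(d1f, 1.0)
    L_adv2, dd2 = mse_loss(d2f, 1.0)
    L_ca, dra = l1_loss(ra, a)
    L_cb, drb = l1_loss(rb, b)
    L_ib, dib = l1_loss(ib, b)
    L_ia, dia = l1_loss(ia, a)
    total = la * (L_adv1 + L_adv2) + lc * (L_ca + L_cb) + li * (L_ib + L_ia)
    opt_g.zero_grad()
    dfb = la * d1.backward(dd1, t_d1) + g2.backward(lc * dra, t_ra)
    g1.backward(dfb, t_fb)
    dfa = la * d2.backward(dd2, t_d2) + g1.backward(lc * drb, t_rb)
    g2.backward(dfa, t_fa)
    g1.backward(li * dib, t_ib)
    g2.backward(li * dia, t_ia)
    opt_g.step()
    # discriminator gradients accumulated above are stale; cleared in _disc_step
    return total, fb, fa


def _disc_step(state, a, b, fb, fa, opt_d):
    d1, d2 = state.d1, state.d2
    opt_d.zero_grad()
    total = 0.0
    for d, real, fake in ((d1, b, fb), (d2, a, fa)):
        dr, tr = d.forward(real)
        lr_, ddr = mse_loss(dr, 1.0)
        d.backward(0.5 * ddr, tr)
        df, tf = d.forward(fake)  # fake detached: no generator backward
        lf, ddf = mse_loss(df, 0.0)
        d.backward(0.5 * ddf, tf)
        total += 0.5 * (lr_ + lf)
    opt_d.step()
    return total


def _train_stage(state: TranslationState, imagesA, imagesB, cfg, epochs,
                 rng, trace: list):
    if not imagesA or not imagesB:
        raise ValueError("both image domains must be nonempty")
    opt_g = Adam(state.g1.params() + state.g2.params(), lr=cfg.lr,
                 betas=(cfg.adam_beta1, cfg.adam_beta2))
    opt_d = Adam(state.d1.params() + state.d2.params(), lr=cfg.lr,
                 betas=(cfg.adam_beta1, cfg.adam_beta2))
    n = min(len(imagesA), len(imagesB))
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        lr = cfg.lr * (1.0 - (1.0 - cfg.lr_final_fraction) * frac)
        opt_g.lr = opt_d.lr = lr
        permA = rng.permutation(len(imagesA))[:n]
        permB = rng.permutation(len(imagesB))[:n]
        g_losses = []
        for i in range(0, n, cfg.batch):
            a = _batch(imagesA, permA[i:i + cfg.batch])
            b = _batch(imagesB, permB[i:i + cfg.batch])
            g_loss, fb, fa = _gen_step(state, a, b, cfg, opt_g)
            _disc_step(state, a, b, fb, fa, opt_d)
            g_losses.append(g_loss)
        trace.append(float(np.mean(g_losses)))
    state.trained = True


def train_two_stage(sourceA, sourceB, targetA, targetB, seg_probs,
                    cfg: VStainConfig | None = None,
                    state: TranslationState | None = None) -> TranslationState:
    """Stage 1: unguided pretraining on the source domains. Stage 2: resume
    the parameters and fine-tune on the target domains with alpha-fused SRS
    inputs built from ``seg_probs`` (one (H, W, C) posterior per target SRS
    image). All images are (H, W, 3) floats in [0, 1].
    """
    cfg = cfg or VStainConfig()
    if cfg.fuse_mode != "multiply":
        raise ValueError("two-stage training supports the multiplicative fusion "
                         "operator only (concat changes the channel count)")
    state = state or init_state(cfg)
    rng = np.random.default_rng(cfg.seed)
    _train_stage(state, list(sourceA), list(sourceB), cfg,
                 cfg.epochs_pretrain, rng, state.pretrain_gen_losses)
    fused = [fuse(img, alpha_mask(p, cfg), cfg.fuse_mode)
             for img, p in zip(targetA, seg_probs)]
    _train_stage(state, fused, list(targetB), cfg,
                 cfg.epochs_finetune, rng, state.finetune_gen_losses)
    return state


def train_single_stage(imagesA, imagesB, cfg: VStainConfig | None = None,
                       state: TranslationState | None = None,
                       epochs: int | None = None) -> TranslationState:
    """Train from the current (possibly freshly initialised) parameters
    without semantic guidance; used for from-scratch baselines."""
    cfg = cfg or VStainConfig()
    state = state or init_state(cfg)
    rng = np.random.default_rng(cfg.seed)
    _train_stage(state, list(imagesA), list(imagesB), cfg,
                 epochs or cfg.epochs_finetune, rng, state.finetune_gen_losses)
    return state


def virtual_stain(srs: np.ndarray, probs: np.ndarray, state: TranslationState,
                  cfg: VStainConfig | None = None) -> np.ndarray:
    """Virtually stained H&E-like RGB (uint8), same spatial size as input.

    Large slides are tiled to ``image_size``, translated per tile and
    stitched. Input SRS is (H, W, 3) in [0, 1].
    """
    import warnings

    cfg = cfg or state.cfg
    if not state.trained:
        warnings.warn("translating with an untrained state", stacklevel=2)
    fused = fuse(srs, alpha_mask(probs, cfg), cfg.fuse_mode)
    tiles, grid = tile_raster(fused, cfg.image_size)
    out_tiles = []
    for t in tiles:
        x = _to_pm1(t)[None]
        y, _ = state.g1.forward(x)
        out_tiles.append(((y[0].transpose(1, 2, 0) + 1.0) / 2.0))
    out = stitch_tiles(out_tiles, grid)
    return (np.clip(out, 0.0, 1.0) * 255).round().astype(np.uint8)


def score_artifacts(image_ids: list, completed: pd.DataFrame | None = None,
                    seed: int = 0):
    """Blinded artifact scoring on the five-level, 10-point scale.

    Without ``completed``: returns a shuffled scoring-sheet DataFrame
    (columns ``blinded_id``, ``image_id``, ``score``) for human raters.
    With ``completed``: validates scores (must be one of 2/4/6/8/10) and
    returns {"mean", "sd", "n"}.
    """
    if completed is None:
        if not image_ids:
            raise ValueError("no images to score")
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(image_ids))
        return pd.DataFrame({"blinded_id": np.arange(len(image_ids)),
                             "image_id": [image_ids[i] for i in order],
                             "score": [None] * len(image_ids)})
    scores = completed["score"].dropna().to_numpy()
    if scores.size == 0:
        raise ValueError("completed sheet contains no scores")
    if not np.isin(scores, VALID_SCORES).all():
        raise ValueError(f"scores must be in {VALID_SCORES}")
    scores = scores.astype(np.float64)
    return {"mean": float(scores.mean()),
            "sd": float(scores.std(ddof=1)) if scores.size > 1 else 0.0,
            "n": int(scores.size)}
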