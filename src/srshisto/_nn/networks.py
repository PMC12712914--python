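"""Network builders: U-Net with skip connections, segmentation backbones,
and CycleGAN-style generator/discriminator pairs."""

from __future__ import annotations

import numpy as np

from .ops import (Conv2d, Identity, InstanceNorm, Layer, LeakyReLU, ReLU,
                  ResBlock, Sequential, Tanh, Upsample2)


class UNet(Layer):
    """Encoder-decoder with concatenated skip connections.

    ``widths`` gives channel counts per level (last = bottleneck); ``depths``
    gives the number of residual blocks per level. A 4-entry ``widths`` is the
    classic four-level design.
    """

    def __init__(self, in_ch: int, out_ch: int,
                 widths=(8, 16, 32, 64), depths=None,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        depths = tuple(depths) if depths is not None else (1,) * len(widths)
        assert len(depths) == len(widths)
        self.L = len(widths) - 1
        self.enc = []
        cin = in_ch
        for i in range(self.L):
            w = widths[i]
            block = Sequential([Conv2d(cin, w, 3, rng=rng), ReLU()] +
                               [ResBlock(w, rng=rng) for _ in range(depths[i] - 1)])
            down = Sequential([Conv2d(w, widths[i + 1], 3, stride=2, rng=rng), ReLU()])
            self.enc.append((block, down))
            cin = widths[i + 1]
        wb = widths[-1]
        self.bottleneck = Sequential([Conv2d(cin, wb, 3, rng=rng), ReLU()] +
                                     [ResBlock(wb, rng=rng) for _ in range(depths[-1] - 1)])
        self.dec = []
        for i in reversed(range(self.L)):
            w = widths[i]
            up = Sequential([Upsample2(), Conv2d(widths[i + 1], w, 3, rng=rng), ReLU()])
            fuse = Sequential([Conv2d(2 * w, w, 3, rng=rng), ReLU()])
            self.dec.append((up, fuse))
        self.head = Conv2d(widths[0], out_ch, 1, rng=rng)

    def params(self):
        out = []
        for block, down in self.enc:
            out += block.params() + down.params()
        out += self.bottleneck.params()
        for up, fuse in self.dec:
            out += up.params() + fuse.params()
        out += self.head.params()
        return out

    def forward(self, x):
        skips, enc_ctx = [], []
        for block, down in self.enc:
            s, cb = block.forward(x)
            x, cd = down.forward(s)
            skips.append(s)
            enc_ctx.append((cb, cd))
        x, cbot = self.bottleneck.forward(x)
        dec_ctx = []
        for (up, fuse), skip in zip(self.dec, reversed(skips)):
            u, cu = up.forward(x)
            cat = np.concatenate([u, skip], axis=1)
            x, cf = fuse.forward(cat)
            dec_ctx.append((cu, cf, u.shape[1]))
        y, chead = self.head.forward(x)
        return y, (enc_ctx, cbot, dec_ctx, chead)

    def backward(self, dy, ctx):
        enc_ctx, cbot, dec_ctx, chead = ctx
        dx = self.head.backward(dy, chead)
        dskips = []
        for (up, fuse), (cu, cf, wu) in zip(reversed(self.dec), reversed(dec_ctx)):
            dcat = fuse.backward(dx, cf)
            du, dskip = dcat[:, :wu], dcat[:, wu:]
            dskips.append(dskip)
            dx = up.backward(du, cu)
        dx = self.bottleneck.backward(dx, cbot)
        for (block, down), (cb, cd), dskip in zip(reversed(self.enc),
                                                  reversed(enc_ctx), reversed(dskips)):
            ds = down.backward(dx, cd) + dskip
            dx = block.backward(ds, cb)
        return dx


def toy_seg_net(in_ch: int, n_classes: int, width: int = 16,
                rng: np.random.Generator | None = None) -> Sequential:
    """Small full-resolution conv net for CPU-scale segmentation tests."""
    rng = rng or np.random.default_rng(0)
    return Sequential([
        Conv2d(in_ch, width, 3, rng=rng), ReLU(),
        Conv2d(width, width, 3, rng=rng), ReLU(),
        Conv2d(width, n_classes, 1, rng=rng),
    ])


def tiny_seg_net(in_ch: int, n_classes: int,
                 rng: np.random.Generator | None = None) -> UNet:
    """Hierarchical four-stage encoder-decoder with (2, 2, 6, 2) residual blocks."""
    return UNet(in_ch, n_classes, widths=(16, 32, 64, 96), depths=(2, 2, 6, 2), rng=rng)


def make_generator(channels: int = 3, width: int = 8, n_res: int = 2,
                   rng: np.random.Generator | None = None) -> Sequential:
    """Residual-block encoder-decoder generator (tanh output in [-1, 1])."""
    rng = rng or np.random.default_rng(0)
    return Sequential([
        Conv2d(channels, width, 3, rng=rng), InstanceNorm(width), ReLU(),
        Conv2d(width, 2 * width, 3, stride=2, rng=rng), InstanceNorm(2 * width), ReLU(),
        *[ResBlock(2 * width, rng=rng) for _ in range(n_res)],
        Upsample2(),
        Conv2d(2 * width, width, 3, rng=rng), InstanceNorm(width), ReLU(),
        Conv2d(width, channels, 3, rng=rng), Tanh(),
    ])


def make_discriminator(channels: int = 3, width: int = 8,
                       rng: np.random.Generator | None = None) -> Sequential:
    """Patch discriminator: strided convs ending in a 1-channel score map."""
    rng = rng or np.random.default_rng(0)
    return Sequential([
        Conv2d(channels, width, 3, stride=2, rng=rng), LeakyReLU(0.2),
        Conv2d(width, 2 * width, 3, stride=2, rng=rng), LeakyReLU(0.2),
        Conv2d(2 * width, 1, 3, rng=rng),
    ])
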