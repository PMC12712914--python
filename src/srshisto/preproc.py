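"""Spectral unmixing of dual-channel SRS images, RGB composition, and tiling.

The two SRS channels (2845 cm^-1 CH2-dominated, 2930 cm^-1 CH3-dominated) are
linear mixtures of lipid and protein concentration; a 2x2 mixing matrix M maps
(lipid, protein) to (I_2845, I_2930) and unmixing applies M^-1 per pixel.
Collagen comes directly from the SHG channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import DEFAULT_PX_PER_UM


class ShapeError(ValueError):
    """Rasters that must share a shape do not."""


class SingularMatrixError(ValueError):
    """The unmixing matrix is not invertible."""


def _check_raster(a, name):
    a = np.asarray(a, dtype=np.float64)
    if a.ndim != 2 or a.size == 0:
        raise ShapeError(f"{name} must be a non-empty 2-D raster")
    if not np.all(np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


@dataclass
class RawSRSFrame:
    """Acquired two-channel SRS + SHG raster with pixel-size metadata (a.u. intensities)."""

    ch2845: np.ndarray
    ch2930: np.ndarray
    shg: np.ndarray
    px_per_um: float = DEFAULT_PX_PER_UM

    def __post_init__(self):
        self.ch2845 = _check_raster(self.ch2845, "ch2845")
        self.ch2930 = _check_raster(self.ch2930, "ch2930")
        self.shg = _check_raster(self.shg, "shg")
        if not (self.ch2845.shape == self.ch2930.shape == self.shg.shape):
            raise ShapeError("SRS/SHG channels must share one shape")
        if self.px_per_um <= 0:
            raise ValueError("px_per_um must be positive")

    @property
    def shape(self):
        return self.ch2845.shape


#: default lipid/protein cross-talk: lipid bleeds into the 2930 channel,
#: protein into the 2845 channel; override from measured spectra when known.
DEFAULT_UNMIX_COEFFS = ((1.0, 0.40), (0.55, 1.0))


@dataclass
class UnmixMatrix:
    """2x2 matrix mapping (lipid, protein) concentrations to (I2845, I2930)."""

    coefficients: np.ndarray = field(
        default_factory=lambda: np.array(DEFAULT_UNMIX_COEFFS))
    det_tol: float = 1e-9

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        if self.coefficients.shape != (2, 2):
            raise ShapeError("unmixing matrix must be 2x2")
        if abs(np.linalg.det(self.coefficients)) <= self.det_tol:
            raise SingularMatrixError("unmixing matrix is singular")

    @property
    def inverse(self) -> np.ndarray:
        return np.linalg.inv(self.coefficients)


@dataclass
class MolecularMaps:
    """Unmixed lipid/protein intensity rasters plus the collagen (SHG) raster."""

    lipid: np.ndarray
    protein: np.ndarray
    collagen: np.ndarray
    px_per_um: float = DEFAULT_PX_PER_UM

    def __post_init__(self):
        self.lipid = _check_raster(self.lipid, "lipid")
        self.protein = _check_raster(self.protein, "protein")
        self.collagen = _check_raster(self.collagen, "collagen")
        if not (self.lipid.shape == self.protein.shape == self.collagen.shape):
            raise ShapeError("molecular maps must share one shape")

    @property
    def shape(self):
        return self.lipid.shape


def unmix(frame: RawSRSFrame, matrix: UnmixMatrix | None = None) -> MolecularMaps:
    """Invert the channel mixture per pixel; negative concentrations are clamped to 0."""
    matrix = matrix or UnmixMatrix()
    inv = matrix.inverse
    lipid = inv[0, 0] * frame.ch2845 + inv[0, 1] * frame.ch2930
    protein = inv[1, 0] * frame.ch2845 + inv[1, 1] * frame.ch2930
    return MolecularMaps(lipid=np.maximum(lipid, 0.0),
                         protein=np.maximum(protein, 0.0),
                         collagen=frame.shg.copy(),
                         px_per_um=frame.px_per_um)


def forward_mix(maps: MolecularMaps, matrix: UnmixMatrix | None = None) -> RawSRSFrame:
    """Forward model: render channel intensities from molecular concentrations."""
    matrix = matrix or UnmixMatrix()
    m = matrix.coefficients
    return RawSRSFrame(ch2845=m[0, 0] * maps.lipid + m[0, 1] * maps.protein,
                       ch2930=m[1, 0] * maps.lipid + m[1, 1] * maps.protein,
                       shg=maps.collagen.copy(),
                       px_per_um=maps.px_per_um)


def _scale_channel(chan: np.ndarray, rng) -> np.ndarray:
    vmin, vmax = (float(chan.min()), float(chan.max())) if rng is None else rng
    if vmax <= vmin:
        return np.zeros(chan.shape, dtype=np.uint8)
    scaled = (chan - vmin) / (vmax - vmin)
    return (np.clip(scaled, 0.0, 1.0) * 255).round().astype(np.uint8)


def compose_rgb(maps: MolecularMaps, scaling=None) -> np.ndarray:
    """RGB colour coding: red collagen, green lipid, blue protein (8-bit).

    ``scaling`` is an optional per-channel (vmin, vmax) triple keyed
    'collagen'/'lipid'/'protein'; channels without a range are min-max scaled.
    """
    scaling = scaling or {}
    rgb = np.stack([
        _scale_channel(maps.collagen, scaling.get("collagen")),
        _scale_channel(maps.lipid, scaling.get("lipid")),
        _scale_channel(maps.protein, scaling.get("protein")),
    ], axis=-1)
    return rgb


@dataclass
class TileGrid:
    """Row-major, 0-based non-overlapping tiling bookkeeping (top-left origin)."""

    tile_size: int
    n_rows: int
    n_cols: int
    pad_bottom: int
    pad_right: int

    def __post_init__(self):
        if self.tile_size <= 0:
            raise ValueError("tile_size must be positive")
        if not (0 <= self.pad_bottom < self.tile_size and 0 <= self.pad_right < self.tile_size):
            raise ValueError("padding must lie in [0, tile_size)")

    @property
    def original_shape(self):
        return (self.n_rows * self.tile_size - self.pad_bottom,
                self.n_cols * self.tile_size - self.pad_right)


def tile(image: np.ndarray, tile_size: int):
    """Split a raster into non-overlapping tiles (bottom/right zero-padded).

    Returns ``(tiles, grid)`` with tiles in row-major order.
    """
    image = np.asarray(image)
    if image.ndim < 2 or image.shape[0] == 0 or image.shape[1] == 0:
        raise ShapeError("cannot tile an empty image")
    if tile_size <= 0:
        raise ValueError("tile_size must be positive")
    h, w = image.shape[:2]
    n_rows = -(-h // tile_size)
    n_cols = -(-w // tile_size)
    pad_bottom = n_rows * tile_size - h
    pad_right = n_cols * tile_size - w
    pad_width = [(0, pad_bottom), (0, pad_right)] + [(0, 0)] * (image.ndim - 2)
    padded = np.pad(image, pad_width)
    tiles = [padded[r * tile_size:(r + 1) * tile_size,
                    c * tile_size:(c + 1) * tile_size]
             for r in range(n_rows) for c in range(n_cols)]
    return tiles, TileGrid(tile_size, n_rows, n_cols, pad_bottom, pad_right)


def stitch(tiles, grid: TileGrid) -> np.ndarray:
    """Exact inverse of :func:`tile`: reassemble and strip the zero padding."""
    if len(tiles) != grid.n_rows * grid.n_cols:
        raise ShapeError(f"expected {grid.n_rows * grid.n_cols} tiles, got {len(tiles)}")
    ts = grid.tile_size
    first = np.asarray(tiles[0])
    if first.shape[:2] != (ts, ts):
        raise ShapeError("tile shape does not match grid tile_size")
    out_shape = (grid.n_rows * ts, grid.n_cols * ts) + first.shape[2:]
    out = np.empty(out_shape, dtype=first.dtype)
    for idx, t in enumerate(tiles):
        t = np.asarray(t)
        if t.shape != first.shape:
            raise ShapeError("tiles must all share one shape")
        r, c = divmod(idx, grid.n_cols)
        out[r * ts:(r + 1) * ts, c * ts:(c + 1) * ts] = t
    h, w = grid.original_shape
    return out[:h, :w]
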