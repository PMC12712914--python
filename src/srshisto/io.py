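"""File formats: multi-channel TIFF for frames/maps, indexed PNG for label
maps, 8-bit PNG for composites, JSON sidecars for tiling metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .preproc import MolecularMaps, RawSRSFrame, TileGrid

#: display palette per class: background, normal alveoli (purple), immune
#: cells (dark blue), low (green), intermediate (yellow), high (red),
#: stroma (gray), tracheal wall (cyan)
LABEL_PALETTE = [
    (0, 0, 0), (128, 64, 192), (24, 48, 160), (64, 192, 64),
    (230, 210, 50), (220, 50, 50), (150, 150, 150), (60, 200, 220),
]


def write_frame(frame: RawSRSFrame, path) -> None:
    stack = np.stack([frame.ch2845, frame.ch2930, frame.shg]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps({"px_per_um": frame.px_per_um,
                                             "channels": ["2845", "2930", "shg"]}))


def read_frame(path) -> RawSRSFrame:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = json.loads(tf.pages[0].description or "{}")
    return RawSRSFrame(ch2845=stack[0], ch2930=stack[1], shg=stack[2],
                       px_per_um=float(meta.get("px_per_um", 2.8986)))


def write_maps(maps: MolecularMaps, path) -> None:
    stack = np.stack([maps.lipid, maps.protein, maps.collagen]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack",
                     description=json.dumps({"px_per_um": maps.px_per_um,
                                             "channels": ["lipid", "protein", "collagen"]}))


def read_maps(path) -> MolecularMaps:
    with tifffile.TiffFile(path) as tf:
        stack = tf.asarray()
        meta = json.loads(tf.pages[0].description or "{}")
    return MolecularMaps(lipid=stack[0], protein=stack[1], collagen=stack[2],
                         px_per_um=float(meta.get("px_per_um", 2.8986)))


def write_rgb_png(rgb: np.ndarray, path) -> None:
    Image.fromarray(np.asarray(rgb, dtype=np.uint8), mode="RGB").save(path)


def write_label_png(labels: np.ndarray, path) -> None:
    """Indexed PNG with the fixed class palette."""
    img = Image.fromarray(np.asarray(labels, dtype=np.uint8), mode="P")
    palette = [c for rgb in LABEL_PALETTE for c in rgb]
    img.putpalette(palette + [0] * (768 - len(palette)))
    img.save(path)


def read_label_png(path) -> np.ndarray:
    return np.asarray(Image.open(path)).astype(np.int64)


def write_mask_png(mask: np.ndarray, path) -> None:
    Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8)).save(path)


def read_mask_png(path) -> np.ndarray:
    return np.asarray(Image.open(path)) > 127


def write_grid_json(grid: TileGrid, path) -> None:
    Path(path).write_text(json.dumps(vars(grid), indent=2))


def read_grid_json(path) -> TileGrid:
    return TileGrid(**json.loads(Path(path).read_text()))
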