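"""Synthetic SRS slide phantoms with known class layout, chemistry and cytology.

A phantom couples a class label map (smoothed-random-field regions), per-class
lipid/protein levels, elliptical nuclei placed at a target cell density, and
collagen fiber texture in stromal classes, then forward-mixes the molecular
maps into the two SRS channels with additive Gaussian noise. Because truth
rasters are recorded before mixing and noise, every downstream module
(unmixing, segmentation, grading, quantification, staining) can be validated
end-to-end against configured ground truth.

Cell geometry is made exactly self-consistent with the quantification module:
a cellular class with cell area A (um^2), density d (um^-2) and
nucleus-to-cytoplasm ratio r occupies a signal-bearing ("tissue") fraction
d*A of its region — the remaining 1 - d*A is signal-free cavity (air space) —
and each nucleus covers A * r/(1+r) um^2, so measured density (per region
area), mean cell area (tissue area per nucleus) and N/C (nuclei over
cytoplasm) all recover the configured values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .classes import DEFAULT_PX_PER_UM, N_CLASSES
from .preproc import MolecularMaps, RawSRSFrame, UnmixMatrix, forward_mix


@dataclass
class ClassSpec:
    """Chemistry and cytology of one tissue class.

    ``cell_area_um2 = 0`` or ``density_per_um2 = 0`` marks an acellular class.
    """

    class_id: int
    lipid_mean: float
    protein_mean: float
    noise_sd: float = 4.0
    cell_area_um2: float = 0.0
    density_per_um2: float = 0.0
    nc_ratio: float = 0.0
    has_collagen: bool = False

    def __post_init__(self):
        if not 0 <= self.class_id < N_CLASSES:
            raise ValueError("class_id out of range")
        if self.lipid_mean < 0 or self.protein_mean < 0 or self.noise_sd < 0:
            raise ValueError("intensity parameters must be nonnegative")
        if self.cellular:
            if not 0.0 < self.nc_ratio < 1.0:
                raise ValueError("nc_ratio must lie in (0, 1) for cellular classes")
            if self.density_per_um2 * self.cell_area_um2 > 1.0:
                raise ValueError("cells cannot overfill area: density * cell_area > 1")

    @property
    def cellular(self) -> bool:
        return self.cell_area_um2 > 0 and self.density_per_um2 > 0


def default_class_specs(noise_sd: float = 4.0) -> list[ClassSpec]:
    """Per-class defaults: tumor-grade cytology and lipid levels follow the
    printed low/intermediate/high-grade values (221.5/212.8/198.0 um^2 cell
    area, 0.0037/0.0045/0.0049 um^-2 density, 0.18/0.20/0.21 N/C,
    109.8/127.2/138.3 a.u. lipid); non-tumor chemistry follows the reported
    ~70 a.u. lipid and 140-180 a.u. protein regime, with low-protein alveoli.
    """
    return [
        ClassSpec(0, 0.0, 0.0, noise_sd=noise_sd),
        ClassSpec(1, 70.2, 90.0, noise_sd, 150.0, 0.0020, 0.12),
        ClassSpec(2, 70.0, 160.0, noise_sd, 60.0, 0.0100, 0.50),
        ClassSpec(3, 109.8, 150.0, noise_sd, 221.5, 0.0037, 0.18),
        ClassSpec(4, 127.2, 160.0, noise_sd, 212.8, 0.0045, 0.20),
        ClassSpec(5, 138.3, 170.0, noise_sd, 198.0, 0.0049, 0.21),
        ClassSpec(6, 70.0, 150.0, noise_sd, has_collagen=True),
        ClassSpec(7, 70.0, 150.0, noise_sd, has_collagen=True),
    ]


@dataclass
class PhantomSpec:
    """Layout and seed for one synthetic slide."""

    height: int = 1024
    width: int = 1024
    px_per_um: float = DEFAULT_PX_PER_UM
    class_specs: list[ClassSpec] = field(default_factory=default_class_specs)
    target_area_fractions: np.ndarray = field(default_factory=lambda: np.array(
        [0.10, 0.14, 0.08, 0.17, 0.17, 0.17, 0.12, 0.05]))
    region_smoothness: float = 32.0
    seed: int = 0

    def __post_init__(self):
        self.target_area_fractions = np.asarray(self.target_area_fractions, dtype=np.float64)
        if len(self.target_area_fractions) != len(self.class_specs):
            raise ValueError("one target fraction per class spec required")
        if np.any(self.target_area_fractions < 0):
            raise ValueError("area fractions must be nonnegative")
        if abs(self.target_area_fractions.sum() - 1.0) > 1e-9:
            raise ValueError("area fractions must sum to 1")


def separable_phantom_spec(height: int = 64, width: int = 64, seed: int = 0,
                           noise_sd: float = 4.0,
                           region_smoothness: float = 8.0) -> PhantomSpec:
    """Four acellular classes with channel means many noise-sd apart — an
    intentionally easy segmentation test bed."""
    specs = [
        ClassSpec(0, 0.0, 0.0, noise_sd=noise_sd),
        ClassSpec(3, 80.0, 220.0, noise_sd=noise_sd),
        ClassSpec(5, 160.0, 120.0, noise_sd=noise_sd),
        ClassSpec(6, 240.0, 40.0, noise_sd=noise_sd, has_collagen=True),
    ]
    return PhantomSpec(height=height, width=width, class_specs=specs,
                       target_area_fractions=np.full(4, 0.25),
                       region_smoothness=region_smoothness, seed=seed)


@dataclass
class PhantomSample:
    """A rendered phantom: raw frame plus all ground-truth rasters."""

    frame: RawSRSFrame
    truth_maps: MolecularMaps
    truth_labels: np.ndarray
    truth_nuclei: np.ndarray
    spec: PhantomSpec
    n_skipped_nuclei: int = 0


def sample_label_map(spec: PhantomSpec) -> np.ndarray:
    """Draw per-pixel class labels by rank-thresholding a Gaussian-smoothed
    random field, so realized area fractions match targets to pixel rounding.
    Deterministic given ``spec.seed``."""
    if spec.height <= 0 or spec.width <= 0:
        raise ValueError("phantom must have positive area")
    rng = np.random.default_rng(spec.seed)
    fld = rng.standard_normal((spec.height, spec.width))
    fld = ndimage.gaussian_filter(fld, sigma=spec.region_smoothness)
    order = np.argsort(fld.ravel(), kind="stable")
    n = order.size
    labels_flat = np.empty(n, dtype=np.int64)
    counts = np.round(np.cumsum(spec.target_area_fractions) * n).astype(int)
    start = 0
    for cs, stop in zip(spec.class_specs, counts):
        labels_flat[order[start:stop]] = cs.class_id
        start = stop
    labels_flat[order[start:]] = spec.class_specs[-1].class_id
    return labels_flat.reshape(spec.height, spec.width)


def _cavity_mask(mask: np.ndarray, n_cavity_px: int, rng, sigma: float = 6.0):
    """Signal-free air spaces: the exact number of lowest-field pixels of a
    smoothed random field within ``mask`` (contiguous, organ-like holes)."""
    cavity = np.zeros_like(mask)
    if n_cavity_px <= 0:
        return cavity
    fld = ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=sigma)
    idx = np.flatnonzero(mask)
    order = np.argsort(fld.ravel()[idx], kind="stable")
    cavity.ravel()[idx[order[:n_cavity_px]]] = True
    return cavity


def _place_nuclei(tissue: np.ndarray, n_target: int, area_px: float, rng,
                  max_attempts: int = 100):
    """Rejection-sample non-overlapping, axis-ratio-jittered ellipses inside
    ``tissue``. Returns (nuclei mask, n skipped)."""
    h, w = tissue.shape
    nuclei = np.zeros((h, w), dtype=bool)
    blocked = np.zeros((h, w), dtype=bool)  # nuclei + 1 px spacing
    coords = np.flatnonzero(tissue)
    if coords.size == 0 or n_target == 0:
        return nuclei, n_target
    skipped = 0
    r0 = np.sqrt(area_px / np.pi)
    for _ in range(n_target):
        placed = False
        for attempt in range(max_attempts):
            idx = coords[rng.integers(coords.size)]
            cy, cx = divmod(idx, w)
            q = rng.uniform(0.65, 1.0)
            a, b = r0 / np.sqrt(q), r0 * np.sqrt(q)
            theta = rng.uniform(0, np.pi)
            strict = attempt < max_attempts // 2
            rr, cc = draw_ellipse(cy, cx, a, b, rotation=theta, shape=(h, w))
            inside = tissue[rr, cc]
            if blocked[rr, cc].any():
                continue
            got = int(inside.sum())
            if strict:
                if not inside.all() or rr.size < area_px * 0.9:
                    continue
            else:
                # clipped fallback for thin regions: keep the in-region part,
                # inflating the ellipse to restore the nominal nuclear area
                if got < 0.5 * area_px:
                    continue
                if got < 0.95 * area_px:
                    scale = min(float(np.sqrt(area_px / got)), 2.0)
                    rr2, cc2 = draw_ellipse(cy, cx, a * scale, b * scale,
                                            rotation=theta, shape=(h, w))
                    in2 = tissue[rr2, cc2]
                    if not blocked[rr2, cc2].any() and in2.sum() > got:
                        rr, cc, inside = rr2, cc2, in2
                        a, b = a * scale, b * scale
            nuclei[rr[inside], cc[inside]] = True
            br, bc = draw_ellipse(cy, cx, a + 1.5, b + 1.5, rotation=theta,
                                  shape=(h, w))
            blocked[br, bc] = True
            placed = True
            break
        if not placed:
            skipped += 1
    return nuclei, skipped


def _collagen_fibers(mask: np.ndarray, rng, amplitude: float = 150.0):
    """Smoothed random line segments confined to a class region."""
    h, w = mask.shape
    canvas = np.zeros((h, w))
    coords = np.flatnonzero(mask)
    n_fibers = max(4, coords.size // 1500)
    for _ in range(n_fibers):
        idx = coords[rng.integers(coords.size)]
        y0, x0 = divmod(idx, w)
        theta = rng.uniform(0, np.pi)
        length = rng.uniform(30, 90)
        y1 = int(np.clip(y0 + length * np.sin(theta), 0, h - 1))
        x1 = int(np.clip(x0 + length * np.cos(theta), 0, w - 1))
        rr, cc = draw_line(y0, x0, y1, x1)
        canvas[rr, cc] = 1.0
    canvas = ndimage.gaussian_filter(canvas, sigma=1.2)
    if canvas.max() > 0:
        canvas = canvas / canvas.max() * amplitude
    return canvas * mask


def render_phantom(labels: np.ndarray, spec: PhantomSpec,
                   matrix: UnmixMatrix | None = None) -> PhantomSample:
    """Render molecular truth maps, nuclei, and a noisy forward-mixed frame.

    Nuclei pixels carry elevated protein and reduced lipid; cytoplasm values
    are balanced so the class mean over signal-bearing pixels equals the
    configured mean exactly (before noise).
    """
    matrix = matrix or UnmixMatrix()
    present = set(np.unique(labels))
    for cs in spec.class_specs:
        if cs.cellular and cs.density_per_um2 * cs.cell_area_um2 > 1.0:
            raise ValueError("infeasible packing")
    if not present <= {cs.class_id for cs in spec.class_specs}:
        raise ValueError("label map contains classes absent from the spec")
    rng = np.random.default_rng(spec.seed + 1)
    h, w = labels.shape
    ppu2 = spec.px_per_um ** 2
    lipid = np.zeros((h, w))
    protein = np.zeros((h, w))
    collagen = np.zeros((h, w))
    nuclei_all = np.zeros((h, w), dtype=bool)
    noise_sd = np.zeros((h, w))
    n_skipped = 0
    for cs in spec.class_specs:
        if cs.class_id not in present:
            continue
        mask = labels == cs.class_id
        noise_sd[mask] = cs.noise_sd
        if cs.cellular:
            # nuclei first (inside the class region), then cavities carved
            # from the remainder so the tissue fraction is exactly d * A
            tissue_frac = cs.density_per_um2 * cs.cell_area_um2
            region_px = int(mask.sum())
            region_area_um2 = region_px / ppu2
            n_target = int(round(cs.density_per_um2 * region_area_um2))
            nuc_area_px = cs.cell_area_um2 * cs.nc_ratio / (1.0 + cs.nc_ratio) * ppu2
            nuclei, skipped = _place_nuclei(mask, n_target, nuc_area_px, rng)
            n_cavity = int(round((1.0 - tissue_frac) * region_px))
            cavity = _cavity_mask(mask & ~nuclei, n_cavity, rng)
            tissue = mask & ~cavity
            n_skipped += skipped
            nuclei_all |= nuclei
            n_px = int(nuclei.sum())
            t_px = int(tissue.sum())
            c_px = t_px - n_px
            cyt = tissue & ~nuclei
            if c_px > 0:
                l_nuc, p_nuc = 0.6 * cs.lipid_mean, 1.5 * cs.protein_mean
                lipid[nuclei] = l_nuc
                protein[nuclei] = p_nuc
                lipid[cyt] = (t_px * cs.lipid_mean - n_px * l_nuc) / c_px
                protein[cyt] = (t_px * cs.protein_mean - n_px * p_nuc) / c_px
            else:
                lipid[tissue] = cs.lipid_mean
                protein[tissue] = cs.protein_mean
        else:
            lipid[mask] = cs.lipid_mean
            protein[mask] = cs.protein_mean
        if cs.has_collagen:
            collagen += _collagen_fibers(mask, rng)
    truth = MolecularMaps(lipid=lipid, protein=protein, collagen=collagen,
                          px_per_um=spec.px_per_um)
    clean = forward_mix(truth, matrix)
    ch2845 = np.maximum(clean.ch2845 + rng.standard_normal((h, w)) * noise_sd, 0.0)
    ch2930 = np.maximum(clean.ch2930 + rng.standard_normal((h, w)) * noise_sd, 0.0)
    shg = np.maximum(clean.shg + rng.standard_normal((h, w)) * noise_sd, 0.0)
    frame = RawSRSFrame(ch2845=ch2845, ch2930=ch2930, shg=shg,
                        px_per_um=spec.px_per_um)
    return PhantomSample(frame=frame, truth_maps=truth, truth_labels=labels,
                         truth_nuclei=nuclei_all, spec=spec,
                         n_skipped_nuclei=n_skipped)


def generate(spec: PhantomSpec, matrix: UnmixMatrix | None = None) -> PhantomSample:
    """Convenience: sample a label map and render it."""
    return render_phantom(sample_label_map(spec), spec, matrix)


def render_he_like(labels: np.ndarray, nuclei: np.ndarray, seed: int = 0) -> np.ndarray:
    """Synthetic H&E-style RGB rendering (float in [0, 1]) of the same label
    process: purple nuclei, pink cytoplasm, deeper pink stroma, white
    background — an unpaired-but-matched staining target domain."""
    rng = np.random.default_rng(seed)
    h, w = labels.shape
    img = np.empty((h, w, 3))
    img[...] = (0.96, 0.96, 0.97)                       # background / cavities
    tissue = labels > 0
    img[tissue] = (0.91, 0.68, 0.78)                    # eosin cytoplasm
    stromal = (labels == 6) | (labels == 7)
    img[stromal] = (0.86, 0.55, 0.71)                   # denser eosin
    img[nuclei.astype(bool)] = (0.42, 0.24, 0.56)       # hematoxylin nuclei
    img += rng.standard_normal((h, w, 3)) * 0.02
    return np.clip(img, 0.0, 1.0)
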