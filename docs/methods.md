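# Methods

## Imaging model and spectral unmixing

Dual-channel SRS intensities are modelled as a linear mixture of lipid and
protein concentration per pixel: `(I₂₈₄₅, I₂₉₃₀)ᵀ = M (L, P)ᵀ`, with SHG
reporting collagen directly. Published work states linear decomposition but
not the mixing coefficients, which depend on the instrument's spectral
response; the default `M = [[1.0, 0.40], [0.55, 1.0]]` encodes the physical
cross-talk direction (lipid CH₂ bleeding into the CH₃ channel more weakly
than protein CH₃ bleeds into CH₂) and is fully configurable. Unmixing is
`M⁻¹` per pixel with negative concentrations clamped to zero (concentrations
are physical); the phantom forward-mixes with the same configured matrix, so
round trips are exact at zero noise by construction. Matrices with
`|det M| ≤ 1e-9` are rejected.

Tiling is row-major with top-left origin; remainder tiles are zero-padded
bottom/right and the padding recorded, making `stitch(tile(x)) == x`
bit-exact for any shape.

## Synthetic tissue phantom

The phantom is the test bed standing in for patient slides (none are
publicly available). It emulates:

- **Region layout** — class labels from rank-thresholding one
  Gaussian-smoothed noise field (correlation length `region_smoothness`,
  default 32 px); realized area fractions equal targets to pixel rounding.
  Regions are contiguous with smooth organ-like borders; a Voronoi layout
  was rejected for its unrealistically straight borders.
- **Chemistry** — per-class lipid/protein means; tumor-grade lipid defaults
  109.8 / 127.2 / 138.3 a.u. (low / intermediate / high), normal alveoli
  70.2 / 90 a.u., other classes ~70 / 150–170 a.u., matching the reported
  regime. Nuclei carry 1.5× the class protein mean and 0.6× the lipid mean;
  cytoplasm values are solved so the class mean over signal-bearing pixels
  equals the configured mean exactly before noise.
- **Cytology** — a cellular class with cell area A (µm²), density d (µm⁻²)
  and N/C ratio r has signal-bearing (tissue) fraction `d·A` of its region;
  the rest is signal-free cavity (air space), carved as the lowest pixels of
  a second smoothed field at the exact count. Each nucleus covers
  `A·r/(1+r)` µm² — the nuclear share when N/C is nucleus over cytoplasm —
  drawn as an axis-ratio-jittered ellipse, rejection-sampled against overlap
  (100 attempts; the second half of attempts permits clipping at region
  borders, inflating the ellipse to preserve the nominal in-region area;
  exhausted attempts are counted and reported). This construction makes
  measured density (count / region area), mean cell area (tissue area /
  count) and N/C (nuclei / (tissue − nuclei)) recover the configured values
  identically in expectation. Grade defaults: areas 221.5 / 212.8 / 198.0
  µm², densities 0.0037 / 0.0045 / 0.0049 µm⁻², N/C 0.18 / 0.20 / 0.21.
  Nuclei are placed before cavities, so nuclear positions are not
  morphologically coupled to air spaces — a deliberate simplification.
- **Collagen** — stromal/tracheal classes receive smoothed random line
  segments in the SHG channel.
- **Noise** — per-class Gaussian noise (default sd 4 a.u.) added to the
  forward-mixed channels, clipped at zero (detector physicality).

What the phantom does **not** emulate: glandular/papillary
sub-architecture, intensity texture within cytoplasm, inter-patient
variability, staining artifacts, or any spatial correlation between
chemistry and morphology beyond the class means. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms, not
clinical performance on real tissue.

A `separable_phantom_spec` variant provides four acellular classes whose
channel means sit many noise standard deviations apart — the intentionally
easy regime used to validate the training/inference contract of the
segmentation stack.

## Segmentation

Preprocessing is resize-first (source patches resized to 600 px, then
cropped to 512 px — random in training, centered at inference) to preserve
lesion context before cropping; channel normalisation defaults to the
identity (zero mean, unit sd as configured). Augmentation: horizontal and
vertical flips, ±15° rotation (applied jointly to image and nearest-
neighbour-resized labels), brightness jitter and Gaussian noise (image
only).

The loss is `w_ce·CE + w_dice·(1 − soft-Dice averaged over classes)` with
default weights (1, 1) — no ratio is published — optimised by AdamW
(lr 1e-4, weight decay 0.01) under polynomial decay (power 0.9). Arg-max
ties break toward the lowest class id (deterministic). Two backbones share
this contract: `toy`, a small full-resolution conv net for CPU-scale work,
and `tiny`, a hierarchical four-stage encoder-decoder with (2, 2, 6, 2)
residual conv blocks per stage mirroring the stage layout of a
Swin-Tiny/UPerNet design. A trainable windowed-attention transformer is out
of reach for the numpy backprop core this package runs on, so the stage
layout is mirrored in convolutional form; the published full-scale
configuration is retained in `SegConfig` but is not what the contract tests
exercise. Toy-scale experiments use a larger learning rate (2e-3) than the
full-scale default, as is appropriate for a much smaller model and dataset.

Evaluation follows the standard per-class one-vs-rest formulas
(IoU, accuracy, Dice, precision, recall) plus symmetric boundary-F1:
boundary pixels are class pixels with a differing 8-neighbour (image border
replicated, so frame pixels are not automatically boundary), matched by
Euclidean distance transform within a 6-px tolerance; the fast path is
verified against a brute-force all-pairs oracle. A class absent from truth
and prediction is excluded from means; absent from truth only contributes
IoU 0. Metrics are reported as percentages with two decimals.

## Grading

Slide percentages are computed over non-background tissue; the three tumor
classes are renormalised to the tumor area. Grade 3 when the high-grade
fraction is **≥** 20 % (the inclusive reading; the threshold is
configurable), otherwise the predominant subtype decides; an exact
low/intermediate tie takes the higher grade (conservative clinical
behaviour; the rule source is silent). Reported fractions are rounded to one
decimal; decisions use unrounded values. Case-level grading pools absolute
tumor pixel areas across slides (large sections dominate) before
renormalising.

## Quantification

"Non-black" pixels are those with any molecular channel above
`black_threshold` (default 25 a.u.): several noise standard deviations above
empty pixels, well below the dimmest configured tissue signal (~40 a.u.).
With exact-zero masked, noise-free inputs a threshold of 0 is equivalent.
Chemistry is averaged per 512-px tile over non-black pixels (empty tiles
skipped); multi-slide summaries weight tile means by their non-black pixel
counts.

Nuclei come from a four-level U-Net with skip connections (combined
CE + Dice loss, rotation/flip/jitter augmentation, foreground posterior
thresholded at 0.5). Components with ≥ `min_component_px` pixels
(default 20 ≈ 2.4 µm², below any plausible nucleus; the published threshold
value is not stated) are counted with weight 0.5 when touching a tile
border — the device that prevents double counting across tiles.

Denominators: mean cell area divides non-black tissue area by the weighted
count; **cell density divides the weighted count by the whole class-region
area including intra-class signal-free cavities** (density "in the alveolar
space"); N/C divides nuclear by cytoplasmic (tissue − nuclei) area. The
region/tissue split is what makes the three reference cytology triplets
mutually consistent — with a single denominator, mean cell area would be
identically the reciprocal of density, which the reference values
contradict (e.g. 221.5 µm² vs 1/0.0037 = 270.3 µm²: an 18 % air-space
fraction). Quantitative recovery tests pool several phantom slides
(mirroring the many-representative-slides analysis design) so that each
tumor class contains several hundred nuclei; with ~80 nuclei per class on a
single 1024² slide, counting noise would swamp the 4–7 % configured gaps
between grades.

## Virtual staining

Standard bidirectional CycleGAN: residual-block encoder-decoder generators
(tanh output in [−1, 1]) and strided-conv patch discriminators, least-squares
adversarial loss, L1 cycle and identity losses weighted 1 / 10 / 0.5, Adam
(β₁ 0.5, β₂ 0.999, lr 2e-4) with linear decay to half the initial rate over
a stage. Semantic guidance: `α(x) = clamp(Σₖ wₖ pₖ(x), floor, 1)` from
segmentation posteriors, multiplied pixel-wise into the SRS input. Default
weights emphasise cellular/tumor classes (1.0) over stroma (0.7) and
background (0.3 floor); the published description ("different weights to
distinct tissue types") fixes neither the operator nor the values, so
multiplication — the literal alpha-mask reading — is the trained operator,
with channel concatenation available behind a config switch for the fusion
op itself. Two-stage training pretrains unguided on a source SRS domain
(the phantom supplies one; brain-tissue SRS is not available) and fine-tunes
on the target domain with fused inputs, resuming parameters. The phantom
also renders an H&E-like domain (purple nuclei, pink cytoplasm, white
background) from the same label process, giving an unpaired-but-matched
test bed. Toy-scale tests run at 64×64 with reduced widths and lr 1e-3; the
512-px configuration is the default for real use.

Artifact scoring uses the five-level, 10-point scale (valid scores
2/4/6/8/10); the package only emits blinded shuffled score sheets and
summarises completed ones — scoring itself is a human task.

## Pipeline and reproducibility

A single global seed is fanned out per stage as
`(seed XOR crc32(stage)) mod 2³¹`, so stages re-run independently yet
reproducibly. Every run writes a manifest with the config hash, stage
timings, artifact registry and machine-readable warnings (skipped nuclei,
empty masks, nuclei-mask provenance). All randomness flows through
`numpy.random.Generator` instances seeded from configs; training is
single-threaded and bitwise reproducible. The backprop core is validated
against numerical gradients in the test suite.

## Known limitations

- Phantom realism limits (above): results on synthetic slides bound
  algorithmic correctness, not clinical accuracy.
- The `tiny` backbone mirrors only the stage layout, not the attention
  mechanism, of the published network; published segmentation scores are
  not reproducible without the authors' cohort.
- The cytology tile edge-weighting scheme undercounts slightly (~2–5 %
  depending on tile size and nucleus size); this is inherent to the 0.5
  edge-weight rule.
- Unpaired translation at toy scale demonstrates training behaviour
  (decreasing generator objective, pretraining benefit), not staining
  fidelity.
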