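"""Rule-based IASLC tumor grading from segmentation label maps.

Slide pipeline: per-class area percentages of tissue (background excluded)
-> tumor-normalised low/intermediate/high fractions -> grade. A case is
Grade 3 when the high-grade fraction reaches the 20% threshold (inclusive,
configurable); otherwise the predominant subtype decides (lepidic -> 1,
acinar/papillary -> 2). Case-level grading pools absolute tumor pixel areas
across slides so large sections dominate appropriately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classes import (CLASS_NAMES, N_CLASSES, TUMOR_HIGH, TUMOR_INTERMEDIATE,
                      TUMOR_LOW)

DEFAULT_HIGH_GRADE_THRESHOLD_PCT = 20.0


class NoTumorError(ValueError):
    """The map contains no tumor pixels; the slide is not gradable."""


@dataclass
class AreaFractions:
    """Percentage of tissue area per class 1-7 (background excluded)."""

    pct: dict[int, float]

    def __post_init__(self):
        for k, v in self.pct.items():
            if not 1 <= k < N_CLASSES:
                raise ValueError("class id out of range (background excluded)")
            if not 0 <= v <= 100:
                raise ValueError("percentages must lie in [0, 100]")
        if abs(sum(self.pct.values()) - 100.0) > 1e-6:
            raise ValueError("tissue percentages must sum to 100")

    def get(self, k: int) -> float:
        return self.pct.get(k, 0.0)


@dataclass
class TumorFractions:
    """Low/intermediate/high percentages of total tumor area."""

    low_pct: float
    intermediate_pct: float
    high_pct: float

    def __post_init__(self):
        vals = (self.low_pct, self.intermediate_pct, self.high_pct)
        if any(v < 0 for v in vals):
            raise ValueError("tumor fractions must be nonnegative")
        if abs(sum(vals) - 100.0) > 1e-6:
            raise ValueError("tumor fractions must sum to 100")

    def rounded(self, ndigits: int = 1) -> tuple[float, float, float]:
        return (round(self.low_pct, ndigits), round(self.intermediate_pct, ndigits),
                round(self.high_pct, ndigits))


@dataclass
class GradeResult:
    grade: int
    rule_fired: str
    fractions: TumorFractions
    threshold_pct: float = DEFAULT_HIGH_GRADE_THRESHOLD_PCT

    def to_dict(self) -> dict:
        low, inter, high = self.fractions.rounded()
        return {"grade": self.grade, "rule_fired": self.rule_fired,
                "threshold_pct": self.threshold_pct,
                "tumor_fractions_pct": {"low": low, "intermediate": inter,
                                        "high": high}}


def area_fractions(labels: np.ndarray) -> AreaFractions:
    """Per-class percentage of non-background tissue area in a label map."""
    labels = np.asarray(labels)
    counts = np.bincount(labels.ravel(), minlength=N_CLASSES)
    tissue = counts[1:].sum()
    if tissue == 0:
        raise ValueError("all-background map has no tissue to grade")
    return AreaFractions({k: 100.0 * counts[k] / tissue
                          for k in range(1, N_CLASSES) if counts[k] > 0})


def tumor_fractions(af: AreaFractions) -> TumorFractions:
    """Normalise the three tumor-class percentages to the total tumor area."""
    low = af.get(TUMOR_LOW)
    inter = af.get(TUMOR_INTERMEDIATE)
    high = af.get(TUMOR_HIGH)
    total = low + inter + high
    if total <= 0:
        raise NoTumorError("no tumor area: slide is not gradable")
    return TumorFractions(low_pct=100.0 * low / total,
                          intermediate_pct=100.0 * inter / total,
                          high_pct=100.0 * high / total)


def assign_grade(tf: TumorFractions,
                 threshold_pct: float = DEFAULT_HIGH_GRADE_THRESHOLD_PCT) -> GradeResult:
    """Grade 3 if high-grade >= threshold; otherwise by predominant subtype.

    An exact low/intermediate tie takes the higher grade (conservative).
    Grading uses unrounded fractions.
    """
    if tf.high_pct >= threshold_pct:
        return GradeResult(3, f"high-grade component {tf.high_pct:.1f}% >= "
                              f"{threshold_pct:g}% threshold", tf, threshold_pct)
    if tf.intermediate_pct >= tf.low_pct:
        name = CLASS_NAMES[TUMOR_INTERMEDIATE]
        return GradeResult(2, f"predominant subtype: {name} "
                              f"({tf.intermediate_pct:.1f}%)", tf, threshold_pct)
    name = CLASS_NAMES[TUMOR_LOW]
    return GradeResult(1, f"predominant subtype: {name} ({tf.low_pct:.1f}%)",
                       tf, threshold_pct)


def slide_grade(labels: np.ndarray,
                threshold_pct: float = DEFAULT_HIGH_GRADE_THRESHOLD_PCT) -> GradeResult:
    """Full slide-level pipeline: label map -> grade."""
    return assign_grade(tumor_fractions(area_fractions(labels)), threshold_pct)


def case_grade(slides: list[tuple[AreaFractions, int]],
               threshold_pct: float = DEFAULT_HIGH_GRADE_THRESHOLD_PCT) -> GradeResult:
    """Case-level grade from (area fractions, tissue pixel count) per slide.

    Tumor areas are pooled in absolute pixels, then normalised and graded.
    """
    if not slides:
        raise NoTumorError("no slides provided")
    pooled = {TUMOR_LOW: 0.0, TUMOR_INTERMEDIATE: 0.0, TUMOR_HIGH: 0.0}
    for af, tissue_px in slides:
        if tissue_px < 0:
            raise ValueError("tissue pixel count must be nonnegative")
        for k in pooled:
            pooled[k] += af.get(k) / 100.0 * tissue_px
    total = sum(pooled.values())
    if total <= 0:
        raise NoTumorError("no gradable slide: pooled tumor area is zero")
    tf = TumorFractions(low_pct=100.0 * pooled[TUMOR_LOW] / total,
                        intermediate_pct=100.0 * pooled[TUMOR_INTERMEDIATE] / total,
                        high_pct=100.0 * pooled[TUMOR_HIGH] / total)
    return assign_grade(tf, threshold_pct)
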