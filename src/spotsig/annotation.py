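"""Histopathology-driven spot classification and cell counting.

Each Visium-style spot carries a table of annotation-area fractions
produced upstream by intersecting pathology annotation masks with the
spot circle.  Tissue-level fractions (``tissue``, ``folded_or_lowquality``)
are fractions of the whole spot area; all remaining fractions are
expressed relative to the tissue-containing area of the spot and
therefore sum to at most 1 among themselves.

The classifier applies a fixed rule cascade:

1. exclusion on low tissue content, folded/low-quality tissue or
   dominant luminal space;
2. stromal call when the combined stromal area exceeds 55%, choosing
   between plain and lymphocyte-enriched stroma by the larger
   sub-fraction;
3. a single-class call (ISUP grade, perineural invasion, lymphocytes)
   when that class covers more than half the tissue area;
4. non-cancerous gland (NCG) call at >=30% gland area;
5. exclusion otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import Iterable, Sequence, Tuple


class SpotClass(str, Enum):
    """Histopathology class assigned to one spot."""

    ISUP1 = "ISUP1"
    ISUP2 = "ISUP2"
    ISUP3 = "ISUP3"
    ISUP4 = "ISUP4"
    ISUP5 = "ISUP5"
    ISUPX = "ISUPX"
    ISUPY = "ISUPY"
    PNI = "PNI"
    LYMPHOCYTES = "LYMPHOCYTES"
    STROMA = "STROMA"
    LYMPH_ENRICHED_STROMA = "LYMPH_ENRICHED_STROMA"
    NCG = "NCG"
    EXCLUDED = "EXCLUDED"


#: Cancer grade classes (certain grading).
ISUP_CLASSES = (
    SpotClass.ISUP1,
    SpotClass.ISUP2,
    SpotClass.ISUP3,
    SpotClass.ISUP4,
    SpotClass.ISUP5,
)

#: Classes competing in the single-class (>50%) rule.
SINGLE_CLASS_RULE = ISUP_CLASSES + (
    SpotClass.ISUPX,
    SpotClass.ISUPY,
    SpotClass.PNI,
    SpotClass.LYMPHOCYTES,
)


class AnnotationError(ValueError):
    """Raised for invalid or contradictory annotation fractions."""


@dataclass
class AnnotationFractions:
    """Per-spot annotation-area fractions.

    ``tissue`` and ``folded_or_lowquality`` are fractions of the spot
    area; every other field is a fraction of the tissue-containing area.
    """

    tissue: float = 0.0
    folded_or_lowquality: float = 0.0
    lumen: float = 0.0
    stroma: float = 0.0
    lymphocyte_enriched_stroma: float = 0.0
    isup1: float = 0.0
    isup2: float = 0.0
    isup3: float = 0.0
    isup4: float = 0.0
    isup5: float = 0.0
    isupx: float = 0.0
    isupy: float = 0.0
    pni: float = 0.0
    lymphocytes: float = 0.0
    non_cancer_glands: float = 0.0

    _single_class_map: dict = field(init=False, repr=False, default=None)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name.startswith("_"):
                continue
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0) or math.isnan(v):
                raise AnnotationError(
                    f"fraction {f.name}={v!r} outside [0, 1]"
                )
        self._single_class_map = {
            SpotClass.ISUP1: self.isup1,
            SpotClass.ISUP2: self.isup2,
            SpotClass.ISUP3: self.isup3,
            SpotClass.ISUP4: self.isup4,
            SpotClass.ISUP5: self.isup5,
            SpotClass.ISUPX: self.isupx,
            SpotClass.ISUPY: self.isupy,
            SpotClass.PNI: self.pni,
            SpotClass.LYMPHOCYTES: self.lymphocytes,
        }

    @property
    def stroma_total(self) -> float:
        return self.stroma + self.lymphocyte_enriched_stroma


def classify_spot(f: AnnotationFractions) -> SpotClass:
    """Assign one histopathology class from annotation fractions.

    The rule order is fixed and exhaustive; every valid input maps to
    exactly one class.  Two single-rule classes both above 50% would be
    a contradictory annotation (sub-tissue fractions cannot both exceed
    half the tissue area without overlap) and raise
    :class:`AnnotationError`.
    """
    if f.tissue < 0.50 or f.folded_or_lowquality > 0.50 or f.lumen > 0.80:
        return SpotClass.EXCLUDED

    if f.stroma_total > 0.55:
        # ties favor plain stroma
        if f.lymphocyte_enriched_stroma > f.stroma:
            return SpotClass.LYMPH_ENRICHED_STROMA
        return SpotClass.STROMA

    above = [c for c in SINGLE_CLASS_RULE if f._single_class_map[c] > 0.50]
    if len(above) > 1:
        raise AnnotationError(
            f"contradictory annotation: {[c.value for c in above]} all >50%"
        )
    if above:
        return above[0]

    if f.non_cancer_glands >= 0.30:
        return SpotClass.NCG

    return SpotClass.EXCLUDED


def count_cells_in_spot(
    centroids: Iterable[Tuple[float, float]],
    center: Tuple[float, float],
    radius: float,
) -> int:
    """Count nuclei centroids inside a circular spot.

    The boundary is inclusive: a centroid exactly at distance ``radius``
    counts.  Raises :class:`AnnotationError` for non-positive radii.
    """
    if not radius > 0:
        raise AnnotationError(f"radius must be > 0, got {radius!r}")
    cx, cy = center
    r2 = radius * radius
    n = 0
    for x, y in centroids:
        dx = x - cx
        dy = y - cy
        if dx * dx + dy * dy <= r2:
            n += 1
    return n


def classify_spots_frame(frac_table) -> "Sequence[SpotClass]":
    """Classify every row of a fractions DataFrame.

    The table must carry one column per :class:`AnnotationFractions`
    field.  Returns a list of :class:`SpotClass` in row order.
    """
    names = [f.name for f in fields(AnnotationFractions)
             if not f.name.startswith("_")]
    out = []
    for row in frac_table[names].itertuples(index=False):
        out.append(classify_spot(AnnotationFractions(*row)))
    return out
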