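"""Spatial concordance (Mapcurves GOF) and range-shift summaries.

Two binary range maps are compared by the Mapcurves goodness of fit,

    GOF = sum_i  C_i/(B_i + C_i) * C_i/(A_i + C_i),

where, per category i, C is the cell count of the intersection and A and B
are the counts exclusive to each map (the original Mapcurves convention,
under which identical maps score 1). A "total" convention, where A and B
are the full category totals of each map, is also available; it caps the
single-category GOF at 0.25 for identical maps.

Range shifts between a derived entity and its progenitor are summarized as
the ratio of their range areas and as the percent increase implied by a
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import RasterGrid


@dataclass
class GofResult:
    """Mapcurves concordance between two categorical maps."""

    gof: float
    per_category: list[tuple[int, int, int]]  # (A, B, C) per category
    n_categories: int
    convention: str = "exclusive"


def _category_counts(m1: np.ndarray, m2: np.ndarray, cat: float) -> tuple[int, int, int]:
    in1 = m1 == cat
    in2 = m2 == cat
    c = int(np.sum(in1 & in2))
    a = int(np.sum(in1 & ~in2))
    b = int(np.sum(~in1 & in2))
    return a, b, c


def mapcurves_gof(
    map1: RasterGrid,
    map2: RasterGrid,
    convention: str = "exclusive",
    categories: list[float] | None = None,
) -> GofResult:
    """Mapcurves goodness of fit between two aligned categorical maps.

    For binary range maps only the presence category (value 1) is scored.
    ``convention="exclusive"`` counts A and B net of the intersection;
    ``convention="total"`` uses each map's full category totals (A + C and
    B + C in the exclusive notation).
    """
    if convention not in ("exclusive", "total"):
        raise ValueError("convention must be 'exclusive' or 'total'")
    if map1.shape != map2.shape or map1.transform != map2.transform:
        raise ValueError("maps are not aligned on the same grid")
    valid = (~map1.mask) & (~map2.mask)
    m1 = map1.values[valid]
    m2 = map2.values[valid]
    if categories is None:
        categories = [1.0]
    per_cat: list[tuple[int, int, int]] = []
    gof = 0.0
    any_occupied = False
    for cat in categories:
        a, b, c = _category_counts(m1, m2, cat)
        if a + c > 0 or b + c > 0:
            any_occupied = True
        per_cat.append((a, b, c))
        if convention == "total":
            a, b = a + c, b + c
        if c > 0:
            gof += (c / (b + c)) * (c / (a + c))
    if not any_occupied:
        raise ValueError("both maps are empty for every category; GOF undefined")
    return GofResult(gof=float(gof), per_category=per_cat,
                     n_categories=len(categories), convention=convention)


def range_ratio(area_crop: float, area_progenitor: float) -> float:
    """Range-area ratio (derived / progenitor), reported to two decimals."""
    if area_progenitor <= 0:
        raise ZeroDivisionError("progenitor range area must be positive")
    return round(area_crop / area_progenitor, 2)


def percent_increase(ratio: float) -> int:
    """Percent increase implied by a range or breadth ratio: (ratio - 1) * 100."""
    if ratio <= 0:
        raise ValueError("ratio must be positive")
    return int(round((ratio - 1.0) * 100.0))
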