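"""Climate predictor assembly: derived layers, point extraction, scaling.

The working predictor set is the 19 bioclim variables plus two derived
layers: growing degree days (GDD, truncated sum of monthly mean temperature
above a base, weighted by calendar day counts) and an aridity index
(annual precipitation / annual potential evapotranspiration).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .occurrence_prep import OccurrenceSet
from .raster import PredictorStack, RasterGrid

logger = logging.getLogger(__name__)

GDD_BASE_C = 5.0
#: day count per month, non-leap year (365 days total)
MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

TMEAN_NAMES = [f"tmean{m:02d}" for m in range(1, 13)]
BIO_NAMES = [f"bio{i}" for i in range(1, 20)]
#: the 21-predictor convention: 19 bioclim + derived gdd and arid
PREDICTOR_NAMES = BIO_NAMES + ["gdd", "arid"]


@dataclass
class SampleMatrix:
    """Predictor values sampled at points (occurrences or background cells)."""

    values: pd.DataFrame  # rows = points, columns = predictor names
    group: str = ""
    n_dropped: int = 0  # rows removed because a predictor was masked

    @property
    def columns(self) -> list[str]:
        return list(self.values.columns)

    def __len__(self) -> int:
        return len(self.values)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)


def compute_gdd(
    monthly_means: list[RasterGrid],
    base: float = GDD_BASE_C,
    day_weighted: bool = True,
) -> RasterGrid:
    """Growing degree days from 12 monthly mean temperature layers (deg C).

    GDD = sum_m max(0, T_m - base) * d_m with d_m the calendar day count of
    month m (non-leap year). ``day_weighted=False`` uses a uniform 365/12
    days per month instead.
    """
    if len(monthly_means) != 12:
        raise ValueError(f"expected exactly 12 monthly layers, got {len(monthly_means)}")
    days = MONTH_DAYS if day_weighted else np.full(12, 365.0 / 12.0)
    first = monthly_means[0]
    acc = np.zeros(first.shape, dtype=float)
    mask = np.zeros(first.shape, dtype=bool)
    for layer, d in zip(monthly_means, days):
        if layer.shape != first.shape or layer.transform != first.transform:
            raise ValueError("monthly layers are not aligned")
        acc += np.maximum(0.0, np.where(layer.mask, 0.0, layer.values) - base) * d
        mask |= layer.mask
    return RasterGrid(np.where(mask, np.nan, acc), first.transform, mask=mask)


def compute_aridity(annual_precip: RasterGrid, annual_pet: RasterGrid) -> RasterGrid:
    """Aridity index = annual precipitation / annual potential evapotranspiration.

    Cells where PET <= 0 are masked as missing (logged), not propagated as
    infinities.
    """
    if annual_precip.shape != annual_pet.shape or annual_precip.transform != annual_pet.transform:
        raise ValueError("precipitation and PET layers are not aligned")
    mask = annual_precip.mask | annual_pet.mask
    bad_pet = (~mask) & (annual_pet.values <= 0)
    if bad_pet.any():
        logger.warning("aridity: masked %d cells with PET <= 0", int(bad_pet.sum()))
    mask = mask | bad_pet
    with np.errstate(divide="ignore", invalid="ignore"):
        arid = annual_precip.values / annual_pet.values
    return RasterGrid(np.where(mask, np.nan, arid), annual_precip.transform, mask=mask)


def add_derived_layers(
    stack: PredictorStack,
    precip_layer: str = "bio12",
    pet_layer: str = "pet",
    base: float = GDD_BASE_C,
) -> PredictorStack:
    """Append gdd and arid layers computed from the stack's monthly/annual layers."""
    monthly = [stack[n] for n in TMEAN_NAMES]
    out = PredictorStack(dict(stack.layers), latent=stack.latent)
    out.add("gdd", compute_gdd(monthly, base=base))
    out.add("arid", compute_aridity(stack[precip_layer], stack[pet_layer]))
    return out


def extract_at_points(
    stack: PredictorStack,
    occ: OccurrenceSet,
    names: list[str] | None = None,
) -> SampleMatrix:
    """Nearest-cell predictor values at occurrence locations.

    Points falling outside the raster extent or in a cell masked in any
    requested layer are dropped (count recorded on the result). Raises if no
    point yields a complete row.
    """
    names = names if names is not None else stack.names
    sub = stack.subset(names)
    valid = sub.combined_valid()
    rows = []
    n_dropped = 0
    for lon, lat in occ.coords:
        idx = stack.transform.index_of(lon, lat, stack.shape)
        if idx is None or not valid[idx]:
            n_dropped += 1
            continue
        rows.append([sub[n].values[idx] for n in names])
    if not rows:
        raise ValueError(f"{occ.taxon}: no occurrence falls on a valid raster cell")
    if n_dropped:
        logger.info("%s: dropped %d points outside valid raster cells", occ.taxon, n_dropped)
    df = pd.DataFrame(rows, columns=names)
    return SampleMatrix(df, group=occ.taxon, n_dropped=n_dropped)


def min_max_scale(
    matrix: SampleMatrix, reference: SampleMatrix | None = None
) -> SampleMatrix:
    """Min–max feature scaling: x -> (x - min)/(max - min) per column.

    Column minima/maxima come from ``reference`` (default: the matrix
    itself). Degenerate columns (max == min in the reference) map to 0 with
    a warning. Scaling twice with the same reference is idempotent only on
    the first application's output range; for comparisons the same
    reference must be used for both groups.
    """
    ref = reference if reference is not None else matrix
    missing = [c for c in matrix.columns if c not in ref.columns]
    if missing:
        raise KeyError(f"reference lacks columns: {missing}")
    lo = ref.values[matrix.columns].min(axis=0)
    hi = ref.values[matrix.columns].max(axis=0)
    span = hi - lo
    degenerate = span == 0
    if degenerate.any():
        logger.warning(
            "min_max_scale: %d degenerate (constant) columns mapped to 0",
            int(degenerate.sum()),
        )
    span = span.where(~degenerate, 1.0)
    scaled = (matrix.values - lo) / span
    scaled.loc[:, degenerate[degenerate].index] = 0.0
    return SampleMatrix(scaled, group=matrix.group, n_dropped=matrix.n_dropped)


def pooled_reference(a: SampleMatrix, b: SampleMatrix) -> SampleMatrix:
    """Stack two sample matrices (shared columns) into one pooled reference."""
    cols = [c for c in a.columns if c in b.columns]
    pooled = pd.concat([a.values[cols], b.values[cols]], ignore_index=True)
    return SampleMatrix(pooled, group=f"{a.group}+{b.group}")
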