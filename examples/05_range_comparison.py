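"""Compare two binary range maps: Mapcurves concordance and range shifts.

Builds two overlapping toy ranges, computes the Mapcurves goodness of fit
(1 for identical maps, 0 for disjoint ones), the range-area ratio and the
percent increase it implies.
"""

import numpy as np

from nichedyn import (
    GridTransform,
    RasterGrid,
    mapcurves_gof,
    percent_increase,
    range_area_km2,
    range_ratio,
)

t = GridTransform(west=-10.0, north=10.0, cellsize=0.5)
crop = np.zeros((40, 40))
crop[5:30, 5:35] = 1.0        # a broad range
progenitor = np.zeros((40, 40))
progenitor[10:20, 8:18] = 1.0  # a small range nested inside it

crop_map = RasterGrid(crop, t)
prog_map = RasterGrid(progenitor, t)

gof = mapcurves_gof(crop_map, prog_map)
a, b, c = gof.per_category[0]
print(f"Mapcurves GOF = {gof.gof:.3f}  (A={a} cells only crop, B={b} only progenitor, C={c} shared)")

area_crop = range_area_km2(crop_map)
area_prog = range_area_km2(prog_map)
ratio = range_ratio(area_crop, area_prog)
print(f"range areas: crop {area_crop:,.0f} km^2, progenitor {area_prog:,.0f} km^2")
print(f"range ratio {ratio:.2f} -> range size increased by {percent_increase(ratio)}%")
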