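"""Clean and spatially rarefy an occurrence table.

Shows the uncertainty filter (drop records located to worse than 10 km),
coordinate deduplication, and greedy 10-km spatial thinning — the standard
pre-processing before any niche or distribution modelling.
"""

import numpy as np
import pandas as pd

from nichedyn import OccurrenceSet, clean_records, haversine_km, rarefy

raw = OccurrenceSet(
    "zea",
    pd.DataFrame(
        {
            "taxon": ["zea"] * 6,
            "lon": [0.00, 0.05, 0.00, 3.00, 3.00, 200.0],
            "lat": [0.00, 0.05, 0.00, 4.00, 4.00, 0.0],
            "uncertainty_km": [1.0, 2.0, 1.0, 50.0, np.nan, 1.0],
        }
    ),
)
print(f"raw records: {len(raw)}")

cleaned = clean_records(raw, max_uncertainty_km=10.0)
print(f"after cleaning: {len(cleaned)} "
      "(dropped: one 50-km-uncertainty record, one duplicate, one off-globe coordinate)")

thinned = rarefy(cleaned, radius_km=10.0, seed=0)
print(f"after 10-km rarefaction: {len(thinned)}")
d = haversine_km(0.0, 0.0, 0.05, 0.05)
print(f"the two nearby points were {d:.2f} km apart, so only one survives thinning")
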