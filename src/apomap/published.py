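"""Published national yearly counts of the four adverse pregnancy outcomes.

These are the reported Kenya DHIS2 national totals for 2016-2019 (events
aggregated over all sub-counties) and the reported national live-birth
total for the same window.  They are inputs for the descriptive reporting
layer — totals, percent changes and crude rates are recomputed from them —
not outputs of this package's model.
"""

from __future__ import annotations

import pandas as pd

YEARS = (2016, 2017, 2018, 2019)

OUTCOME_COUNTS = {
    "Low Birth Weight": (38_440, 23_162, 43_150, 46_051),
    "Stillbirths": (16_888, 11_381, 17_781, 17_810),
    "Pre-term births": (23_597, 15_672, 24_976, 27_437),
    "Neonatal deaths": (9_891, 5_688, 9_959, 10_157),
}

TOTAL_LIVE_BIRTHS = 2_896_659          # 2016-2019, all sub-counties

# reported national stillbirth rate per 1,000 live births, first/last year
STILLBIRTH_RATE_2016 = 19.4
STILLBIRTH_RATE_2019 = 18.1


def national_counts() -> pd.DataFrame:
    """Outcome x year table of the published national event counts."""
    return pd.DataFrame.from_dict(OUTCOME_COUNTS, orient="index",
                                  columns=list(YEARS))
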