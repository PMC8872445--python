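"""Published case-study tables used as worked-example inputs.

The package's worked example is a ~1455 km² mountainous district in western
Beijing with a 2014 land-cover composition, a business-as-usual 2030
projection ("scenario 1") and a suitability-constrained optimized 2030
structure ("scenario 2"), together with the district's published land-
suitability structure and ecosystem-service totals.  These are printed
summary tables (the underlying rasters were never deposited), so they feed
the composition-only computations — carbon stocks, scenario change tables,
suitability accounting — and serve as consistency fixtures.
"""

from __future__ import annotations

import pandas as pd

#: District total area covered by the suitability evaluation (km²).
TOTAL_AREA_KM2 = 1454.88

#: Land-cover composition (km²) for 2014 and the two 2030 scenarios.
COMPOSITIONS: dict[str, dict[str, float]] = {
    "2014": {
        "CL": 9.93, "OC": 53.21, "FL": 556.54, "SL": 689.23, "GL": 17.98,
        "WB": 16.45, "BUL": 86.27, "WL": 24.05, "BL": 1.22,
    },
    "scenario_1": {
        "CL": 5.07, "OC": 41.43, "FL": 503.07, "SL": 759.39, "GL": 13.05,
        "WB": 16.17, "BUL": 90.81, "WL": 25.27, "BL": 0.61,
    },
    "scenario_2": {
        "CL": 9.93, "OC": 53.21, "FL": 579.45, "SL": 689.23, "GL": 0.19,
        "WB": 22.33, "BUL": 99.32, "WL": 0.00, "BL": 1.22,
    },
}

#: Suitability structure (km²): rows appropriate / relatively appropriate /
#: inappropriate, columns the five evaluated classes.
SUITABILITY_STRUCTURE: dict[str, dict[str, float]] = {
    "CL": {"appropriate": 16.45, "relatively_appropriate": 497.91, "inappropriate": 940.52},
    "OC": {"appropriate": 27.79, "relatively_appropriate": 1102.86, "inappropriate": 324.23},
    "FL": {"appropriate": 1341.78, "relatively_appropriate": 9.16, "inappropriate": 103.94},
    "GL": {"appropriate": 1331.26, "relatively_appropriate": 19.68, "inappropriate": 103.94},
    "SL": {"appropriate": 1346.02, "relatively_appropriate": 4.92, "inappropriate": 103.94},
}

#: Published ecosystem-service totals per scenario (native units).
ES_TOTALS: dict[str, dict[str, float]] = {
    "2014":       {"WY_m3": 2.02e8, "CS_t": 1713.54e4, "SC_t": 0.50e8, "SLO_t": 0.66e6},
    "scenario_1": {"WY_m3": 1.86e8, "CS_t": 1707.39e4, "SC_t": 0.42e8, "SLO_t": 0.74e6},
    "scenario_2": {"WY_m3": 2.65e8, "CS_t": 1707.53e4, "SC_t": 0.56e8, "SLO_t": 0.60e6},
}


def compositions() -> pd.DataFrame:
    """Class compositions (km²) as a classes × scenarios frame."""
    return pd.DataFrame(COMPOSITIONS)


def suitability_structure() -> pd.DataFrame:
    """Suitability structure (km²) as a grades × classes frame."""
    return pd.DataFrame(SUITABILITY_STRUCTURE)


def es_totals() -> pd.DataFrame:
    """Service totals as a services × scenarios frame."""
    return pd.DataFrame(ES_TOTALS)
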