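"""Published reference data from the phantom measurement campaign.

These tables are the printed inputs the worked examples and projections
operate on: the measured conversion coefficients per projection and target
(µGy per Gy·cm², acquisition mode for the nine standard projections plus an
extra-large-patient and a fluoroscopy variant of LAO30), the clinically
weighted CC row derived from two months of dose-monitoring exports, the
in-range clinical P_KA totals, and a routine annual workload for one
operator.  All derived quantities (ratios, annual doses, years-to-threshold)
are recomputed from these inputs by the package, never stored.
"""

from __future__ import annotations

import pandas as pd

from .mapping import CC_TABLE_COLUMNS
from .projection import ShieldingScenario, WorkloadItem, WorkloadSpec

__all__ = [
    "MEASURED_CC_TABLE",
    "WEIGHTED_CCS",
    "FLUORO_REFERENCE_PROJECTION",
    "CLINICAL_IN_RANGE_PKA_GYCM2",
    "CLINICAL_FLUORO_PKA_GYCM2",
    "CLINICAL_EVENTS_TOTAL",
    "CLINICAL_EVENTS_IN_RANGE",
    "DEFAULT_WORKLOAD",
    "CEILING_SHIELD_SCENARIO",
    "FULL_PROTECTION_SCENARIO",
]

_CC_ROWS = {
    #                 whole  left  right upper lower front rear  l_eye r_eye
    "PA":            (0.36, 0.47, 0.25, 0.30, 0.47, 0.45, 0.32, 1.69, 1.09),
    "LAO30":         (0.92, 1.18, 0.66, 0.88, 0.99, 1.07, 0.83, 3.87, 1.78),
    "RAO30":         (0.34, 0.40, 0.27, 0.34, 0.34, 0.44, 0.28, 1.76, 1.52),
    "CAUD30":        (0.32, 0.39, 0.25, 0.35, 0.26, 0.41, 0.27, 1.17, 0.80),
    "CRAN30":        (0.80, 0.99, 0.60, 0.74, 0.91, 1.01, 0.68, 4.78, 3.69),
    "LAO30/CAUD30":  (0.63, 0.84, 0.42, 0.54, 0.79, 0.66, 0.62, 2.03, 0.91),
    "LAO30/CRAN30":  (0.82, 1.00, 0.63, 0.77, 0.90, 1.05, 0.68, 5.47, 4.83),
    "RAO30/CAUD30":  (0.14, 0.15, 0.12, 0.12, 0.17, 0.15, 0.12, 0.52, 0.46),
    "RAO30/CRAN30":  (0.77, 0.92, 0.62, 0.79, 0.74, 1.09, 0.59, 4.40, 4.01),
    "LAO30_XL":      (0.85, 1.07, 0.62, 0.80, 0.94, 1.00, 0.76, 3.56, 1.66),
    "LAO30_FL":      (1.33, 1.71, 0.94, 1.30, 1.39, 1.59, 1.18, 5.04, 2.56),
}

#: Measured CCs per configuration (rows) and target (columns), µGy/(Gy·cm²).
#: LAO30_XL is the extra-large-patient sensitivity row; LAO30_FL is the single
#: fluoroscopy measurement used as the fluoroscopy/acquisition reference.
MEASURED_CC_TABLE = pd.DataFrame.from_dict(
    _CC_ROWS, orient="index", columns=CC_TABLE_COLUMNS
).rename_axis(index="configuration")

#: Clinically weighted CCs per target, µGy/(Gy·cm²), as published.
WEIGHTED_CCS = dict(
    zip(CC_TABLE_COLUMNS, (0.70, 0.89, 0.52, 0.66, 0.79, 0.86, 0.61, 3.39, 2.32))
)

#: Projection at which the fluoroscopy/acquisition CC ratio was measured.
FLUORO_REFERENCE_PROJECTION = "LAO30"

#: Clinical P_KA totals within +-45 deg on both axes, Gy·cm², two months of
#: dose-monitoring exports (25 552 events from 249 cardiac procedures).
CLINICAL_IN_RANGE_PKA_GYCM2 = 5324.6
CLINICAL_FLUORO_PKA_GYCM2 = 3415.5
CLINICAL_EVENTS_TOTAL = 25_552
CLINICAL_EVENTS_IN_RANGE = 24_913

#: Routine annual workload of one operator: coronary angiography (CA),
#: percutaneous coronary intervention (PCI), combined CA/PCI and
#: transcatheter aortic valve implantation (TAVI), with mean P_KA per
#: procedure in Gy·cm².  Totals 11 050 Gy·cm² per year.
DEFAULT_WORKLOAD = WorkloadSpec(
    items=(
        WorkloadItem("CA", 150, 10.0),
        WorkloadItem("PCI", 10, 25.0),
        WorkloadItem("CA/PCI", 150, 29.0),
        WorkloadItem("TAVI", 150, 33.0),
    )
)

#: A correctly used ceiling-suspended shield reduces scatter by >= 75%.
CEILING_SHIELD_SCENARIO = ShieldingScenario(name="ceiling_shield", ceiling_shield=0.25)
#: Leaded eyewear reduces eye-lens dose by >= a further 30%.
FULL_PROTECTION_SCENARIO = ShieldingScenario(
    name="ceiling_shield+eyewear", ceiling_shield=0.25, eyewear=0.70
)

#: The measured rows of the CC table (excludes derived/weighted rows).
MEASURED_ROWS = tuple(_CC_ROWS)
#: The nine standard-projection acquisition rows.
ACQUISITION_ROWS = tuple(r for r in _CC_ROWS if r not in ("LAO30_XL", "LAO30_FL"))
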