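"""Reference cohort-level results shipped with the package.

``pilot_cohort_table()`` returns the cohort-mean percent-change matrix
reported by the ten-infant NICU pilot cohort this package operationalizes:
for each quantifier and body region, the mean percentage change in movement
level between 30 s windows recorded near NICU admission and near hospital
discharge.  These numbers are *inputs* (published cohort-level results, not
recomputable from raw data here); the package's cohort operations derive
the Average column and the region-vs-whole-body similarity matrix from
them, which serves as an arithmetic cross-check of those operations.
"""

from __future__ import annotations

import pandas as pd

from .cohort import TABLE_REGION_ORDER

_PILOT_ROWS: dict[str, tuple[float, ...]] = {
    # whole_body, head, left_arm, right_arm, left_leg, right_leg, trunk,
    # upper_body, lower_body
    "euclidean": (86.70, 118.16, 82.69, 141.76, 77.35, 105.28, 106.78, 98.68, 86.56),
    "manhattan": (76.67, 93.14, 67.26, 102.90, 71.71, 92.30, 89.02, 79.60, 80.88),
    "chebyshev": (78.57, 100.59, 64.25, 102.81, 63.06, 89.61, 86.42, 81.98, 76.14),
    "minkowski": (77.78, 98.40, 64.91, 101.45, 64.72, 89.87, 87.39, 80.99, 77.09),
    "mahalanobis": (77.34, 96.66, 65.56, 101.56, 66.77, 90.47, 87.95, 80.45, 78.14),
    "diffacc": (76.12, 92.33, 66.44, 104.22, 70.89, 92.77, 89.76, 78.91, 80.90),
    "angular": (84.40, 122.48, 79.19, 139.48, 71.72, 106.20, 104.39, 95.36, 84.58),
    "lucas_kanade": (55.38, 102.35, 67.52, 76.55, 67.98, 90.91, 67.75, 55.35, 74.00),
    "farneback": (127.01, 101.50, 1054.57, 2304.37, 953.76, 1237.19, 240.27, 440.29, 794.18),
}


def pilot_cohort_table() -> pd.DataFrame:
    """Methods x regions matrix of published mean percent changes."""
    return pd.DataFrame.from_dict(
        _PILOT_ROWS, orient="index", columns=list(TABLE_REGION_ORDER)
    ).rename_axis("method")
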