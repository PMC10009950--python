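"""Default cohort profile and biomarker cutoffs.

The numbers below describe a large cross-sectional memory-clinic cohort
(n = 437) that is deeply phenotyped with CSF biomarkers and structural MRI:
per-ATN-group sample sizes, demographic summaries, and per-group biomarker
means/SDs.  They serve two purposes:

* as the default parameters of the synthetic-data generator, so simulated
  cohorts reproduce the group structure and bimodal marker distributions the
  analysis assumes (rare groups stay rare, markers separate by status);
* as a published mean-profile panel against which the fixed cutoffs can be
  sanity-checked (each group's mean marker values classify back into that
  group's own A/T/N status).

Units: abeta_ratio is the unitless CSF Aβ42/Aβ40 ratio; ptau and ttau are
pg/ml; adjusted hippocampal volume (aHV) is μl; TICV and WMH are ml.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "GROUP_SIZES",
    "GROUP_PROFILE",
    "FIXED_CUTOFFS",
    "TOTAL_N",
    "group_profile_frame",
]

#: Subjects per ATN group (canonical group order), totalling 437.
GROUP_SIZES: dict[str, int] = {
    "A-T-N-": 143,
    "A-T-N+": 41,
    "A-T+N-": 29,
    "A-T+N+": 14,
    "A+T-N-": 45,
    "A+T-N+": 23,
    "A+T+N-": 61,
    "A+T+N+": 81,
}

TOTAL_N: int = sum(GROUP_SIZES.values())

#: Fixed operational cutoffs: A+ below 0.09 (ratio), T+ above 57 pg/ml,
#: N+ below 2821.1 μl (aHV mode) or above 470 pg/ml (total-tau mode).
FIXED_CUTOFFS: dict[str, float] = {
    "abeta_ratio": 0.09,
    "ptau": 57.0,
    "ahv": 2821.1,
    "ttau": 470.0,
}

#: Per-group (mean, sd) summaries.  aHV is stored in μl (the table's ml
#: values times 1000); WMH is the observed mean/SD of a right-skewed marker.
GROUP_PROFILE: dict[str, dict[str, tuple[float, float]]] = {
    "A-T-N-": {
        "age": (69.64, 5.50), "pct_female": (48.25, 0.0),
        "education": (14.65, 2.92), "abeta_ratio": (0.110, 0.011),
        "ptau": (41.02, 8.81), "ttau": (288.18, 89.16),
        "ahv": (3140.0, 210.0), "wmh": (3.29, 5.31),
    },
    "A-T-N+": {
        "age": (68.10, 5.85), "pct_female": (48.78, 0.0),
        "education": (14.71, 2.87), "abeta_ratio": (0.108, 0.011),
        "ptau": (39.85, 11.84), "ttau": (291.24, 131.09),
        "ahv": (2640.0, 150.0), "wmh": (3.27, 6.07),
    },
    "A-T+N-": {
        "age": (70.20, 4.56), "pct_female": (72.41, 0.0),
        "education": (13.79, 2.02), "abeta_ratio": (0.112, 0.013),
        "ptau": (68.02, 10.88), "ttau": (465.98, 115.59),
        "ahv": (3180.0, 240.0), "wmh": (1.42, 1.70),
    },
    "A-T+N+": {
        "age": (70.86, 5.90), "pct_female": (28.57, 0.0),
        "education": (16.57, 2.53), "abeta_ratio": (0.118, 0.014),
        "ptau": (74.68, 19.41), "ttau": (544.38, 167.71),
        "ahv": (2630.0, 110.0), "wmh": (2.09, 2.83),
    },
    "A+T-N-": {
        "age": (69.97, 5.12), "pct_female": (42.22, 0.0),
        "education": (14.07, 2.53), "abeta_ratio": (0.074, 0.012),
        "ptau": (41.88, 9.99), "ttau": (321.41, 104.50),
        "ahv": (3120.0, 210.0), "wmh": (3.19, 3.61),
    },
    "A+T-N+": {
        "age": (70.91, 7.10), "pct_female": (39.13, 0.0),
        "education": (14.43, 3.19), "abeta_ratio": (0.064, 0.015),
        "ptau": (44.49, 9.40), "ttau": (312.96, 94.48),
        "ahv": (2600.0, 210.0), "wmh": (4.66, 6.05),
    },
    "A+T+N-": {
        "age": (73.20, 5.30), "pct_female": (47.54, 0.0),
        "education": (13.67, 3.33), "abeta_ratio": (0.053, 0.011),
        "ptau": (93.26, 50.38), "ttau": (677.41, 335.83),
        "ahv": (3120.0, 230.0), "wmh": (6.99, 11.61),
    },
    "A+T+N+": {
        "age": (73.46, 5.84), "pct_female": (55.56, 0.0),
        "education": (13.75, 2.98), "abeta_ratio": (0.050, 0.013),
        "ptau": (95.06, 31.09), "ttau": (778.43, 287.03),
        "ahv": (2560.0, 220.0), "wmh": (6.34, 7.96),
    },
}


def group_profile_frame() -> pd.DataFrame:
    """Per-group mean values as a DataFrame (groups × markers), plus size."""
    rows = {}
    for grp, stats in GROUP_PROFILE.items():
        rows[grp] = {k: v[0] for k, v in stats.items()}
        rows[grp]["n"] = GROUP_SIZES[grp]
    return pd.DataFrame.from_dict(rows, orient="index")
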