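"""Reference pediatric cohort used in worked examples and protocol checks.

Twenty pediatric cardiology patients (ages 5-17) with congenital or
acquired heart disease: age, sex, body weight, body height and mean
R-R interval.  These descriptives drive the worked examples for the
DuBois body-surface-area calculation and the per-patient choice of the
binning cycle length.  Cohort summary statistics are reported as
mean ± SD with the population divisor (n).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reference_cohort"]

_ROWS = [
    # patient, age_years, sex, weight_kg, height_cm, bsa_m2, rr_ms
    # bsa_m2 is the recorded per-patient DuBois value (1 decimal); for two
    # patients it reflects unrounded weight/height and differs by ~0.05 from
    # DuBois applied to the rounded columns here
    (1, 13, "F", 52, 160, 1.5, 700),
    (2, 15, "M", 64, 178, 1.8, 750),
    (3, 8, "F", 23, 124, 0.9, 640),
    (4, 7, "F", 22, 122, 0.9, 500),
    (5, 14, "M", 70, 189, 2.0, 990),
    (6, 10, "F", 65, 153, 1.6, 850),
    (7, 17, "M", 42, 167, 1.4, 525),
    (8, 17, "M", 94, 193, 2.3, 950),
    (9, 11, "F", 30, 153, 1.2, 700),
    (10, 15, "F", 55, 154, 1.5, 875),
    (11, 11, "M", 49, 172, 1.6, 740),
    (12, 14, "M", 78, 187, 2.0, 700),
    (13, 17, "M", 55, 160, 1.6, 900),
    (14, 17, "M", 92, 180, 2.1, 840),
    (15, 10, "M", 48, 146, 1.4, 750),
    (16, 10, "M", 33, 133, 1.1, 530),
    (17, 14, "F", 64, 165, 1.7, 750),
    (18, 16, "M", 58, 181, 1.8, 800),
    (19, 5, "F", 15, 101, 0.6, 650),
    (20, 15, "M", 85, 183, 2.1, 800),
]


def reference_cohort() -> pd.DataFrame:
    """The reference cohort as a DataFrame (one row per patient)."""
    return pd.DataFrame(
        _ROWS,
        columns=["patient", "age_years", "sex", "weight_kg", "height_cm", "bsa_m2", "rr_ms"],
    )
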