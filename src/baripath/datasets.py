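"""Small built-in datasets.

Currently a single table: the clinical profiles of the 13 human donors
(4 from the Mild, 9 from the Severe 5-year T2D-severity cluster) whose
stool was transplanted into mice.  These clinical values are used
by the worked examples and by the donor-level group comparisons.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["fmt_donor_profiles"]

_DONORS = [
    # donor, cluster, dr_status, treatment_group, age, weight_kg, bmi,
    # weight_loss_1y_pct, weight_change_1_5y_pct, t2d_duration_y, hba1c_pct,
    # fbg_mmol_l, n_glucose_drugs, insulin_use, metformin_use
    ("Mild-1", "Mild", "DR", "none", 47.7, 79.0, 30.9, -24.9, 5.9, 6.2, 5.5, 5.5, 0, False, False),
    ("Mild-2", "Mild", "DR", "none", 59.2, 74.8, 30.0, -34.1, 5.5, 10.2, 6.1, 4.8, 0, False, False),
    ("Mild-3", "Mild", "DR", "none", 65.5, 74.5, 29.5, -39.0, 2.2, 17.5, 5.2, 4.3, 0, False, False),
    ("Mild-4", "Mild", "DR", "none", 68.1, 77.5, 27.5, -33.6, 3.2, 11.8, 5.9, 5.6, 0, False, False),
    ("Severe-1", "Severe", "non-DR", "metformin+insulin", 54.8, 80.0, 34.6, -23.1, 4.7, 23.6, 7.3, 3.7, 2, True, True),
    ("Severe-2", "Severe", "non-DR", "metformin+insulin", 55.2, 86.0, 32.4, -40.6, 14.1, 12.3, 7.0, 8.3, 2, True, True),
    ("Severe-3", "Severe", "non-DR", "metformin+insulin", 59.1, 94.0, 37.7, -17.4, -8.0, 18.9, 6.6, 6.6, 2, True, True),
    ("Severe-4", "Severe", "non-DR", "insulin-only", 67.5, 115.0, 40.7, -14.6, -7.3, 30.2, 6.9, 7.0, 2, True, False),
    ("Severe-5", "Severe", "non-DR", "insulin-only", 59.0, 68.0, 28.3, -28.4, -19.8, 25.1, 7.9, 7.7, 2, True, False),
    ("Severe-6", "Severe", "non-DR", "insulin-only", 63.8, 85.0, 30.1, -16.6, -18.5, 11.0, 10.2, 8.9, 2, True, False),
    ("Severe-7", "Severe", "non-DR", "metformin-only", 68.9, 69.0, 31.5, -35.3, 12.0, 8.5, 6.7, 8.2, 1, False, True),
    ("Severe-8", "Severe", "non-DR", "metformin-only", 60.3, 79.0, 29.0, -34.8, 5.8, 25.1, 7.6, 8.8, 1, False, True),
    ("Severe-9", "Severe", "non-DR", "metformin-only", 64.3, 67.0, 24.6, -28.6, -5.5, 17.8, 7.2, 8.7, 1, False, True),
]

_COLUMNS = [
    "donor", "cluster", "dr_status", "treatment_group", "age", "weight_kg",
    "bmi", "weight_loss_1y_pct", "weight_change_1_5y_pct", "t2d_duration",
    "hba1c", "fbg", "n_glucose_drugs", "insulin_use", "metformin_use",
]


def fmt_donor_profiles() -> pd.DataFrame:
    """Clinical profiles of the 13 FMT donors, one row per donor.

    Glucose-lowering drug counts are binned at 2 (``2`` means "two or
    more").  All Mild donors were in diabetes remission and medication
    free; all Severe donors were not.
    """
    return pd.DataFrame(_DONORS, columns=_COLUMNS).set_index("donor")
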