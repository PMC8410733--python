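"""Paediatric dosage-card calculators for [18F]FDG torso examinations.

Two published recommendation schemes are implemented:

* the EANM paediatric dosage card — recommended activity = baseline
  activity (25.9 MBq for FDG torso) x a weight-dependent multiple from the
  class-B column of the card, floored at a 26 MBq minimum;
* the North-American consensus — a weight-proportional scheme of
  3.7-5.2 MBq/kg with the same 26 MBq minimum.

Both anchor at the card's maximum: 68 kg -> 25.9 x 14.0 = 362.6 MBq (EANM)
and 68 x 5.2 = 353.6 MBq (North-American).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .phantom import PatientMeta, cohort_fixture

__all__ = [
    "EANM_BASELINE_MBQ", "MINIMUM_ACTIVITY_MBQ", "EANM_CLASS_B_MULTIPLES",
    "NA_PER_KG_RANGE", "eanm_recommended", "na_recommended",
    "cohort_vs_recommendation", "cohort_summary",
]

#: EANM baseline activity for [18F]FDG torso, MBq.
EANM_BASELINE_MBQ = 25.9

#: Minimum injected activity, MBq (shared by both schemes).
MINIMUM_ACTIVITY_MBQ = 26.0

#: North-American consensus weight-based range, MBq/kg.
NA_PER_KG_RANGE = (3.7, 5.2)

#: EANM dosage card, class B: weight (kg) -> multiple of the baseline
#: activity.  Published card rows; weights between rows use the nearest row.
EANM_CLASS_B_MULTIPLES: tuple[tuple[float, float], ...] = (
    (3, 1.00), (4, 1.14), (6, 1.71), (8, 2.14), (10, 2.71), (12, 3.14),
    (14, 3.57), (16, 4.00), (18, 4.43), (20, 4.86), (22, 5.29), (24, 5.71),
    (26, 6.14), (28, 6.43), (30, 6.86), (32, 7.29), (34, 7.72), (36, 8.00),
    (38, 8.43), (40, 8.86), (42, 9.14), (44, 9.57), (46, 10.00), (48, 10.29),
    (50, 10.71), (52, 11.29), (54, 11.29), (56, 12.00), (58, 12.00),
    (60, 12.71), (62, 12.71), (64, 13.43), (66, 13.43), (68, 14.00),
)

_CARD_WEIGHTS = np.array([w for w, _ in EANM_CLASS_B_MULTIPLES])
_CARD_MULTIPLES = np.array([m for _, m in EANM_CLASS_B_MULTIPLES])


def eanm_recommended(weight: float) -> float:
    """EANM class-B recommended [18F]FDG activity (MBq) for a body weight.

    Baseline x the class-B multiple at the nearest card weight, floored at
    the 26 MBq minimum; weights above the last card row (68 kg) use the
    card's maximum multiple (14.0 -> 362.6 MBq).
    """
    if not (3.0 <= weight <= 110.0):
        raise ValueError(f"weight {weight} kg outside the dosage-card range [3, 110]")
    idx = int(np.argmin(np.abs(_CARD_WEIGHTS - weight)))
    activity = EANM_BASELINE_MBQ * _CARD_MULTIPLES[idx]
    return max(float(activity), MINIMUM_ACTIVITY_MBQ)


def na_recommended(weight: float, per_kg: float = 5.2) -> float:
    """North-American consensus recommended activity (MBq): weight x per-kg.

    ``per_kg`` must lie within the consensus range 3.7-5.2 MBq/kg; the
    result is floored at the 26 MBq minimum.
    """
    if weight <= 0:
        raise ValueError("weight must be positive")
    lo, hi = NA_PER_KG_RANGE
    if not (lo <= per_kg <= hi):
        raise ValueError(f"per_kg {per_kg} outside the consensus range [{lo}, {hi}]")
    return max(float(weight * per_kg), MINIMUM_ACTIVITY_MBQ)


def cohort_vs_recommendation(
    cohort: list[PatientMeta] | None = None,
    levels: tuple[float, ...] = (1.0, 0.75, 0.50, 0.35, 0.20, 0.10),
) -> pd.DataFrame:
    """Injected / EANM-recommended fraction per patient and virtual level.

    Multiplying the injected activity by a virtual count level scales the
    fraction linearly, so the 0.75-level column is exactly 0.75 x the
    full-activity column.
    """
    if cohort is None:
        cohort = cohort_fixture()
    rows = []
    for m in cohort:
        rec = eanm_recommended(m.weight)
        row = {
            "patient_id": m.patient_id,
            "weight": m.weight,
            "injected_activity": m.injected_activity,
            "eanm_recommended": rec,
        }
        for lv in levels:
            row[f"fraction_{int(lv * 100)}"] = lv * m.injected_activity / rec
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_summary(cohort: list[PatientMeta] | None = None) -> pd.DataFrame:
    """Mean / SD / median of the cohort's demographic and injection columns."""
    if cohort is None:
        cohort = cohort_fixture()
    df = pd.DataFrame(
        {
            "injected_activity": [m.injected_activity for m in cohort],
            "activity_per_kg": [m.activity_per_kg for m in cohort],
            "weight": [m.weight for m in cohort],
            "bmi": [m.bmi for m in cohort],
            "age": [m.age for m in cohort],
        }
    )
    return df.agg(["mean", "std", "median"]).T


def check_cohort_consistency(
    cohort: list[PatientMeta] | None = None,
    bmi_tol: float = 0.5,
) -> pd.DataFrame:
    """Internal-consistency report of the embedded cohort table.

    Flags rows where BMI deviates from weight/height^2 by more than
    ``bmi_tol`` kg/m^2 (rounded heights in the source make small deviations
    expected).  Discrepancies are reported, never corrected.
    """
    if cohort is None:
        cohort = cohort_fixture()
    rows = []
    for m in cohort:
        bmi_calc = m.weight / m.height ** 2
        rows.append(
            {
                "patient_id": m.patient_id,
                "bmi_table": m.bmi,
                "bmi_computed": bmi_calc,
                "bmi_discrepant": abs(bmi_calc - m.bmi) > bmi_tol,
                "per_kg_computed": m.injected_activity / m.weight,
            }
        )
    return pd.DataFrame(rows)
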