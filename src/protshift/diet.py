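"""Dietary arithmetic: Harris-Benedict BMR, energy shares, prescribed intake.

The intervention prescribes a hypocaloric diet: estimated daily needs are the
Harris-Benedict basal metabolic rate times an activity coefficient of 1.3
(sedentary), minus a 600 kcal deficit. Reported intakes are screened for
plausibility against 0.5-3x BMR. Macronutrient energy shares use the Atwater
factors 4/9/4 kcal per gram of protein/fat/carbohydrate.
"""

from __future__ import annotations

import numpy as np

__all__ = ["harris_benedict", "energy_shares", "prescribed_intake", "ATWATER"]

ATWATER = {"protein": 4.0, "fat": 9.0, "carbohydrate": 4.0}

ACTIVITY_COEFFICIENT = 1.3
CALORIC_DEFICIT_KCAL = 600.0


def harris_benedict(weight_kg, height_cm, age_years, sex, revised: bool = False):
    """Basal metabolic rate (kcal/day) from the Harris-Benedict equations.

    Original (1919) coefficients by default::

        men:   66.473  + 13.7516 W + 5.0033 H - 6.755  A
        women: 655.0955 + 9.5634 W + 1.8496 H - 4.6756 A

    with weight W in kg, height H in cm and age A in years. ``revised=True``
    uses the Roza-Shizgal (1984) re-estimation instead. ``sex`` is "male" /
    "female" (or M/F), scalar or array.
    """
    w = np.asarray(weight_kg, dtype=float)
    h = np.asarray(height_cm, dtype=float)
    a = np.asarray(age_years, dtype=float)
    s = np.char.lower(np.asarray(sex, dtype=str))
    male = np.isin(s, ("male", "m"))
    female = np.isin(s, ("female", "f"))
    if not (male | female).all():
        bad = np.asarray(sex)[~(male | female)]
        raise ValueError(f"sex must be male/female, got {bad!r}")
    if revised:
        men = 88.362 + 13.397 * w + 4.799 * h - 5.677 * a
        women = 447.593 + 9.247 * w + 3.098 * h - 4.330 * a
    else:
        men = 66.473 + 13.7516 * w + 5.0033 * h - 6.755 * a
        women = 655.0955 + 9.5634 * w + 1.8496 * h - 4.6756 * a
    out = np.where(male, men, women)
    return float(out) if out.ndim == 0 else out


def energy_shares(protein_g: float, fat_g: float, carbohydrate_g: float) -> dict[str, float]:
    """Percent of total energy from each macronutrient (Atwater 4/9/4)."""
    kcal = {
        "protein": protein_g * ATWATER["protein"],
        "fat": fat_g * ATWATER["fat"],
        "carbohydrate": carbohydrate_g * ATWATER["carbohydrate"],
    }
    total = sum(kcal.values())
    if total <= 0:
        raise ValueError("total energy must be positive")
    return {k: 100.0 * v / total for k, v in kcal.items()}


def prescribed_intake(bmr, activity: float = ACTIVITY_COEFFICIENT,
                      deficit: float = CALORIC_DEFICIT_KCAL):
    """Prescribed daily intake: activity-adjusted needs minus the deficit."""
    return np.asarray(bmr, dtype=float) * activity - deficit
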