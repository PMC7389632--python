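"""Conventional pediatric dose calculators and the comparison report.

Four empirical rules scale an adult dose to a child: Young's rule (age),
Clark's rule (weight in pounds), linear weight-based (mg/kg) and body
surface area-based scaling.  All four are strictly increasing in their
covariate and recover the adult dose at the adult covariate value.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import DomainError

LB_PER_KG = 2.20462
CLARK_ADULT_LB = 150.0
DEFAULT_ADULT_DOSE_MG = 20.0
DEFAULT_ADULT_WEIGHT_KG = 70.0
DEFAULT_ADULT_BSA_M2 = 1.73


@dataclass
class ChildSpec:
    """Covariates of one child for the dose calculators."""

    age_years: float
    weight_kg: float
    bsa_m2: float
    weight_lb: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if self.age_years <= 0 or self.weight_kg <= 0 or self.bsa_m2 <= 0:
            raise DomainError("age, weight and BSA must be positive")
        if self.weight_lb is None:
            self.weight_lb = self.weight_kg * LB_PER_KG
        elif abs(self.weight_lb - self.weight_kg * LB_PER_KG) > 0.01 * self.weight_lb + 1.0:
            raise DomainError("weight_lb inconsistent with weight_kg")


def young_dose(age_years: float, adult_dose_mg: float = DEFAULT_ADULT_DOSE_MG) -> float:
    """Young's rule: adult dose * age / (age + 12)."""
    if age_years <= 0:
        raise DomainError("age must be positive")
    return adult_dose_mg * age_years / (age_years + 12.0)


def clark_dose(weight_lb: float, adult_dose_mg: float = DEFAULT_ADULT_DOSE_MG) -> float:
    """Clark's rule: adult dose * weight(lb) / 150 (percent-of-adult-dose form)."""
    if weight_lb <= 0:
        raise DomainError("weight must be positive")
    return adult_dose_mg * weight_lb / CLARK_ADULT_LB


def weight_based_dose(
    weight_kg: float,
    adult_dose_mg: float = DEFAULT_ADULT_DOSE_MG,
    adult_weight_kg: float = DEFAULT_ADULT_WEIGHT_KG,
) -> float:
    """Linear mg/kg scaling from the adult dose."""
    if weight_kg <= 0 or adult_weight_kg <= 0:
        raise DomainError("weights must be positive")
    return adult_dose_mg * weight_kg / adult_weight_kg


def bsa_based_dose(
    bsa_m2: float,
    adult_dose_mg: float = DEFAULT_ADULT_DOSE_MG,
    adult_bsa_m2: float = DEFAULT_ADULT_BSA_M2,
) -> float:
    """BSA-proportional scaling from the adult dose."""
    if bsa_m2 <= 0 or adult_bsa_m2 <= 0:
        raise DomainError("BSA values must be positive")
    return adult_dose_mg * bsa_m2 / adult_bsa_m2


def round_dose(dose_mg: float) -> float:
    """Report rounding: two decimals below 10 mg, integer at/above 10 mg."""
    if dose_mg < 10.0:
        return round(dose_mg, 2)
    return float(round(dose_mg))


def comparison_table(
    child_specs: list[ChildSpec],
    pbpk_ranges: dict[str, str] | None = None,
    adult_dose_mg: float = DEFAULT_ADULT_DOSE_MG,
    adult_weight_kg: float = DEFAULT_ADULT_WEIGHT_KG,
    adult_bsa_m2: float = DEFAULT_ADULT_BSA_M2,
) -> pd.DataFrame:
    """All four conventional doses per child, plus the PBPK-recommended range.

    Same dose applies to both sexes.  Values are report-rounded; the
    individual calculators return unrounded values.
    """
    pbpk_ranges = pbpk_ranges or {}
    rows = []
    for c in child_specs:
        rows.append(
            {
                "group": c.label,
                "age_years": c.age_years,
                "weight_lb": round(c.weight_lb, 2),
                "weight_kg": c.weight_kg,
                "bsa_m2": c.bsa_m2,
                "young_mg": round_dose(young_dose(c.age_years, adult_dose_mg)),
                "clark_mg": round_dose(clark_dose(c.weight_lb, adult_dose_mg)),
                "weight_based_mg": round_dose(
                    weight_based_dose(c.weight_kg, adult_dose_mg, adult_weight_kg)
                ),
                "bsa_based_mg": round_dose(
                    bsa_based_dose(c.bsa_m2, adult_dose_mg, adult_bsa_m2)
                ),
                "pbpk_range_mg": pbpk_ranges.get(c.label, ""),
            }
        )
    return pd.DataFrame(rows)


# The four worked rows of the study's comparison (age, printed lb, kg, BSA).
REFERENCE_CHILDREN = [
    ChildSpec(age_years=1, weight_kg=10, bsa_m2=0.43, weight_lb=22, label="infants_to_toddler"),
    ChildSpec(age_years=5, weight_kg=17, bsa_m2=0.78, weight_lb=37, label="preschool"),
    ChildSpec(age_years=12, weight_kg=40, bsa_m2=1.25, weight_lb=88, label="school"),
    ChildSpec(age_years=17, weight_kg=60, bsa_m2=1.58, weight_lb=132, label="adolescent"),
]
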