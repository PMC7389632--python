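"""Virtual individuals and populations.

Age- and sex-dependent anthropometry, lumped organ volumes and blood flows,
gut geometry, and renal (GFR) maturation.  The body is lumped into eight
perfused compartments — venous blood, arterial blood, lung, liver, kidney,
gut wall, a richly perfused lump (brain, heart, spleen, ...) and a poorly
perfused lump (muscle, skin, adipose, bone) — which is sufficient for a
renally cleared, non-metabolised, non-binding drug.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

# ---------------------------------------------------------------------------
# Growth table: median weight (kg) and height (cm) by age, sexes pooled.
# Anchors chosen so that the conventional-dosing worked examples (10 kg at
# 1 y, 17 kg at 5 y, 40 kg at 12 y, 60 kg at 17 y) lie on the pooled table
# and the male adult lands exactly on the 70 kg / 170 cm reference plateau
# after the +/-3 % sex offset that ramps in beyond age 12 (male +, female -).
_GROWTH_AGE = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 5.0, 8.0, 12.0, 15.0, 17.0, 21.0, 90.0])
_GROWTH_WT = np.array([3.4, 5.6, 7.5, 10.0, 12.5, 17.0, 26.0, 40.0, 52.4, 60.0, 67.96, 67.96])
_GROWTH_HT = np.array([50.0, 60.0, 66.0, 75.0, 87.0, 110.0, 128.0, 150.0, 161.2, 164.1, 165.05, 165.05])

_SEX_OFFSET = 0.03  # fractional offset beyond age 12

# Organ volumes as fractions of body weight (density ~ 1 kg/L).  The richly
# perfused fraction carries an infancy surcharge (relatively large brain);
# the poorly perfused lump absorbs the balance so the total stays at 0.93.
_VOL_FRAC = {
    "venous": 0.0514,
    "arterial": 0.0257,
    "lung": 0.0076,
    "liver": 0.0260,
    "kidney": 0.0044,
    "gut_wall": 0.0171,
    "rich": 0.1000,  # + infancy surcharge, see build_individual
    "poor": None,    # balance to _TOTAL_VOL_FRAC
}
_TOTAL_VOL_FRAC = 0.93

# Blood flows as fixed fractions of cardiac output (systemic side; the lung
# receives the whole cardiac output in series).
FLOW_FRAC = {
    "liver_arterial": 0.065,
    "gut_wall": 0.190,
    "kidney": 0.190,
    "rich": 0.250,
    "poor": 0.305,
}
assert abs(sum(FLOW_FRAC.values()) - 1.0) < 1e-12

# Adult gut geometry (cm); lengths scale with height, radii with an age
# multiplier table.  Stomach holds fluid but does not absorb.
_GUT_SEGMENTS = ("stomach", "duodenum", "jejunum", "ileum", "colon")
_ADULT_GUT_LENGTH = {"stomach": 20.0, "duodenum": 25.0, "jejunum": 110.0, "ileum": 145.0, "colon": 150.0}
_ADULT_GUT_RADIUS = {"stomach": 4.0, "duodenum": 1.6, "jejunum": 1.5, "ileum": 1.4, "colon": 2.5}
_RADIUS_AGE = np.array([0.0, 1.0, 5.0, 12.0, 17.0, 29.0, 90.0])
_RADIUS_MULT = np.array([0.45, 0.55, 0.70, 0.85, 0.95, 1.0, 1.0])

_ADULT_CO_L_H = 336.0  # 5.6 L/min at 70 kg; allometric exponent 0.75

# GFR maturation: Hill sigmoid in postmenstrual age (weeks).
_GFR_HILL = 3.4
_GFR_TM50_WK = 47.7
_WEEKS_PER_YEAR = 52.14
_TERM_PMA_WK = 40.0


def anthropometry(age_years: float, sex: str = "male") -> tuple[float, float]:
    """Median (weight_kg, height_cm) at a given age.

    Piecewise-linear interpolation over the built-in growth table with an
    adult plateau of 70 kg / 170 cm; a +/-3 % sex offset beyond age 12.
    """
    if age_years <= 0 or age_years > 90:
        raise DomainError(f"age_years must be in (0, 90], got {age_years}")
    if sex not in ("male", "female"):
        raise DomainError(f"sex must be 'male' or 'female', got {sex!r}")
    wt = float(np.interp(age_years, _GROWTH_AGE, _GROWTH_WT))
    ht = float(np.interp(age_years, _GROWTH_AGE, _GROWTH_HT))
    if age_years > 12.0:
        s = _SEX_OFFSET if sex == "male" else -_SEX_OFFSET
        # ramp the offset in over ages 12-15 so the table stays continuous
        ramp = min(1.0, (age_years - 12.0) / 3.0)
        wt *= 1.0 + s * ramp
        ht *= 1.0 + s * ramp
    return wt, ht


def bsa(height_cm: float, weight_kg: float) -> float:
    """Body surface area (m^2) by the Mosteller formula, sqrt(h*w/3600)."""
    if height_cm <= 0 or weight_kg <= 0:
        raise DomainError("height_cm and weight_kg must be positive")
    return float(np.sqrt(height_cm * weight_kg / 3600.0))


def gfr_fraction(age_years: float) -> float:
    """Fraction of adult GFR at a given postnatal age (term birth).

    Hill sigmoid in postmenstrual age: f = PMA^h / (PMA^h + TM50^h) with
    h = 3.4 and TM50 = 47.7 weeks, which puts renal function above 90 % of
    the adult level by the first birthday.
    """
    if age_years < 0:
        raise DomainError(f"age_years must be >= 0, got {age_years}")
    pma = _TERM_PMA_WK + _WEEKS_PER_YEAR * age_years
    x = (pma / _GFR_TM50_WK) ** _GFR_HILL
    return float(x / (1.0 + x))


@dataclass
class Individual:
    """One virtual subject: demographics plus the physiology the PBPK model needs."""

    age_years: float
    sex: str
    weight_kg: float
    height_cm: float
    bsa_m2: float
    organ_volumes: dict[str, float]      # L
    blood_flows: dict[str, float]        # L/h, fractions of cardiac output
    cardiac_output_l_h: float
    gut_geometry: dict[str, dict[str, float]]  # per segment: length_cm, radius_cm, surface_area_cm2, volume_l
    gfr_fraction: float
    subject_id: int = 0

    def __post_init__(self) -> None:
        for organ, v in self.organ_volumes.items():
            if v <= 0:
                raise DomainError(f"organ volume {organ} must be positive")
        for organ, q in self.blood_flows.items():
            if q <= 0:
                raise DomainError(f"blood flow {organ} must be positive")
        if not 0 < self.gfr_fraction <= 1:
            raise DomainError("gfr_fraction must be in (0, 1]")

    def to_row(self) -> dict:
        return {
            "id": self.subject_id,
            "age_years": self.age_years,
            "sex": self.sex,
            "weight_kg": self.weight_kg,
            "height_cm": self.height_cm,
            "bsa_m2": self.bsa_m2,
            "gfr_fraction": self.gfr_fraction,
        }


_OVERRIDE_KEYS = {"weight_kg", "height_cm"}


def build_individual(
    age_years: float,
    sex: str = "male",
    overrides: dict | None = None,
    rng: np.random.Generator | None = None,
) -> Individual:
    """Construct an :class:`Individual` from age and sex.

    Organ volumes come from fraction-of-body-weight tables, blood flows are
    fixed fractions of an allometrically scaled cardiac output
    (CO = 336 * (W/70)^0.75 L/h), gut segment lengths scale with height and
    radii with an age multiplier, and renal function follows the GFR
    maturation sigmoid.  ``overrides`` may replace weight_kg / height_cm
    (used by population sampling).
    """
    overrides = dict(overrides or {})
    unknown = set(overrides) - _OVERRIDE_KEYS
    if unknown:
        raise ConfigError(f"unknown override keys: {sorted(unknown)}")
    wt_med, ht_med = anthropometry(age_years, sex)
    weight = float(overrides.get("weight_kg", wt_med))
    height = float(overrides.get("height_cm", ht_med))
    if weight <= 0 or height <= 0:
        raise DomainError("weight and height overrides must be positive")

    rich_frac = _VOL_FRAC["rich"] + 0.05 * np.exp(-age_years / 2.0)
    fixed = sum(v for k, v in _VOL_FRAC.items() if v is not None and k != "rich")
    poor_frac = _TOTAL_VOL_FRAC - fixed - rich_frac
    volumes = {k: v * weight for k, v in _VOL_FRAC.items() if v is not None and k != "rich"}
    volumes["rich"] = rich_frac * weight
    volumes["poor"] = poor_frac * weight

    co = _ADULT_CO_L_H * (weight / 70.0) ** 0.75
    flows = {k: f * co for k, f in FLOW_FRAC.items()}

    hscale = height / 170.0
    rmult = float(np.interp(age_years, _RADIUS_AGE, _RADIUS_MULT))
    gut = {}
    for seg in _GUT_SEGMENTS:
        length = _ADULT_GUT_LENGTH[seg] * hscale
        radius = _ADULT_GUT_RADIUS[seg] * rmult
        gut[seg] = {
            "length_cm": length,
            "radius_cm": radius,
            "surface_area_cm2": 2.0 * np.pi * radius * length,
            "volume_l": np.pi * radius**2 * length / 1000.0,
        }

    return Individual(
        age_years=age_years,
        sex=sex,
        weight_kg=weight,
        height_cm=height,
        bsa_m2=bsa(height, weight),
        organ_volumes=volumes,
        blood_flows=flows,
        cardiac_output_l_h=co,
        gut_geometry=gut,
        gfr_fraction=gfr_fraction(age_years),
    )


@dataclass
class PopulationSpec:
    """Specification of a virtual population."""

    n: int
    prop_female: float = 0.5
    age_min_years: float = 21.0
    age_max_years: float = 37.0
    height_sd_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise DomainError("n must be >= 1")
        if not 0.0 <= self.prop_female <= 1.0:
            raise DomainError("prop_female must be in [0, 1]")
        if self.age_min_years > self.age_max_years:
            raise DomainError("age_min_years must be <= age_max_years")
        if self.height_sd_fraction < 0:
            raise DomainError("height_sd_fraction must be >= 0")


def sample_population(spec: PopulationSpec) -> list[Individual]:
    """Sample a reproducible virtual population.

    Exactly round-half-up(n * prop_female) subjects are female; ages are
    uniform on [age_min, age_max]; height is the age/sex median times a
    lognormal factor with CV = height_sd_fraction; weight co-varies with
    height through the median BMI at that age (w = w_med * (h/h_med)^2),
    which keeps BMI in the age-typical band.
    """
    rng = np.random.default_rng(spec.seed)
    n_female = int(np.floor(spec.n * spec.prop_female + 0.5))
    sexes = ["female"] * n_female + ["male"] * (spec.n - n_female)
    sigma = np.sqrt(np.log(1.0 + spec.height_sd_fraction**2))
    out: list[Individual] = []
    for i, sex in enumerate(sexes):
        age = float(rng.uniform(spec.age_min_years, spec.age_max_years))
        wt_med, ht_med = anthropometry(age, sex)
        hfac = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
        height = ht_med * hfac
        weight = wt_med * hfac**2
        ind = build_individual(age, sex, overrides={"weight_kg": weight, "height_cm": height})
        ind.subject_id = i
        out.append(ind)
    return out


def population_frame(individuals: list[Individual]) -> pd.DataFrame:
    """One row per subject: id, age_years, sex, weight_kg, height_cm, bsa_m2, gfr_fraction."""
    return pd.DataFrame([ind.to_row() for ind in individuals])


# Pediatric groups: age bounds per the study's population table.
PEDIATRIC_GROUPS: dict[str, tuple[float, float]] = {
    "neonates_to_infants": (0.25, 1.0),
    "infants_to_toddler": (0.25, 1.9),
    "preschool": (2.0, 5.0),
    "school": (5.0, 12.0),
    "adolescent": (12.0, 16.0),
}


def group_spec(group: str, n: int = 100, seed: int = 0) -> PopulationSpec:
    """Population spec for a named pediatric group (n=100, 50 % female by default)."""
    if group not in PEDIATRIC_GROUPS:
        raise DomainError(f"unknown pediatric group {group!r}")
    lo, hi = PEDIATRIC_GROUPS[group]
    return PopulationSpec(n=n, prop_female=0.5, age_min_years=lo, age_max_years=hi, seed=seed)
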