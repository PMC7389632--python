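"""Drug parameter set, tissue partitioning and oral release kinetics.

Lisinopril is hydrophilic (log P -1.22), freely soluble (97 g/L), does not
bind plasma proteins, is not metabolised and is cleared exclusively by the
kidney.  Tissue partitioning is therefore modelled as a single scalar on
tissue water fractions; a linear "deep" compartment exchanging with venous
plasma stands in for slow, saturable ACE binding; uptake by the intestinal
peptide transporter PEPT1 is folded into regional permeability weights
(increasing duodenum -> ileum, minor colonic), with the absolute scale
carried by a calibrated effective permeability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .errors import DomainError, InfeasibleError
from .physiology import Individual

# Fractional tissue water content, used as the shape of the partition map
# for a hydrophilic non-binding drug (Kp_organ = kp_scalar * water fraction).
TISSUE_WATER_FRACTION = {
    "lung": 0.80,
    "liver": 0.75,
    "kidney": 0.78,
    "gut_wall": 0.75,
    "rich": 0.75,
    "poor": 0.65,
}

# Regional absorption weights follow the distally increasing expression of
# the intestinal peptide transporter PEPT1 (duodenum < jejunum < ileum),
# with minor residual colonic uptake; the absolute scale is the calibrated
# effective permeability.
DEFAULT_REGIONAL_WEIGHTS = {"duodenum": 0.2, "jejunum": 0.6, "ileum": 1.0, "colon": 0.1}


@dataclass
class DrugParameters:
    """Physicochemistry, clearance and distribution parameters.

    ``peff_cm_h``, ``cl_renal_adult_l_h``, ``kp_scalar``, ``fed_alpha`` and
    the deep-exchange constants are the calibrated parameters; the rest are
    literature physicochemistry.
    """

    log_p: float = -1.22
    pka: float = 2.5            # stored for documentation; ionisation not modelled
    mw_g_mol: float = 405.48
    solubility_mg_l: float = 97000.0
    fu_plasma: float = 1.0      # no plasma protein binding
    peff_cm_h: float = 0.06
    cl_renal_adult_l_h: float = 4.3
    kp_scalar: float = 1.0
    deep_kin_per_h: float = 0.0
    deep_kout_per_h: float = 1.0
    fed_alpha: float = 5.0      # gastric-emptying multiplier slope per 524 kcal
    regional_perm_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGIONAL_WEIGHTS)
    )

    def __post_init__(self) -> None:
        if not 0 < self.fu_plasma <= 1:
            raise DomainError("fu_plasma must be in (0, 1]")
        for name in ("mw_g_mol", "solubility_mg_l", "cl_renal_adult_l_h"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.peff_cm_h < 0:
            raise DomainError("peff_cm_h must be >= 0")
        if self.kp_scalar < 0 or self.deep_kin_per_h < 0 or self.deep_kout_per_h <= 0:
            raise DomainError("kp_scalar, deep_kin must be >= 0 and deep_kout > 0")
        for seg, w in self.regional_perm_weights.items():
            if not 0 <= w <= 1:
                raise DomainError(f"regional weight for {seg} must be in [0, 1]")

    def with_(self, **kwargs) -> "DrugParameters":
        return replace(self, **kwargs)


@dataclass
class Formulation:
    """Immediate-release oral formulation with first-order release."""

    release_model: str = "first_order"
    t80_min: float = 30.0

    def __post_init__(self) -> None:
        if self.release_model != "first_order":
            raise DomainError(f"unsupported release model {self.release_model!r}")
        if self.t80_min <= 0:
            raise DomainError("t80_min must be positive")


def release_rate(t80_min: float) -> float:
    """First-order release constant (1/h) from the time to 80 % release.

    k = -ln(0.2) / (t80/60), so the released fraction 1 - exp(-k t) is
    exactly 0.80 at t = t80.
    """
    if t80_min <= 0:
        raise DomainError("t80_min must be positive")
    return -math.log(0.2) / (t80_min / 60.0)


def kp_map(drug: DrugParameters, individual: Individual) -> dict[str, float]:
    """Tissue-to-plasma partition coefficients, Kp = kp_scalar * water fraction."""
    return {
        organ: drug.kp_scalar * TISSUE_WATER_FRACTION[organ]
        for organ in individual.organ_volumes
        if organ in TISSUE_WATER_FRACTION
    }


def vss_analytic(drug: DrugParameters, individual: Individual) -> float:
    """Steady-state distribution volume (L) implied by the model parameters.

    Vss = V_ven + V_art + sum_T V_T * Kp_T + (kin/kout) * V_ven.  Exact for
    this model because elimination is referenced to (and removed from) the
    venous compartment, which is also where concentration is sampled.
    """
    v_ven = individual.organ_volumes["venous"]
    v_art = individual.organ_volumes.get("arterial", 0.0)
    kps = kp_map(drug, individual)
    tissue = sum(individual.organ_volumes[o] * kp for o, kp in kps.items())
    deep = (drug.deep_kin_per_h / drug.deep_kout_per_h) * v_ven
    return v_ven + v_art + tissue + deep


def solve_kp_scalar(
    target_vss_l_per_kg: float,
    individual: Individual,
    drug: DrugParameters,
    water_fractions: dict[str, float] | None = None,
) -> float:
    """Closed-form partition scalar that makes the model Vss hit a target.

    Solves target*W = V_ven + V_art + s * sum_T V_T*wf_T + (kin/kout)*V_ven
    for s (linear).  Raises if the target is below the drug-accessible
    blood + deep volume, where no non-negative scalar works.
    """
    if target_vss_l_per_kg <= 0:
        raise DomainError("target Vss must be positive")
    wf = TISSUE_WATER_FRACTION if water_fractions is None else water_fractions
    v_ven = individual.organ_volumes["venous"]
    v_art = individual.organ_volumes.get("arterial", 0.0)
    deep = (drug.deep_kin_per_h / drug.deep_kout_per_h) * v_ven
    base = v_ven + v_art + deep
    denom = sum(v * wf[o] for o, v in individual.organ_volumes.items() if o in wf)
    target_l = target_vss_l_per_kg * individual.weight_kg
    if target_l <= base:
        raise InfeasibleError(
            f"target Vss {target_l:.3g} L is not above the blood+deep volume {base:.3g} L"
        )
    return (target_l - base) / denom
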