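"""Structured run configuration (YAML) with schema validation.

A single hierarchical config file drives the pipeline; every field has a
documented default, unknown keys are rejected by name, and units are
embedded in the key names.  The packaged ``lisinopril.yaml`` reproduces the
literature parameter set.
"""

from __future__ import annotations

import importlib.resources
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError

from .errors import ConfigError


class DrugSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    log_p: float = -1.22
    pka: float = 2.5
    mw_g_mol: float = 405.48
    solubility_mg_l: float = 97000.0
    fu_plasma: float = 1.0
    peff_cm_h: float = 0.06
    cl_renal_adult_l_h: float = 2.82
    kp_scalar: float = 1.0
    deep_kin_per_h: float = 0.0
    deep_kout_per_h: float = 1.0
    fed_alpha: float = 5.0
    regional_perm_weights: dict[str, float] = Field(
        default_factory=lambda: {"duodenum": 0.2, "jejunum": 0.6, "ileum": 1.0, "colon": 0.1}
    )


class FormulationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    release_model: str = "first_order"
    t80_min: float = 30.0


class PhysiologySection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n: int = 18
    prop_female: float = 0.0
    age_min_years: float = 21.0
    age_max_years: float = 37.0
    height_sd_fraction: float = 0.10
    seed: int = 0


class RegimenSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    route: str = "oral"
    dose_mg: float = 20.0
    n_doses: int = 1
    tau_h: float = 24.0
    fed: bool = False
    meal_kcal: float = 524.0


class CalibrationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    observations_csv: str | None = None
    passes: int = 8
    vss_target_l_per_kg: float = 0.89
    multiple_dose_fed: bool = False


class WindowSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    cmax_range: tuple[float, float] = (38.0, 124.0)
    tmax_range: tuple[float, float] = (5.1, 7.3)
    auc_range: tuple[float, float] = (611.0, 1851.0)


class DosefindSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_per_group: int = 100
    seed: int = 0
    groups: list[str] = Field(
        default_factory=lambda: [
            "neonates_to_infants", "infants_to_toddler", "preschool", "school", "adolescent",
        ]
    )
    window: WindowSection = Field(default_factory=WindowSection)


class OutputSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    directory: str = "pedpk_output"
    grid_h: float = 0.05


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    drug: DrugSection = Field(default_factory=DrugSection)
    formulation: FormulationSection = Field(default_factory=FormulationSection)
    physiology: PhysiologySection = Field(default_factory=PhysiologySection)
    regimen: RegimenSection = Field(default_factory=RegimenSection)
    calibration: CalibrationSection = Field(default_factory=CalibrationSection)
    dosefind: DosefindSection = Field(default_factory=DosefindSection)
    output: OutputSection = Field(default_factory=OutputSection)

    def drug_parameters(self):
        from .drug import DrugParameters

        d = self.drug
        return DrugParameters(
            log_p=d.log_p, pka=d.pka, mw_g_mol=d.mw_g_mol,
            solubility_mg_l=d.solubility_mg_l, fu_plasma=d.fu_plasma,
            peff_cm_h=d.peff_cm_h, cl_renal_adult_l_h=d.cl_renal_adult_l_h,
            kp_scalar=d.kp_scalar, deep_kin_per_h=d.deep_kin_per_h,
            deep_kout_per_h=d.deep_kout_per_h, fed_alpha=d.fed_alpha,
            regional_perm_weights=dict(d.regional_perm_weights),
        )

    def formulation_obj(self):
        from .drug import Formulation

        return Formulation(
            release_model=self.formulation.release_model, t80_min=self.formulation.t80_min
        )

    def population_spec(self):
        from .physiology import PopulationSpec

        p = self.physiology
        return PopulationSpec(
            n=p.n, prop_female=p.prop_female, age_min_years=p.age_min_years,
            age_max_years=p.age_max_years, height_sd_fraction=p.height_sd_fraction,
            seed=p.seed,
        )

    def regimen_obj(self):
        from .engine import Regimen

        r = self.regimen
        return Regimen(
            route=r.route, dose_mg=r.dose_mg, n_doses=r.n_doses,
            tau_h=r.tau_h, fed=r.fed, meal_kcal=r.meal_kcal,
        )

    def window_obj(self):
        from .dosefind import ReferenceWindow

        w = self.dosefind.window
        return ReferenceWindow(
            cmax_range=tuple(w.cmax_range),
            tmax_range=tuple(w.tmax_range),
            auc_range=tuple(w.auc_range),
        )


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config; ``None`` loads the packaged default.

    An empty file yields all defaults; unknown or misspelled keys raise
    :class:`ConfigError` naming the offending key.
    """
    if path is None:
        ref = importlib.resources.files("pedpk.data") / "lisinopril.yaml"
        text = ref.read_text()
    else:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {p}")
        text = p.read_text()
    raw = yaml.safe_load(text) or {}
    try:
        return RunConfig.model_validate(raw)
    except ValidationError as exc:
        keys = ", ".join(
            "->".join(str(x) for x in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration key(s): {keys}") from exc
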