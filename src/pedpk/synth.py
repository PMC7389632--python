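"""Synthetic "observed" data with the statistical structure the analysis assumes.

Two generators: :func:`gen_observed` emulates a sampled clinical
concentration-time study (sparse schedule, multiplicative lognormal
residual error per sample), and :func:`gen_reference_observation_set`
produces the summary-metric observation set the calibration stages consume
(per-subject lognormal scale factors, geometric-mean aggregation) from a
known ground-truth parameter set, enabling parameter-recovery experiments
without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .calibration import ReferenceObservation
from .drug import DrugParameters, Formulation
from .engine import Regimen, build_model, simulate
from .errors import DomainError
from .metrics import auc, cmax_tmax, troughs, vss_moment
from .physiology import Individual, PopulationSpec, sample_population

DEFAULT_SAMPLE_TIMES_H = (0.0, 0.5, 1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0, 48.0, 72.0, 96.0, 120.0)


class _Scaled:
    """A simulated profile with a multiplicative noise factor applied."""

    def __init__(self, result, factor):
        self.time_h = result.time_h
        self.plasma_conc_ng_ml = factor * result.plasma_conc_ng_ml


@dataclass
class ObservedProfile:
    """One subject's sampled, noisy concentration-time profile."""

    subject_id: int
    sample_times_h: np.ndarray
    conc_ng_ml: np.ndarray
    true_params: dict = field(default_factory=dict)
    noise_cv: float = 0.0
    seed: int = 0


def _sigma(noise_cv: float) -> float:
    return float(np.sqrt(np.log(1.0 + noise_cv**2)))


def gen_observed(
    true_drug: DrugParameters,
    regimen: Regimen,
    sample_times_h=DEFAULT_SAMPLE_TIMES_H,
    noise_cv: float = 0.15,
    n_subjects: int = 12,
    seed: int = 0,
    population_spec: PopulationSpec | None = None,
    formulation: Formulation | None = None,
) -> list[ObservedProfile]:
    """Simulate subjects and sample them with multiplicative lognormal noise.

    The noise factor is exp(N(0, sigma)) with sigma = sqrt(ln(1 + cv^2)),
    so the geometric mean of replicates equals the model prediction and
    concentrations stay positive.
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    spec = population_spec or PopulationSpec(n=n_subjects, prop_female=0.0, seed=seed)
    spec.n = n_subjects
    individuals = sample_population(spec)
    rng = np.random.default_rng(seed + 1)
    sigma = _sigma(noise_cv)
    t_end = max(float(max(sample_times_h)), (regimen.n_doses - 1) * regimen.tau_h + 24.0)
    truth = {
        "cl_renal_adult_l_h": true_drug.cl_renal_adult_l_h,
        "peff_cm_h": true_drug.peff_cm_h,
        "kp_scalar": true_drug.kp_scalar,
        "fed_alpha": true_drug.fed_alpha,
        "deep_kin_per_h": true_drug.deep_kin_per_h,
        "deep_kout_per_h": true_drug.deep_kout_per_h,
    }
    out = []
    for ind in individuals:
        model = build_model(ind, true_drug, formulation)
        res = simulate(model, regimen, t_end_h=t_end)
        pred = np.interp(sample_times_h, res.time_h, res.plasma_conc_ng_ml)
        noise = np.exp(rng.normal(0.0, sigma, size=len(pred))) if sigma > 0 else 1.0
        out.append(
            ObservedProfile(
                subject_id=ind.subject_id,
                sample_times_h=np.asarray(sample_times_h, dtype=float),
                conc_ng_ml=pred * noise,
                true_params=truth,
                noise_cv=noise_cv,
                seed=seed,
            )
        )
    return out


def gen_reference_observation_set(
    true_drug: DrugParameters,
    seed: int = 0,
    noise_cv: float = 0.0,
    n_subjects: int = 12,
    formulation: Formulation | None = None,
    population_spec: PopulationSpec | None = None,
) -> list[ReferenceObservation]:
    """Summary-metric observation set from a known ground truth.

    Mirrors the structure of the packaged reference set (IV AUC, oral
    fasting Cmax/AUC/Tmax, fed Cmax/Tmax, day-1/day-10 troughs).  Residual
    variability is a per-subject lognormal scale factor on the whole
    concentration profile; observation values are geometric means across
    subjects.  By default every subject is the age-29 reference adult male
    (only the noise varies), so the zero-noise set reproduces the model
    metrics exactly and the calibration workflow recovers the generating
    parameters — the parameter-recovery oracle.
    """
    if noise_cv < 0:
        raise DomainError("noise_cv must be >= 0")
    spec = population_spec or PopulationSpec(
        n=n_subjects, prop_female=0.0, age_min_years=29.0, age_max_years=29.0,
        height_sd_fraction=0.0, seed=seed,
    )
    individuals = sample_population(spec)
    rng = np.random.default_rng(seed + 2)
    sigma = _sigma(noise_cv)

    protocols = {
        "iv": Regimen(route="iv_bolus", dose_mg=2.97),
        "oral_fast": Regimen(route="oral", dose_mg=20.0),
        "oral_fed": Regimen(route="oral", dose_mg=20.0, fed=True),
        "multi": Regimen(route="oral", dose_mg=20.0, n_doses=10),
    }
    metrics: dict[str, list[float]] = {k: [] for k in (
        "iv_auc72", "vss", "oral_cmax", "oral_tmax", "oral_auc120",
        "fed_cmax", "fed_tmax", "cmin_day1", "cmin_day10",
    )}
    for ind in individuals:
        fac = float(np.exp(rng.normal(0.0, sigma))) if sigma > 0 else 1.0
        model = build_model(ind, true_drug, formulation)

        res = simulate(model, protocols["iv"], t_end_h=400.0)
        metrics["iv_auc72"].append(fac * auc(res.time_h, res.plasma_conc_ng_ml, 0.0, 72.0))
        metrics["vss"].append(
            vss_moment(_Scaled(res, fac), protocols["iv"].dose_mg, weight_kg=ind.weight_kg)
        )

        res = simulate(model, protocols["oral_fast"], t_end_h=120.0)
        cmx, tmx = cmax_tmax(res.time_h, res.plasma_conc_ng_ml)
        metrics["oral_cmax"].append(fac * cmx)
        metrics["oral_tmax"].append(tmx)
        metrics["oral_auc120"].append(fac * auc(res.time_h, res.plasma_conc_ng_ml, 0.0, 120.0))

        res = simulate(model, protocols["oral_fed"], t_end_h=120.0)
        cmx, tmx = cmax_tmax(res.time_h, res.plasma_conc_ng_ml)
        metrics["fed_cmax"].append(fac * cmx)
        metrics["fed_tmax"].append(tmx)

        res = simulate(model, protocols["multi"], t_end_h=240.0)
        cmins = troughs(res, 24.0, 10)
        metrics["cmin_day1"].append(fac * cmins[0])
        metrics["cmin_day10"].append(fac * cmins[9])

    def gmean(v):
        return float(np.exp(np.mean(np.log(v))))

    return [
        ReferenceObservation("iv_auc72_2.97", "auc_last", gmean(metrics["iv_auc72"]),
                             1.0, protocols["iv"], window_h=72.0),
        ReferenceObservation("vss_iv", "vss", gmean(metrics["vss"]),
                             1.0, protocols["iv"]),
        ReferenceObservation("oral_fast_cmax", "cmax", gmean(metrics["oral_cmax"]),
                             1.0, protocols["oral_fast"]),
        ReferenceObservation("oral_fast_tmax", "tmax", gmean(metrics["oral_tmax"]),
                             0.5, protocols["oral_fast"]),
        ReferenceObservation("oral_fast_auc120", "auc_last", gmean(metrics["oral_auc120"]),
                             1.0, protocols["oral_fast"], window_h=120.0),
        ReferenceObservation("oral_fed_cmax", "cmax", gmean(metrics["fed_cmax"]),
                             1.0, protocols["oral_fed"]),
        ReferenceObservation("oral_fed_tmax", "tmax", gmean(metrics["fed_tmax"]),
                             0.5, protocols["oral_fed"]),
        ReferenceObservation("cmin_day1", "cmin_day", gmean(metrics["cmin_day1"]),
                             1.0, protocols["multi"], day=1),
        ReferenceObservation("cmin_day10", "cmin_day", gmean(metrics["cmin_day10"]),
                             1.0, protocols["multi"], day=10),
    ]
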