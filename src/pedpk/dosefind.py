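"""Graded decremental dose search for pediatric groups.

Each candidate dose is simulated in the group's virtual population and the
population min/mean/max of Cmax and AUC(0-120 h) are compared against the
adult reference exposure window.  The colour labels are three independent
conditions: *green* — the population maximum of both Cmax and AUC falls
inside the window (even the most-exposed subject is within the adult
range); *blue* — min and mean of AUC inside; *yellow* — min of both Cmax
and AUC inside (even the least-exposed subject reaches the range);
otherwise *out*; when several hold, precedence is green > blue > yellow.
Tmax is reported but does not enter classification.  The rule set is
isolated in :func:`classify_dose` for easy revision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .drug import DrugParameters, Formulation
from .engine import PopulationSummary, Regimen, simulate_population
from .errors import DomainError
from .physiology import Individual

DOSE_GRID_MG = [20.0, 10.0, 5.0, 2.5, 1.5]
DOSE_GRID_NEONATES_MG = [5.0, 2.5, 1.5, 1.0]

_GROUPS = ("neonates_to_infants", "infants_to_toddler", "preschool", "school", "adolescent")


@dataclass
class ReferenceWindow:
    """Adult single-dose 20 mg exposure window used as the pediatric target."""

    cmax_range: tuple[float, float] = (38.0, 124.0)
    tmax_range: tuple[float, float] = (5.1, 7.3)
    auc_range: tuple[float, float] = (611.0, 1851.0)

    def __post_init__(self) -> None:
        for lo, hi in (self.cmax_range, self.tmax_range, self.auc_range):
            if not lo < hi:
                raise DomainError("window bounds must satisfy low < high")


@dataclass
class DoseDecision:
    """Classification of one candidate dose against the reference window."""

    group: str
    dose_mg: float
    flags: dict[str, dict[str, bool]]
    label: str
    stats: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    tmax_mean_h: float | None = None


def dose_grid(group: str) -> list[float]:
    """Descending candidate doses for a pediatric group."""
    if group not in _GROUPS:
        raise DomainError(f"unknown pediatric group {group!r}")
    if group == "neonates_to_infants":
        return list(DOSE_GRID_NEONATES_MG)
    return list(DOSE_GRID_MG)


def classify_dose(
    pop_summary: PopulationSummary,
    window: ReferenceWindow,
    group: str = "",
    dose_mg: float = float("nan"),
) -> DoseDecision:
    """Label a simulated dose from the population Cmax and AUC statistics."""
    cmaxes = np.array([s.cmax_ng_ml for s in pop_summary.subject_summaries])
    aucs = np.array([s.auc_last_ng_h_ml for s in pop_summary.subject_summaries])
    tmaxes = np.array([s.tmax_h for s in pop_summary.subject_summaries])

    def _flags(values, lo, hi):
        return {
            "min_in": bool(lo <= values.min() <= hi),
            "mean_in": bool(lo <= values.mean() <= hi),
            "max_in": bool(lo <= values.max() <= hi),
        }

    flags = {
        "cmax": _flags(cmaxes, *window.cmax_range),
        "auc": _flags(aucs, *window.auc_range),
    }
    if flags["cmax"]["max_in"] and flags["auc"]["max_in"]:
        label = "green"
    elif flags["auc"]["min_in"] and flags["auc"]["mean_in"]:
        label = "blue"
    elif flags["cmax"]["min_in"] and flags["auc"]["min_in"]:
        label = "yellow"
    else:
        label = "out"
    stats = {
        "cmax": (float(cmaxes.min()), float(cmaxes.mean()), float(cmaxes.max())),
        "auc": (float(aucs.min()), float(aucs.mean()), float(aucs.max())),
    }
    return DoseDecision(
        group=group,
        dose_mg=dose_mg,
        flags=flags,
        label=label,
        stats=stats,
        tmax_mean_h=float(tmaxes.mean()),
    )


def decremental_search(
    group: str,
    population: list[Individual],
    window: ReferenceWindow,
    drug: DrugParameters,
    formulation: Formulation | None = None,
    t_end_h: float = 120.0,
    grid_h: float | None = None,
) -> tuple[list[DoseDecision], tuple[float, float] | None]:
    """Simulate every grid dose and return decisions plus the recommended range.

    The recommended range is [lowest, highest] grid dose whose label is not
    "out"; ``None`` if no dose qualifies.
    """
    decisions = []
    for dose in dose_grid(group):
        regimen = Regimen(route="oral", dose_mg=dose)
        summary = simulate_population(
            population, drug, formulation, regimen,
            t_end_h=t_end_h, grid_h=grid_h, keep_profiles=False,
        )
        decisions.append(classify_dose(summary, window, group=group, dose_mg=dose))
    in_range = [d.dose_mg for d in decisions if d.label != "out"]
    recommended = (min(in_range), max(in_range)) if in_range else None
    return decisions, recommended


def decisions_frame(decisions: list[DoseDecision], recommended=None) -> pd.DataFrame:
    """CSV-ready report: one row per (group, dose)."""
    rows = []
    rec = "" if recommended is None else f"{recommended[0]}-{recommended[1]}"
    for d in decisions:
        rows.append(
            {
                "group": d.group,
                "dose_mg": d.dose_mg,
                "cmax_min": d.stats["cmax"][0],
                "cmax_mean": d.stats["cmax"][1],
                "cmax_max": d.stats["cmax"][2],
                "auc_min": d.stats["auc"][0],
                "auc_mean": d.stats["auc"][1],
                "auc_max": d.stats["auc"][2],
                "tmax_mean_h": d.tmax_mean_h,
                "label": d.label,
                "recommended_range": rec,
            }
        )
    return pd.DataFrame(rows)
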