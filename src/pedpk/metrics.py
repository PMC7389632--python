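"""Non-compartmental PK metrics on concentration-time grids.

All functions work on plain arrays (time in h, concentration in ng/ml) so
they apply equally to simulated and synthetic observed profiles.  AUC uses
the linear trapezoid on the dense grid; AUC to infinity extrapolates the
tail as C_last/lambda_z with lambda_z from a log-linear fit over the last
20 % of the time span.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError


@dataclass
class PKSummary:
    """Per-subject NCA summary."""

    cmax_ng_ml: float
    tmax_h: float
    auc_last_ng_h_ml: float
    auc_inf_ng_h_ml: float
    cmin_by_day_ng_ml: list[float] = field(default_factory=list)
    f_percent: float | None = None
    vss_l_per_kg: float | None = None
    cl_l_h: float | None = None


def _window_indices(times: np.ndarray, t_start: float, t_end: float) -> tuple[int, int]:
    if t_start < times[0] - 1e-9 or t_end > times[-1] + 1e-9:
        raise DomainError(
            f"window [{t_start}, {t_end}] outside the grid [{times[0]}, {times[-1]}]"
        )
    i0 = int(np.searchsorted(times, t_start - 1e-9))
    i1 = int(np.searchsorted(times, t_end - 1e-9))
    if abs(times[i0] - t_start) > 1e-6 or abs(times[i1] - t_end) > 1e-6:
        raise DomainError("window endpoints must be grid points")
    return i0, i1


def auc(times, conc, t_start: float | None = None, t_end: float | None = None) -> float:
    """Linear trapezoidal AUC over [t_start, t_end] (ng*h/ml)."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if times.ndim != 1 or np.any(np.diff(times) <= 0):
        raise DomainError("times must be strictly increasing")
    t_start = times[0] if t_start is None else t_start
    t_end = times[-1] if t_end is None else t_end
    i0, i1 = _window_indices(times, t_start, t_end)
    return float(np.trapezoid(conc[i0 : i1 + 1], times[i0 : i1 + 1]))


def aumc(times, conc, t_start: float | None = None, t_end: float | None = None) -> float:
    """Area under the first-moment curve, trapezoid on t*C."""
    times = np.asarray(times, dtype=float)
    return auc(times, times * np.asarray(conc, dtype=float), t_start, t_end)


def cmax_tmax(times, conc) -> tuple[float, float]:
    """Peak concentration and its grid time (first occurrence on ties)."""
    conc = np.asarray(conc, dtype=float)
    if conc.size == 0:
        raise DomainError("empty profile")
    i = int(np.argmax(conc))  # argmax returns the first maximum
    return float(conc[i]), float(np.asarray(times, dtype=float)[i])


def lambda_z(times, conc, tail_fraction: float = 0.2) -> float:
    """Terminal slope (1/h) by log-linear regression over the last
    ``tail_fraction`` of the time span (positive concentrations only)."""
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    t_cut = times[-1] - tail_fraction * (times[-1] - times[0])
    mask = (times >= t_cut) & (conc > 0)
    if mask.sum() < 3:
        raise DomainError("not enough positive tail points for lambda_z")
    slope = np.polyfit(times[mask], np.log(conc[mask]), 1)[0]
    if slope >= 0:
        raise DomainError("terminal slope is non-negative; cannot extrapolate")
    return float(-slope)


def auc_inf(times, conc) -> float:
    """AUC extrapolated to infinity: AUC_last + C_last / lambda_z."""
    lz = lambda_z(times, conc)
    return auc(times, conc) + float(np.asarray(conc)[-1]) / lz


def _profile(result_or_times, conc=None):
    if conc is not None:
        return np.asarray(result_or_times, dtype=float), np.asarray(conc, dtype=float)
    return result_or_times.time_h, result_or_times.plasma_conc_ng_ml


def troughs(result, tau_h: float, n_doses: int) -> list[float]:
    """Cmin immediately before each next scheduled dose, k*tau for k=1..n.

    Values are read at the grid point of k*tau; for oral dosing the venous
    concentration is continuous across a dose event, so the grid value at
    the dose time is the trough.
    """
    times, conc = _profile(result)
    if times[-1] + 1e-9 < n_doses * tau_h:
        raise DomainError("simulation does not span n_doses * tau")
    out = []
    for k in range(1, n_doses + 1):
        i0, _ = _window_indices(times, k * tau_h, times[-1])
        out.append(float(conc[i0]))
    return out


def f_abs(oral_summary, iv_summary, dose_oral_mg: float, dose_iv_mg: float) -> float:
    """Absolute bioavailability (%) from dose-normalised AUC_inf ratio."""
    auc_oral = getattr(oral_summary, "auc_inf_ng_h_ml", oral_summary)
    auc_iv = getattr(iv_summary, "auc_inf_ng_h_ml", iv_summary)
    if auc_iv <= 0:
        raise DomainError("IV AUC must be positive")
    return 100.0 * (auc_oral / dose_oral_mg) / (auc_iv / dose_iv_mg)


def vss_moment(result, dose_mg: float, weight_kg: float | None = None):
    """Steady-state distribution volume from an IV bolus profile.

    Vss = dose * AUMC_inf / AUC_inf^2 with exponential tail extrapolation.
    Returns litres, or L/kg when ``weight_kg`` is given.  Warns if the
    extrapolated tail exceeds 20 % of AUC_inf (flagged, still returned).
    """
    times, conc = _profile(result)
    lz = lambda_z(times, conc)
    c_last, t_last = float(conc[-1]), float(times[-1])
    auc_last = auc(times, conc)
    aumc_last = aumc(times, conc)
    auc_tail = c_last / lz
    aumc_tail = c_last * t_last / lz + c_last / lz**2
    auc_total = auc_last + auc_tail
    if auc_tail > 0.2 * auc_total:
        warnings.warn(
            f"extrapolated tail is {100 * auc_tail / auc_total:.1f}% of AUC_inf; "
            "Vss estimate is flagged as unreliable",
            stacklevel=2,
        )
    vss_l = dose_mg * 1000.0 * (aumc_last + aumc_tail) / auc_total**2  # mg->ng/ml units: L
    if weight_kg is not None:
        return vss_l / weight_kg
    return vss_l


def pk_summary(
    times,
    conc,
    tau_h: float = 24.0,
    n_doses: int = 1,
    weight_kg: float | None = None,
    auc_window_h: float | None = None,
) -> PKSummary:
    """Assemble the per-subject NCA summary from a profile.

    ``auc_window_h`` selects the reporting window for AUC_last (72 h for the
    IV protocols, 120 h for oral; defaults to min(120, span)).
    """
    times = np.asarray(times, dtype=float)
    conc = np.asarray(conc, dtype=float)
    cmax, tmax = cmax_tmax(times, conc)
    if auc_window_h is None:
        auc_window_h = min(120.0, float(times[-1]))
    a_last = auc(times, conc, times[0], min(auc_window_h, times[-1]))
    try:
        a_inf = auc_inf(times, conc)
    except DomainError:
        a_inf = a_last
    cmins = troughs(_Arr(times, conc), tau_h, n_doses) if n_doses > 1 else []
    return PKSummary(
        cmax_ng_ml=cmax,
        tmax_h=tmax,
        auc_last_ng_h_ml=a_last,
        auc_inf_ng_h_ml=a_inf,
        cmin_by_day_ng_ml=cmins,
    )


class _Arr:
    """Minimal profile wrapper for the array-based entry points."""

    def __init__(self, times, conc):
        self.time_h = np.asarray(times, dtype=float)
        self.plasma_conc_ng_ml = np.asarray(conc, dtype=float)
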