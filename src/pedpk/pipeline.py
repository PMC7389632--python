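"""End-to-end pipeline: calibrate -> validate -> pediatrics -> dosefind ->
convdose -> synth -> report, writing CSV artifacts and a plain-text run log."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import calibrate_workflow, load_observations
from .config import RunConfig
from .dosefind import decisions_frame, decremental_search
from .engine import Regimen, build_model, simulate, simulate_population
from .errors import PedpkError
from .metrics import auc, cmax_tmax, f_abs, pk_summary, troughs, vss_moment
from .physiology import group_spec, population_frame, sample_population
from .refdosing import REFERENCE_CHILDREN, comparison_table
from .synth import gen_observed

STAGES = ("calibrate", "validate", "pediatrics", "dosefind", "convdose", "synth", "report")


class _Log:
    def __init__(self, path: Path):
        self.path = path
        self.lines: list[str] = []

    def write(self, msg: str) -> None:
        self.lines.append(msg)
        self.path.write_text("\n".join(self.lines) + "\n")


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> dict:
    """Execute the requested stages; returns a dict of in-memory artifacts.

    Stage order is canonical; stages that need the calibrated model trigger
    calibration implicitly.  All outputs are deterministic for a fixed
    config (timestamps only in the log).
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise PedpkError(f"unknown stages: {sorted(unknown)}")
    outdir = Path(config.output.directory)
    outdir.mkdir(parents=True, exist_ok=True)
    log = _Log(outdir / "run.log")
    log.write(f"pedpk {__version__}")
    log.write(f"seeds: physiology={config.physiology.seed} dosefind={config.dosefind.seed}")
    artifacts: dict = {}

    needs_cal = {"calibrate", "validate", "pediatrics", "dosefind", "report"} & set(stages)
    drug = config.drug_parameters()
    formulation = config.formulation_obj()

    if needs_cal:
        t0 = time.perf_counter()
        obs = load_observations(config.calibration.observations_csv)
        cal = calibrate_workflow(
            obs, drug=drug, formulation=formulation,
            passes=config.calibration.passes,
            vss_target_l_per_kg=config.calibration.vss_target_l_per_kg,
        )
        drug = cal.drug
        artifacts["calibration"] = cal
        log.write(f"calibrate: {time.perf_counter() - t0:.1f} s, params={cal.params}")
        for k, v in cal.stage_objectives.items():
            log.write(f"  objective {k} = {v:.3e}")
        if "calibrate" in stages:
            (outdir / "calibrated_parameters.json").write_text(
                json.dumps(cal.params, indent=2) + "\n"
            )

    if "validate" in stages:
        t0 = time.perf_counter()
        rows = []
        ref = {o.label: o.value for o in load_observations(config.calibration.observations_csv)}
        adult = sample_population(config.population_spec())
        from .calibration import ADULT_REFERENCE_AGE
        from .physiology import build_individual

        mean_ind = build_individual(ADULT_REFERENCE_AGE, "male")
        model = build_model(mean_ind, drug, formulation)
        # IV protocols
        for dose, label in ((2.97, "iv_auc72_2.97"), (5.53, "iv_auc72_5.53"), (11.20, "iv_auc72_11.20")):
            res = simulate(model, Regimen(route="iv_bolus", dose_mg=dose), t_end_h=72.0)
            rows.append({"label": label, "observed": ref.get(label),
                         "predicted": auc(res.time_h, res.plasma_conc_ng_ml, 0, 72)})
        res_iv = simulate(model, Regimen(route="iv_bolus", dose_mg=2.97), t_end_h=400.0)
        vss = vss_moment(res_iv, 2.97, weight_kg=mean_ind.weight_kg)
        rows.append({"label": "vss_iv", "observed": ref.get("vss_iv"), "predicted": vss})
        # oral fasting / fed
        res_fast = simulate(model, Regimen(route="oral", dose_mg=20.0), t_end_h=120.0)
        cmx, tmx = cmax_tmax(res_fast.time_h, res_fast.plasma_conc_ng_ml)
        rows += [
            {"label": "oral_fast_cmax", "observed": ref.get("oral_fast_cmax"), "predicted": cmx},
            {"label": "oral_fast_tmax", "observed": ref.get("oral_fast_tmax"), "predicted": tmx},
            {"label": "oral_fast_auc120", "observed": ref.get("oral_fast_auc120"),
             "predicted": auc(res_fast.time_h, res_fast.plasma_conc_ng_ml, 0, 120)},
        ]
        res_fed = simulate(model, Regimen(route="oral", dose_mg=20.0, fed=True), t_end_h=120.0)
        cmx, tmx = cmax_tmax(res_fed.time_h, res_fed.plasma_conc_ng_ml)
        rows += [
            {"label": "oral_fed_cmax", "observed": ref.get("oral_fed_cmax"), "predicted": cmx},
            {"label": "oral_fed_tmax", "observed": ref.get("oral_fed_tmax"), "predicted": tmx},
        ]
        # bioavailability and troughs
        from .metrics import auc_inf

        f = f_abs(
            auc_inf(res_fast.time_h, res_fast.plasma_conc_ng_ml),
            auc_inf(res_iv.time_h, res_iv.plasma_conc_ng_ml),
            20.0, 2.97,
        )
        rows.append({"label": "f_percent", "observed": 25.0, "predicted": f})
        res_md = simulate(model, Regimen(route="oral", dose_mg=20.0, n_doses=10), t_end_h=240.0)
        cmins = troughs(res_md, 24.0, 10)
        for day in range(1, 11):
            rows.append({"label": f"cmin_day{day}", "observed": ref.get(f"cmin_day{day}"),
                         "predicted": cmins[day - 1]})
        val = pd.DataFrame(rows)
        val.to_csv(outdir / "validation.csv", index=False)
        artifacts["validation"] = val
        artifacts["profiles"] = {"iv": res_iv, "fast": res_fast, "fed": res_fed, "multi": res_md}
        artifacts["adult_population"] = adult
        log.write(f"validate: {time.perf_counter() - t0:.1f} s ({len(rows)} comparisons)")

    if "pediatrics" in stages or "dosefind" in stages:
        t0 = time.perf_counter()
        window = config.window_obj()
        ped_rows, dose_frames, ranges = [], [], {}
        for group in config.dosefind.groups:
            spec = group_spec(group, n=config.dosefind.n_per_group, seed=config.dosefind.seed)
            pop = sample_population(spec)
            population_frame(pop).to_csv(outdir / f"population_{group}.csv", index=False)
            if "pediatrics" in stages:
                summary = simulate_population(
                    pop, drug, formulation, Regimen(route="oral", dose_mg=20.0),
                    t_end_h=120.0, grid_h=config.output.grid_h, keep_profiles=False,
                )
                aucs = [s.auc_last_ng_h_ml for s in summary.subject_summaries]
                ped_rows.append({"group": group, "dose_mg": 20.0,
                                 "auc_mean": float(np.mean(aucs)),
                                 "cmax_mean": float(np.mean([s.cmax_ng_ml for s in summary.subject_summaries]))})
            if "dosefind" in stages:
                decisions, rec = decremental_search(
                    group, pop, window, drug, formulation, grid_h=config.output.grid_h
                )
                dose_frames.append(decisions_frame(decisions, rec))
                ranges[group] = rec
        if ped_rows:
            ped = pd.DataFrame(ped_rows)
            ped.to_csv(outdir / "pediatric_20mg_summary.csv", index=False)
            artifacts["pediatrics"] = ped
        if dose_frames:
            dd = pd.concat(dose_frames, ignore_index=True)
            dd.to_csv(outdir / "dose_decisions.csv", index=False)
            artifacts["dose_decisions"] = dd
            artifacts["recommended_ranges"] = ranges
        log.write(f"pediatrics/dosefind: {time.perf_counter() - t0:.1f} s")

    if "convdose" in stages:
        ranges = artifacts.get("recommended_ranges", {})
        pbpk = {g: (f"{r[0]}-{r[1]}" if r else "") for g, r in ranges.items()}
        table = comparison_table(REFERENCE_CHILDREN, pbpk)
        table.to_csv(outdir / "conventional_doses.csv", index=False)
        artifacts["conventional_doses"] = table
        log.write("convdose: written")

    if "synth" in stages:
        profiles = gen_observed(
            drug, config.regimen_obj(), n_subjects=config.physiology.n,
            seed=config.physiology.seed,
        )
        rows = [
            {"subject_id": p.subject_id, "time_h": t, "conc_ng_ml": c}
            for p in profiles
            for t, c in zip(p.sample_times_h, p.conc_ng_ml)
        ]
        pd.DataFrame(rows).to_csv(outdir / "synthetic_observed.csv", index=False)
        (outdir / "synthetic_truth.json").write_text(
            json.dumps(profiles[0].true_params, indent=2) + "\n"
        )
        artifacts["synthetic"] = profiles
        log.write("synth: written")

    if "report" in stages:
        _write_plots(artifacts, outdir, drug, formulation, config)
        log.write("report: plots written")

    artifacts["drug"] = drug
    return artifacts


def _write_plots(artifacts: dict, outdir: Path, drug, formulation, config) -> None:
    """Profile plots with 5th-95th percentile bands (presentation only)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    adult = artifacts.get("adult_population")
    if adult is None:
        adult = sample_population(config.population_spec())
    summary = simulate_population(
        adult, drug, formulation, Regimen(route="oral", dose_mg=20.0),
        t_end_h=120.0, keep_profiles=False,
    )
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.fill_between(summary.time_h, summary.p05, summary.p95, alpha=0.3, label="5th-95th pct")
    ax.plot(summary.time_h, summary.mean, "k-", label="mean")
    ax.plot(summary.time_h, summary.min, "k:", lw=0.8)
    ax.plot(summary.time_h, summary.max, "k:", lw=0.8, label="min/max")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("plasma concentration (ng/ml)")
    ax.set_title("20 mg oral, fasting adults")
    ax.legend()
    fig.tight_layout()
    fig.savefig(outdir / "adult_oral_population.png", dpi=120)
    plt.close(fig)
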