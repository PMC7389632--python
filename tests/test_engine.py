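"""Conservation, linearity, superposition, limits and solver cross-checks."""

import numpy as np
import pytest

from pedpk.drug import DrugParameters
from pedpk.engine import (
    Regimen,
    apply_fed_state,
    build_model,
    mass_balance,
    simulate,
    simulate_population,
)
from pedpk.errors import DomainError
from pedpk.metrics import auc, cmax_tmax
from pedpk.physiology import build_individual
from pedpk.drug import vss_analytic


@pytest.fixture(scope="module")
def plain_drug():
    # mid-range parameters; absolute values irrelevant for structural checks
    return DrugParameters(
        peff_cm_h=0.04, cl_renal_adult_l_h=4.2, kp_scalar=0.4,
        deep_kin_per_h=0.1, deep_kout_per_h=0.01,
    )


@pytest.fixture(scope="module")
def model(plain_drug):
    return build_model(build_individual(29, "male"), plain_drug)


class TestConservation:
    @pytest.mark.parametrize(
        "regimen,t_end",
        [
            (Regimen(route="iv_bolus", dose_mg=2.97), 72.0),
            (Regimen(route="oral", dose_mg=20.0), 120.0),
            (Regimen(route="oral", dose_mg=20.0, n_doses=10), 240.0),
        ],
        ids=["iv", "oral", "multidose"],
    )
    def test_mass_balance_below_1e6(self, model, regimen, t_end):
        res = simulate(model, regimen, t_end_h=t_end)
        assert mass_balance(res) <= 1e-6

    def test_iv_fully_excreted_in_urine(self, model):
        res = simulate(model, Regimen(route="iv_bolus", dose_mg=2.97), t_end_h=2000.0, grid_h=0.05)
        assert res.cumulative_urine_mg[-1] >= 0.999 * 2.97

    def test_zero_permeability_all_to_feces(self, model):
        drug = model.drug.with_(peff_cm_h=0.0)
        m0 = build_model(model.individual, drug)
        res = simulate(m0, Regimen(route="oral", dose_mg=20.0), t_end_h=300.0)
        assert res.cumulative_urine_mg[-1] == pytest.approx(0.0, abs=1e-9)
        assert res.cumulative_feces_mg[-1] == pytest.approx(20.0, rel=1e-3)
        assert np.max(res.plasma_conc_ng_ml) == 0.0


class TestLinearity:
    def test_concentration_proportional_to_dose(self, model):
        r1 = simulate(model, Regimen(route="oral", dose_mg=10.0), t_end_h=72.0)
        r2 = simulate(model, Regimen(route="oral", dose_mg=20.0), t_end_h=72.0)
        mask = r1.plasma_conc_ng_ml > 0
        ratio = r2.plasma_conc_ng_ml[mask] / r1.plasma_conc_ng_ml[mask]
        assert np.max(np.abs(ratio - 2.0)) <= 1e-6

    def test_multiple_dose_superposition(self, model):
        multi = simulate(model, Regimen(route="oral", dose_mg=20.0, n_doses=10), t_end_h=240.0)
        single = simulate(model, Regimen(route="oral", dose_mg=20.0), t_end_h=240.0)
        t, c = single.time_h, single.plasma_conc_ng_ml
        built = np.zeros_like(c)
        shift = int(round(24.0 / (t[1] - t[0])))
        for k in range(10):
            built[k * shift:] += c[: len(c) - k * shift]
        denom = np.max(multi.plasma_conc_ng_ml)
        assert np.max(np.abs(multi.plasma_conc_ng_ml - built)) / denom <= 1e-6


class TestLimitsAndCrossChecks:
    def test_fast_perfusion_limit_matches_one_compartment(self):
        # with flows blown up the whole body becomes a single well-stirred
        # volume Vss eliminating at CL: C(t) = D/Vss * exp(-CL t / Vss)
        ind = build_individual(29, "male")
        ind.blood_flows = {k: v * 1e5 for k, v in ind.blood_flows.items()}
        ind.cardiac_output_l_h *= 1e5
        drug = DrugParameters(peff_cm_h=0.04, cl_renal_adult_l_h=4.2,
                              kp_scalar=0.4, deep_kin_per_h=0.0)
        m = build_model(ind, drug)
        dose = 10.0
        res = simulate(m, Regimen(route="iv_bolus", dose_mg=dose), t_end_h=72.0)
        vss = vss_analytic(drug, ind)
        cl = m.cl_renal_l_h
        t = res.time_h[10:]
        expected = dose * 1000.0 / vss * np.exp(-cl * t / vss)
        rel = (res.plasma_conc_ng_ml[10:] - expected) / expected
        assert np.sqrt(np.mean(rel**2)) <= 0.005

    def test_expm_and_lsoda_agree(self, model):
        reg = Regimen(route="oral", dose_mg=20.0)
        a = simulate(model, reg, t_end_h=48.0, method="expm")
        b = simulate(model, reg, t_end_h=48.0, method="lsoda", rtol=1e-10, atol=1e-12)
        denom = np.max(a.plasma_conc_ng_ml)
        assert np.max(np.abs(a.plasma_conc_ng_ml - b.plasma_conc_ng_ml)) / denom < 1e-6

    def test_renal_clearance_capped_at_kidney_flow(self):
        ind = build_individual(29, "male")
        m = build_model(ind, DrugParameters(cl_renal_adult_l_h=1e5, peff_cm_h=0.04))
        assert m.cl_renal_l_h == pytest.approx(ind.blood_flows["kidney"])

    def test_solubility_never_approached(self, model):
        res = simulate(model, Regimen(route="oral", dose_mg=20.0), t_end_h=24.0)
        assert res.max_lumen_solubility_fraction < 0.01


class TestFedState:
    def test_zero_meal_is_identity(self, model):
        assert apply_fed_state(model, 0.0) is model

    def test_fed_slows_gastric_emptying_only(self, calibrated_drug, adult):
        m = build_model(adult, calibrated_drug)
        fast = simulate(m, Regimen(route="oral", dose_mg=20.0), t_end_h=120.0)
        fed = simulate(m, Regimen(route="oral", dose_mg=20.0, fed=True), t_end_h=120.0)
        cf, tf = cmax_tmax(fast.time_h, fast.plasma_conc_ng_ml)
        ce, te = cmax_tmax(fed.time_h, fed.plasma_conc_ng_ml)
        assert te > tf and ce < cf
        ratio = auc(fed.time_h, fed.plasma_conc_ng_ml, 0, 120) / auc(
            fast.time_h, fast.plasma_conc_ng_ml, 0, 120
        )
        assert 0.9 <= ratio <= 1.1  # food does not change bioavailability

    def test_negative_meal_rejected(self, model):
        with pytest.raises(DomainError):
            apply_fed_state(model, -1.0)


class TestPopulation:
    def test_single_subject_summary_collapses(self, plain_drug):
        pop = [build_individual(29, "male")]
        s = simulate_population(pop, plain_drug, regimen=Regimen(route="oral", dose_mg=20.0),
                                t_end_h=48.0)
        assert np.allclose(s.mean, s.min) and np.allclose(s.mean, s.max)
        assert np.allclose(s.p05, s.p95)

    def test_percentile_ordering(self, plain_drug):
        pop = [build_individual(a, s) for a, s in ((25, "male"), (30, "female"), (35, "male"))]
        s = simulate_population(pop, plain_drug, regimen=Regimen(route="oral", dose_mg=20.0),
                                t_end_h=48.0)
        assert np.all(s.min <= s.p05 + 1e-12)
        assert np.all(s.p05 <= s.p95 + 1e-12)
        assert np.all(s.p95 <= s.max + 1e-12)

    def test_empty_population_rejected(self, plain_drug):
        with pytest.raises(DomainError):
            simulate_population([], plain_drug)


class TestRegimenValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"route": "intramuscular", "dose_mg": 5},
            {"route": "oral", "dose_mg": 0},
            {"route": "oral", "dose_mg": 5, "n_doses": 0},
            {"route": "oral", "dose_mg": 5, "meal_kcal": -1},
        ],
    )
    def test_invalid_regimens(self, kwargs):
        with pytest.raises(DomainError):
            Regimen(**kwargs)

    def test_t_end_must_cover_schedule(self, model):
        with pytest.raises(DomainError):
            simulate(model, Regimen(route="oral", dose_mg=5, n_doses=3), t_end_h=40.0)

    def test_off_grid_dose_time_rejected(self, model):
        with pytest.raises(DomainError):
            simulate(model, Regimen(route="oral", dose_mg=5, n_doses=2, tau_h=24.017),
                     t_end_h=60.0)
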