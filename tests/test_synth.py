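"""Synthetic observed-data generators and the recovery experiment wiring."""

import numpy as np
import pytest

from pedpk.engine import Regimen, build_model, simulate
from pedpk.errors import DomainError
from pedpk.metrics import auc, cmax_tmax
from pedpk.physiology import PopulationSpec, sample_population
from pedpk.synth import (
    DEFAULT_SAMPLE_TIMES_H,
    gen_observed,
    gen_reference_observation_set,
)


@pytest.fixture(scope="module")
def regimen():
    return Regimen(route="oral", dose_mg=20.0)


class TestGenObserved:
    def test_zero_noise_reproduces_model_predictions(self, calibrated_drug, regimen):
        profiles = gen_observed(calibrated_drug, regimen, noise_cv=0.0, n_subjects=2, seed=5)
        spec = PopulationSpec(n=2, prop_female=0.0, seed=5)
        ind = sample_population(spec)[0]
        res = simulate(build_model(ind, calibrated_drug), regimen, t_end_h=120.0)
        expected = np.interp(DEFAULT_SAMPLE_TIMES_H, res.time_h, res.plasma_conc_ng_ml)
        assert np.allclose(profiles[0].conc_ng_ml, expected)

    def test_seeded_reproducibility(self, calibrated_drug, regimen):
        a = gen_observed(calibrated_drug, regimen, noise_cv=0.2, n_subjects=3, seed=9)
        b = gen_observed(calibrated_drug, regimen, noise_cv=0.2, n_subjects=3, seed=9)
        c = gen_observed(calibrated_drug, regimen, noise_cv=0.2, n_subjects=3, seed=10)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa.conc_ng_ml, pb.conc_ng_ml)
        assert not np.allclose(a[0].conc_ng_ml, c[0].conc_ng_ml)

    def test_noise_is_median_unbiased(self, calibrated_drug, regimen):
        # 1000 replicate samples of the same time point: geometric mean
        # within 1 % of the model value
        times = np.full(1000, 6.0)
        profiles = gen_observed(calibrated_drug, regimen, sample_times_h=times,
                                noise_cv=0.15, n_subjects=1, seed=3)
        noisy = profiles[0].conc_ng_ml
        clean = gen_observed(calibrated_drug, regimen, sample_times_h=[6.0],
                             noise_cv=0.0, n_subjects=1, seed=3)[0].conc_ng_ml[0]
        gmean = np.exp(np.mean(np.log(noisy)))
        assert abs(gmean / clean - 1) < 0.01

    def test_negative_cv_rejected(self, calibrated_drug, regimen):
        with pytest.raises(DomainError):
            gen_observed(calibrated_drug, regimen, noise_cv=-0.1)

    def test_truth_sidecar_carries_generating_parameters(self, calibrated_drug, regimen):
        p = gen_observed(calibrated_drug, regimen, noise_cv=0.0, n_subjects=1, seed=0)[0]
        assert p.true_params["cl_renal_adult_l_h"] == calibrated_drug.cl_renal_adult_l_h
        assert p.true_params["peff_cm_h"] == calibrated_drug.peff_cm_h


class TestReferenceObservationSet:
    def test_schema_matches_packaged_fit_set(self, calibrated_drug, reference_observations):
        synth = gen_reference_observation_set(calibrated_drug, seed=0, n_subjects=1)
        packaged_fit = {(o.label, o.metric) for o in reference_observations if o.weight > 0}
        synth_set = {(o.label, o.metric) for o in synth}
        assert packaged_fit == synth_set

    def test_zero_noise_equals_reference_individual_metrics(self, calibrated_drug, adult):
        synth = {o.label: o.value for o in
                 gen_reference_observation_set(calibrated_drug, seed=0, n_subjects=1)}
        model = build_model(adult, calibrated_drug)
        res = simulate(model, Regimen(route="oral", dose_mg=20.0), t_end_h=120.0)
        cmx, tmx = cmax_tmax(res.time_h, res.plasma_conc_ng_ml)
        assert synth["oral_fast_cmax"] == pytest.approx(cmx, rel=1e-9)
        assert synth["oral_fast_tmax"] == pytest.approx(tmx, rel=1e-9)
        assert synth["oral_fast_auc120"] == pytest.approx(
            auc(res.time_h, res.plasma_conc_ng_ml, 0, 120), rel=1e-9
        )
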