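"""Non-compartmental metrics against closed-form oracles."""

import numpy as np
import pytest

from pedpk.errors import DomainError
from pedpk.metrics import (
    auc,
    auc_inf,
    cmax_tmax,
    f_abs,
    lambda_z,
    pk_summary,
    troughs,
    vss_moment,
    _Arr,
)


class TestAuc:
    def test_constant_profile(self):
        t = np.arange(0, 120.05, 0.05)
        assert auc(t, np.full_like(t, 10.0)) == pytest.approx(1200.0, rel=1e-12)

    def test_single_triangle(self):
        assert auc([0.0, 1.0], [0.0, 2.0]) == pytest.approx(1.0, rel=1e-12)

    def test_exponential_against_analytic(self):
        t = np.arange(0, 120.01, 0.01)
        c = 100.0 * np.exp(-0.1 * t)
        expected = 1000.0 * (1 - np.exp(-12.0))
        assert abs(auc(t, c) - expected) / expected <= 1e-4

    def test_additivity(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 50.05, 0.05)
        c = rng.uniform(0, 100, len(t))
        whole = auc(t, c, 0.0, 50.0)
        split = auc(t, c, 0.0, 20.0) + auc(t, c, 20.0, 50.0)
        assert split == pytest.approx(whole, rel=1e-12)

    def test_window_outside_grid_rejected(self):
        with pytest.raises(DomainError):
            auc([0, 1, 2], [1, 1, 1], 0, 5)


class TestCmaxTmax:
    def test_monotone_decreasing_profile_peaks_at_zero(self):
        t = np.arange(0, 10, 0.05)
        _, tmax = cmax_tmax(t, 50 * np.exp(-t))
        assert tmax == 0.0

    def test_tie_takes_earlier_time(self):
        c = [0.0, 5.0, 3.0, 5.0, 1.0]
        cmx, tmx = cmax_tmax([0, 1, 2, 3, 4], c)
        assert (cmx, tmx) == (5.0, 1.0)

    def test_empty_profile_rejected(self):
        with pytest.raises(DomainError):
            cmax_tmax([], [])


class TestTroughs:
    def test_long_interval_trough_vanishes(self):
        t = np.arange(0, 200.05, 0.05)
        c = 100 * np.exp(-0.5 * t)  # half-life 1.4 h, tau 100 h
        assert troughs(_Arr(t, c), 100.0, 2)[0] < 1e-10

    def test_one_compartment_superposition_oracle(self):
        # oral one-compartment: C(t) = A (e^{-ke t} - e^{-ka t}); troughs of
        # the q24h regimen follow from the geometric accumulation series
        ka, ke, tau, n = 0.8, 0.1, 24.0, 5
        t = np.arange(0, n * tau + 0.05, 0.05)
        c = np.zeros_like(t)
        for k in range(n):
            tk = np.clip(t - k * tau, 0, None)
            c += np.where(t >= k * tau, np.exp(-ke * tk) - np.exp(-ka * tk), 0.0)
        got = troughs(_Arr(t, c), tau, n)
        for j in range(1, n + 1):
            expected = sum(
                np.exp(-ke * (j * tau - k * tau)) - np.exp(-ka * (j * tau - k * tau))
                for k in range(j)
            )
            assert got[j - 1] == pytest.approx(expected, rel=1e-9)

    def test_accumulation_monotone_with_decreasing_increments(self):
        ka, ke, tau, n = 0.8, 0.05, 24.0, 8
        t = np.arange(0, n * tau + 0.05, 0.05)
        c = np.zeros_like(t)
        for k in range(n):
            tk = np.clip(t - k * tau, 0, None)
            c += np.where(t >= k * tau, np.exp(-ke * tk) - np.exp(-ka * tk), 0.0)
        cm = troughs(_Arr(t, c), tau, n)
        inc = np.diff(cm)
        assert np.all(inc > 0) and np.all(np.diff(inc) < 0)

    def test_insufficient_span_rejected(self):
        with pytest.raises(DomainError):
            troughs(_Arr([0, 1, 2], [1, 1, 1]), 24.0, 2)


class TestBioavailability:
    def test_equal_dose_normalised_auc_gives_100(self):
        assert f_abs(500.0, 100.0, 20.0, 4.0) == pytest.approx(100.0)

    def test_scales_with_auc_ratio(self):
        assert f_abs(125.0, 100.0, 20.0, 4.0) == pytest.approx(25.0)

    def test_zero_iv_auc_rejected(self):
        with pytest.raises(DomainError):
            f_abs(100.0, 0.0, 20.0, 4.0)


class TestVssMoment:
    def test_one_compartment_recovers_volume(self):
        v, k, dose = 62.3, 0.08, 10.0
        t = np.arange(0, 150.05, 0.05)
        c = dose * 1000.0 / v * np.exp(-k * t)
        assert vss_moment(_Arr(t, c), dose) == pytest.approx(v, rel=1e-3)

    def test_two_compartment_closed_form(self):
        # central V1 with micro-constants k10, k12, k21:
        # Vss = V1 * (1 + k12/k21); profile built from the exact
        # bi-exponential solution (eigen-decomposition oracle)
        v1, k10, k12, k21, dose = 20.0, 0.2, 0.15, 0.05, 10.0
        s = k10 + k12 + k21
        disc = np.sqrt(s**2 - 4 * k10 * k21)
        lam1, lam2 = (s + disc) / 2, (s - disc) / 2
        t = np.arange(0, 400.05, 0.05)
        c0 = dose * 1000.0 / v1
        c = c0 * ((lam1 - k21) * np.exp(-lam1 * t) + (k21 - lam2) * np.exp(-lam2 * t)) / (lam1 - lam2)
        expected = v1 * (1 + k12 / k21)
        assert vss_moment(_Arr(t, c), dose) == pytest.approx(expected, rel=2e-3)

    def test_truncated_tail_warns(self):
        t = np.arange(0, 4.05, 0.05)
        c = 1000.0 * np.exp(-0.05 * t)  # half-life 14 h, window 4 h
        with pytest.warns(UserWarning, match="extrapolated tail"):
            vss_moment(_Arr(t, c), 1.0)


class TestSummary:
    def test_summary_field_consistency(self):
        t = np.arange(0, 120.05, 0.05)
        c = 80 * (np.exp(-0.1 * t) - np.exp(-0.5 * t))
        s = pk_summary(t, c)
        assert s.cmax_ng_ml >= c.max() - 1e-12
        assert s.auc_last_ng_h_ml <= s.auc_inf_ng_h_ml
        assert s.tmax_h == pytest.approx(np.log(0.5 / 0.1) / 0.4, abs=0.05)

    def test_lambda_z_on_pure_exponential(self):
        t = np.arange(0, 100.05, 0.05)
        assert lambda_z(t, 50 * np.exp(-0.07 * t)) == pytest.approx(0.07, rel=1e-6)
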