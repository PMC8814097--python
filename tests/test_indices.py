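"""Pulsatility indices: decomposition, CI/RCI/CCI, compliance relations."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavatrack.errors import ConfigError, InputError
from cavatrack.indices import (
    SizeSeries,
    analyze,
    cardiac_caval_index,
    caval_index,
    compliance,
    decompose,
    respiratory_caval_index,
    segment_breaths,
    total_compliance,
)
from cavatrack.phantom import (
    PhantomSpec,
    PressureDrivers,
    PressureVolumeCurve,
    generate_long_axis,
    pressure_series,
    _true_indices,
)

from conftest import two_sinusoid_series

FPS = 30.0


class TestDecompose:
    def test_single_band_leaves_no_cardiac(self):
        t = np.arange(1800) / FPS
        x = 40.0 + 3.0 * np.sin(2 * np.pi * 0.25 * t)
        resp, card, _, _ = decompose(SizeSeries(x, FPS), f_cut=0.6)
        assert np.abs(card).max() < 0.05

    def test_two_sinusoid_amplitude_recovery(self):
        x, resp_true, card_true = two_sinusoid_series()
        resp, card, f_r, f_c = decompose(SizeSeries(x, FPS), f_cut=0.6)
        amp_r = 0.5 * (resp.max() - resp.min())
        amp_c = 0.5 * (card.max() - card.min())
        assert amp_r == pytest.approx(3.0, rel=0.05)
        assert amp_c == pytest.approx(0.8, rel=0.05)
        assert f_r == pytest.approx(0.25, abs=0.03)
        assert f_c == pytest.approx(1.2, abs=0.1)

    def test_components_sum_exactly_to_input(self):
        rng = np.random.default_rng(0)
        x = 40 + rng.normal(0, 1, 900).cumsum() * 0.01 + rng.normal(0, 0.3, 900)
        resp, card, _, _ = decompose(SizeSeries(x, FPS), f_cut=0.6)
        np.testing.assert_array_equal(resp + card, x)

    def test_config_errors(self):
        x = np.full(900, 40.0)
        with pytest.raises(ConfigError):
            decompose(SizeSeries(x, FPS), f_cut=20.0)
        with pytest.raises(InputError):
            decompose(SizeSeries(x[:60], FPS), f_cut=0.6)


class TestSegmentBreaths:
    def test_three_cosine_cycles_three_boundaries(self):
        t = np.arange(int(3 / 0.25 * FPS)) / FPS
        resp = 40.0 - 3.0 * (1 - np.cos(2 * np.pi * 0.25 * t))
        bounds = segment_breaths(resp, FPS)
        assert len(bounds) == 3

    def test_phantom_boundaries_near_inspiration_onsets(self):
        """Raised-cosine breathing: onsets recovered within 3 frames."""
        drv = PressureDrivers(A_card=0.8, A_resp=4.5, f_resp=0.25)
        curve = PressureVolumeCurve()
        p = pressure_series(drv, FPS, 720)
        d = 40.0 * np.sqrt(curve.volume(p) / curve.volume(drv.P_in_mean))
        d = d[60:]  # start mid-expiration: 5 complete interior breaths
        resp, _, f_r, f_c = decompose(SizeSeries(d, FPS), 0.6)
        bounds = segment_breaths(resp, FPS, f_r, raw=d, f_card_est=f_c)
        true_onsets = np.arange(0, 720, FPS / 0.25) - 60
        assert len(bounds) == 5
        for b in bounds:
            assert np.min(np.abs(true_onsets - b)) <= 3

    def test_monotone_series_has_no_cycle(self):
        with pytest.raises(InputError):
            segment_breaths(np.linspace(30, 40, 600), FPS)


class TestCavalIndex:
    def test_constant_series_gives_zero(self):
        s = SizeSeries(np.full(100, 30.0), FPS)
        assert caval_index(s, np.array([0, 99])) == 0.0

    def test_printed_toy_breath(self):
        """One breath swinging 25 down to 15 must give CI = 0.4 exactly."""
        t = np.arange(120) / FPS
        x = 20.0 + 5.0 * np.cos(2 * np.pi * 0.25 * t)
        ci = caval_index(SizeSeries(x, FPS), np.array([0, 119]))
        assert ci == pytest.approx(0.4, abs=1e-6)

    def test_phantom_recovery_within_002(self, dynamic_long):
        _, _, truth = dynamic_long
        series = SizeSeries(truth.size_series, FPS)
        rep = analyze(series)
        assert rep.ci == pytest.approx(truth.ci, abs=0.02)


class TestRespiratoryCavalIndex:
    def test_no_cardiac_content_makes_rci_equal_ci(self):
        t = np.arange(1800) / FPS
        x = 40.0 + 3.0 * np.sin(2 * np.pi * 0.25 * t)
        s = SizeSeries(x, FPS)
        resp, _, f_r, _ = decompose(s, 0.6)
        bounds = segment_breaths(resp, FPS, f_r)
        assert (respiratory_caval_index(resp, bounds)
                == pytest.approx(caval_index(s, bounds), abs=1e-6))

    def test_pure_cardiac_series_has_tiny_rci(self):
        t = np.arange(1800) / FPS
        x = 40.0 + 0.8 * np.sin(2 * np.pi * 1.2 * t)
        resp, _, _, _ = decompose(SizeSeries(x, FPS), 0.6)
        bounds = np.array([0, 900, 1799])  # arbitrary windows
        assert respiratory_caval_index(resp, bounds) < 0.02

    def test_two_sinusoid_value(self):
        """RCI of the bench series is 2·3/(40+3) = 0.1395."""
        x, _, _ = two_sinusoid_series()
        rep = analyze(SizeSeries(x, FPS))
        assert rep.rci == pytest.approx(6.0 / 43.0, rel=0.05)


class TestCardiacCavalIndex:
    def test_zero_cardiac_component(self):
        resp = 40 + np.sin(2 * np.pi * 0.25 * np.arange(900) / FPS)
        card = np.zeros(900)
        assert cardiac_caval_index(card, resp, FPS) == pytest.approx(0.0,
                                                                     abs=1e-6)

    def test_two_sinusoid_against_brute_force_oracle(self):
        """Median per-beat index, beats segmented at the known 1.2 Hz."""
        x, _, _ = two_sinusoid_series()
        period = FPS / 1.2
        starts = np.round(np.arange(0.75 * period, len(x), period)).astype(int)
        oracle_vals = [
            (x[a:b + 1].max() - x[a:b + 1].min()) / x[a:b + 1].max()
            for a, b in zip(starts[:-1], starts[1:]) if b < len(x)
        ]
        oracle = float(np.median(oracle_vals))
        rep = analyze(SizeSeries(x, FPS))
        assert rep.cci == pytest.approx(oracle, rel=0.10)

    def test_scale_invariance_of_all_indices(self):
        x, _, _ = two_sinusoid_series()
        r1 = analyze(SizeSeries(x, FPS))
        r2 = analyze(SizeSeries(2.0 * x, FPS))
        assert r2.ci == pytest.approx(r1.ci, abs=1e-9)
        assert r2.rci == pytest.approx(r1.rci, abs=1e-9)
        assert r2.cci == pytest.approx(r1.cci, abs=1e-9)

    def test_too_few_cycles_error(self):
        """A two-second clip holds at most two heartbeats: not enough."""
        t = np.arange(60) / FPS
        resp = np.full(60, 40.0)
        card = 0.3 * np.sin(2 * np.pi * 1.0 * t)
        with pytest.raises(InputError):
            cardiac_caval_index(card, resp, FPS)


class TestCompliance:
    def test_direct_formula(self):
        assert compliance(4.0, 2.0) == 2.0
        assert compliance(0.0, 2.0) == 0.0
        with pytest.raises(InputError):
            compliance(1.0, 0.0)

    def test_logistic_slope_at_half_volume(self, curve):
        """Numerical ΔV/ΔP at P_half equals V_max/(4k) within 1%."""
        h = 0.05
        c_num = compliance(curve.volume(curve.P_half + h)
                           - curve.volume(curve.P_half - h), 2 * h)
        assert c_num == pytest.approx(curve.V_max / (4 * curve.k), rel=0.01)

    def test_total_compliance_closed_forms(self):
        assert total_compliance(2.0, 2.0) == pytest.approx(1.0)
        assert total_compliance(3.0, 6.0) == pytest.approx(2.0)
        assert total_compliance(3.0, 1e9) == pytest.approx(3.0, abs=1e-6)
        with pytest.raises(InputError):
            total_compliance(-1.0, 2.0)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_total_compliance_below_both(self, cv, cev):
        ct = total_compliance(cv, cev)
        assert ct < cv and ct < cev


class TestParameterRecovery:
    def _make(self, p_in, a_resp, a_card, n=1800):
        curve = PressureVolumeCurve()
        drv = PressureDrivers(P_in_mean=p_in, A_resp=a_resp, A_card=a_card)
        p = pressure_series(drv, FPS, n)
        d = 40 * np.sqrt(curve.volume(p) / curve.volume(p_in))
        p_r = pressure_series(dataclasses.replace(drv, A_card=0.0), FPS, n)
        d_r = 40 * np.sqrt(curve.volume(p_r) / curve.volume(p_in))
        return d, _true_indices(d, d_r, FPS, drv, n)[:3]

    def test_recovery_on_random_volume_states(self):
        """CI/RCI/CCI recovered across seeded volume states."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            d, (ci, rci, cci) = self._make(rng.uniform(0.5, 12),
                                           rng.uniform(3, 7),
                                           rng.uniform(0.5, 1.2))
            rep = analyze(SizeSeries(d, FPS))
            assert rep.ci == pytest.approx(ci, abs=0.02)
            assert rep.rci == pytest.approx(rci, rel=0.10)
            assert rep.cci == pytest.approx(cci, rel=0.10)

    def test_high_pressure_means_bigger_vessel_lower_pulsatility(self):
        d_lo, (ci_lo, _, _) = self._make(2.0, 4.5, 0.8)
        d_hi, (ci_hi, _, _) = self._make(12.0, 4.5, 0.8)
        assert d_hi.mean() > d_lo.mean()
        assert ci_hi < ci_lo
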