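"""Estimator correctness: closed forms, OLS oracle, NLS refinement, maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from adcconcord.fitting import (
    FitConfig,
    adc_hi_low,
    adc_two_point,
    fit_loglinear,
    fit_nls,
    fit_perfusion_minimized,
    fit_volume,
    grid_search_adc,
)
from adcconcord.synth import rician_sample

B4_BREAST = np.array([0.0, 100.0, 600.0, 800.0])
B4_PHANTOM = np.array([0.0, 500.0, 900.0, 2000.0])


def _signal(s0, adc, bs):
    return s0 * np.exp(-np.asarray(bs) * adc)


class TestTwoPoint:
    def test_explicit_solution(self):
        assert adc_two_point(1000.0, 1000 * np.exp(-0.8), 0.0, 800.0) == pytest.approx(
            1.0e-3, rel=1e-12)

    def test_equal_signals_give_zero(self):
        assert adc_two_point(500.0, 500.0, 0.0, 800.0) == 0.0

    def test_rising_signal_gives_negative_adc(self):
        assert adc_two_point(100.0, 110.0, 0.0, 800.0) < 0

    def test_nonpositive_signal_masks_not_raises(self):
        assert np.isnan(adc_two_point(0.0, 10.0, 0.0, 800.0))
        assert np.isnan(adc_two_point(10.0, -1.0, 0.0, 800.0))

    def test_b_order_enforced(self):
        with pytest.raises(ValueError):
            adc_two_point(1.0, 1.0, 800.0, 0.0)


class TestLogLinear:
    @pytest.mark.parametrize("adc", [0.12e-3, 0.5e-3, 1.2e-3])
    @pytest.mark.parametrize("bs", [B4_BREAST, B4_PHANTOM])
    def test_noiseless_exact_recovery(self, adc, bs):
        a, s0 = fit_loglinear(_signal(900.0, adc, bs), bs)
        assert a == pytest.approx(adc, rel=1e-12)
        assert s0 == pytest.approx(900.0, rel=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(s1=st.floats(10, 1e4), s2=st.floats(10, 1e4),
           b2=st.floats(100, 3000))
    def test_two_point_input_equals_explicit_solution(self, s1, s2, b2):
        a_ll, _ = fit_loglinear([s1, s2], [0.0, b2])
        assert a_ll == pytest.approx(adc_two_point(s1, s2, 0.0, b2), rel=1e-9, abs=1e-15)

    def test_matches_hand_computed_normal_equations(self):
        """Perturbed point set against the closed-form OLS solution."""
        bs = B4_BREAST
        sig = _signal(800.0, 1.1e-3, bs) * np.array([1.02, 0.97, 1.05, 0.99])
        y = np.log(sig)
        n = bs.size
        slope = (n * np.sum(bs * y) - bs.sum() * y.sum()) / (
            n * np.sum(bs ** 2) - bs.sum() ** 2)
        intercept = y.mean() - slope * bs.mean()
        a, s0 = fit_loglinear(sig, bs)
        assert a == pytest.approx(-slope, rel=1e-12)
        assert s0 == pytest.approx(np.exp(intercept), rel=1e-12)

    def test_weighted_variant_matches_weighted_normal_equations(self):
        bs = B4_BREAST
        sig = _signal(800.0, 1.1e-3, bs) * np.array([1.02, 0.97, 1.05, 0.99])
        w = sig
        y = np.log(sig)
        bw = np.sum(w * bs) / w.sum()
        yw = np.sum(w * y) / w.sum()
        slope = np.sum(w * (bs - bw) * (y - yw)) / np.sum(w * (bs - bw) ** 2)
        a, _ = fit_loglinear(sig, bs, weighted=True)
        assert a == pytest.approx(-slope, rel=1e-12)


class TestNLS:
    @pytest.mark.parametrize("bs", [B4_BREAST, B4_PHANTOM])
    def test_noiseless_recovery_equals_loglinear(self, bs):
        sig = _signal(700.0, 0.9e-3, bs)
        a_nls, s0, conv = fit_nls(sig, bs)
        assert conv
        assert a_nls == pytest.approx(0.9e-3, rel=1e-9)
        assert s0 == pytest.approx(700.0, rel=1e-9)

    def test_objective_never_worse_than_initialization(self):
        """LM only accepts cost-decreasing steps from the log-linear start."""
        rng = np.random.default_rng(4)
        for _ in range(50):
            adc = rng.uniform(0.3e-3, 2.0e-3)
            sig = rician_sample(rng, _signal(600.0, adc, B4_BREAST), 600 / 20)
            a_ll, s0_ll = fit_loglinear(sig, B4_BREAST)
            a_n, s0_n, _ = fit_nls(sig, B4_BREAST)
            sse_ll = np.sum((s0_ll * np.exp(-B4_BREAST * a_ll) - sig) ** 2)
            sse_n = np.sum((s0_n * np.exp(-B4_BREAST * a_n) - sig) ** 2)
            assert sse_n <= sse_ll + 1e-9

    def test_matches_brute_force_grid_search(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            adc = rng.uniform(0.8e-3, 2.2e-3)
            sig = rician_sample(rng, _signal(600.0, adc, B4_BREAST), 600 / 30)
            a_n, _, _ = fit_nls(sig, B4_BREAST)
            hits += abs(a_n - grid_search_adc(sig, B4_BREAST)) <= 1e-7
        assert hits >= 19

    def test_nonpositive_signal_masked(self):
        a, s0, conv = fit_nls([1000.0, -5.0, 300.0, 200.0], B4_BREAST)
        assert np.isnan(a) and not conv


class TestPerfusionMinimized:
    def test_worked_example(self):
        """S(0)=1000 with a (900, 1.0e-3) slow component sampled at
        b={100,600,800} recovers ADCslow=1.0e-3 and Pf=0.100 exactly."""
        bs = np.array([0.0, 100.0, 600.0, 800.0])
        sig = np.array([1000.0, 900 * np.exp(-0.1), 900 * np.exp(-0.6),
                        900 * np.exp(-0.8)])
        for method in ("loglinear", "nls"):
            adc_slow, s0_slow, pf = fit_perfusion_minimized(sig, bs, method)
            assert adc_slow == pytest.approx(1.0e-3, rel=1e-9)
            assert s0_slow == pytest.approx(900.0, rel=1e-9)
            assert pf == pytest.approx(0.100, abs=1e-9)

    def test_pure_monoexponential_gives_zero_pf(self):
        bs = B4_BREAST
        sig = _signal(1000.0, 1.3e-3, bs)
        _, _, pf = fit_perfusion_minimized(sig, bs)
        assert pf == pytest.approx(0.0, abs=1e-12)

    def test_slow_fast_pseudodiffusion_biases_slow_fit(self):
        """When the fast component has not fully decayed by b=100
        (d_fast=0.02), its residual elevates the b=100 point: the slow-fit
        slope steepens (ADCslow biased up) and the extrapolated S0slow is
        inflated, so Pf is biased downward.  The bias grows as the fast
        component decays more slowly."""
        bs = B4_BREAST
        pf_true, adc, s0 = 0.1, 1.0e-3, 1000.0
        biases = []
        for d_fast in (0.05, 0.02, 0.01):
            sig = s0 * ((1 - pf_true) * np.exp(-bs * adc)
                        + pf_true * np.exp(-bs * d_fast))
            adc_hat, _, pf_hat = fit_perfusion_minimized(sig, bs)
            assert adc_hat > adc
            assert pf_hat < pf_true
            biases.append(pf_true - pf_hat)
        assert biases[0] < biases[1] < biases[2]

    def test_requires_b0_and_two_high_b(self):
        with pytest.raises(ValueError, match="b=0"):
            fit_perfusion_minimized([1.0, 2.0], [100.0, 800.0])
        with pytest.raises(ValueError, match="100"):
            fit_perfusion_minimized([1.0, 2.0], [0.0, 800.0])


class TestHiLow:
    def test_two_point_on_extreme_b(self):
        sig = [1000.0, 500.0, 300.0, 1000 * np.exp(-0.24)]
        assert adc_hi_low(sig, B4_PHANTOM) == pytest.approx(0.12e-3, rel=1e-12)

    def test_noiseless_equals_full_fit(self):
        sig = _signal(1000.0, 0.7e-3, B4_PHANTOM)
        a_hl = adc_hi_low(sig, B4_PHANTOM)
        a_ll, _ = fit_loglinear(sig, B4_PHANTOM)
        assert a_hl == pytest.approx(a_ll, rel=1e-12)

    def test_missing_b0_rejected(self):
        with pytest.raises(ValueError, match="b=0"):
            adc_hi_low([1.0, 2.0], [100.0, 800.0])


class TestFitVolume:
    def test_noiseless_phantom_map_equals_truth(self, phantom_spec, phantom_adc4_map):
        from adcconcord.synth import phantom_truth_map

        truth = phantom_truth_map(phantom_spec) * 1e6
        inside = truth > 0
        assert np.allclose(phantom_adc4_map.values[inside], truth[inside], rtol=1e-9)
        assert phantom_adc4_map.mask[inside].all()
        assert not phantom_adc4_map.mask[~inside].any()

    def test_nls_map_equals_loglinear_map_noiseless(self, phantom_trace):
        m_ll = fit_volume(phantom_trace, FitConfig(method="loglinear"), "ADC4")
        m_nls = fit_volume(phantom_trace, FitConfig(method="nls"), "ADC4")
        sel = m_ll.mask
        assert np.allclose(m_nls.values[sel], m_ll.values[sel], rtol=1e-9)

    def test_nan_voxels_are_masked(self, phantom_trace):
        st = phantom_trace.copy()
        st.images[500.0][0, 1, 64, 64] = np.nan
        m = fit_volume(st, FitConfig(method="loglinear"), "ADC4")
        assert not m.mask[1, 64, 64]
        assert m.values[1, 64, 64] == 0.0

    def test_metric_b_value_mismatch_names_missing_b(self, phantom_trace):
        with pytest.raises(ValueError, match="exactly 2 b-values"):
            fit_volume(phantom_trace, FitConfig(), "ADC2")
        no_b0 = phantom_trace.copy()
        del no_b0.images[0.0]
        no_b0.b_values = tuple(b for b in no_b0.b_values if b != 0.0)
        with pytest.raises(ValueError, match="b=0"):
            fit_volume(no_b0, FitConfig(), "ADChi-low")

    def test_perfusion_maps_on_noiseless_breast(self):
        from adcconcord.synth import default_breast_spec, make_breast

        spec = default_breast_spec(seed=9)
        study = make_breast(spec)
        cfg = FitConfig(method="loglinear")
        adc_slow = fit_volume(study, cfg, "ADCslow")
        pf = fit_volume(study, cfg, "PerfFrac")
        m = spec.tumor_mask
        # the d_fast=0.05 fast residual at b>=100 perturbs the slow fit by
        # well under 1% (ADC) / 0.005 (Pf) even at the largest Pf in the field
        assert np.allclose(adc_slow.values[m],
                           spec.adc_slow_field[m] * 1e6, rtol=5e-3)
        assert np.allclose(pf.values[m], spec.perf_fraction_field[m], atol=5e-3)
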