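"""Sensitivity integral and homeostatic weight rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad
from scipy.special import expit

import intensitynet as inet
from intensitynet import LogisticUnit
from intensitynet.homeostasis import WeightPositivityError


class TestSensitivityIntegral:
    @settings(derandomize=True, max_examples=50)
    @given(
        a=st.floats(-3, 3),
        b=st.floats(0.2, 3),
        c0=st.floats(-5, 0),
        width=st.floats(0.5, 8),
    )
    def test_closed_form_matches_quadrature(self, a, b, c0, width):
        c1 = c0 + width
        closed = inet.sensitivity(a, b, c0, c1).s
        numeric, _ = quad(lambda i: expit(4 * b * (i - a)), c0, c1, epsabs=1e-12)
        assert abs(closed - numeric) < 1e-8

    def test_limits(self):
        # very sensitive unit: integral approaches the full range width;
        # very insensitive unit: integral approaches zero
        assert inet.sensitivity(-50.0, 1.2, -2, 2).s == pytest.approx(4.0, abs=1e-6)
        assert inet.sensitivity(50.0, 1.2, -2, 2).s == pytest.approx(0.0, abs=1e-6)

    def test_point_symmetry_at_midrange(self):
        assert inet.sensitivity(0.5, 0.8, -1, 2).s == pytest.approx(1.5)

    def test_strictly_decreasing_in_a(self):
        s = [inet.sensitivity(a, 1.0, -4, 4).s for a in np.linspace(-6, 6, 61)]
        assert np.all(np.diff(s) < 0)

    def test_bounds(self):
        s = inet.sensitivity(0.3, 1.2, -2, 2).s
        assert 0 < s < 4

    def test_invalid_range(self):
        with pytest.raises(ValueError):
            inet.sensitivity(0.0, 1.0, 2.0, -2.0)


class TestWeightRules:
    def test_w_exc_increases_with_a(self):
        # less sensitive unit -> stronger excitatory synapse
        w = [inet.homeostatic_w_exc(a, 1.0, 9.0, 1.0, -4, 4) for a in (-1, 0, 1)]
        assert w[0] < w[1] < w[2]

    def test_w_exc_vanishes_for_very_sensitive_unit(self):
        # with d = c1 - c0 the weight tends to 0+ as a -> -inf
        w = inet.homeostatic_w_exc(-8.0, 1.0, 8.0, 1.0, -4, 4)
        assert 0 < w < 1e-6

    def test_w_inh_magnitude_decreases_with_a(self):
        w = [inet.homeostatic_w_inh(a, 1.0, 1.0, -4, 4) for a in (-1, 0, 1)]
        assert abs(w[0]) > abs(w[1]) > abs(w[2])
        assert all(v < 0 for v in w)

    def test_w_inh_midrange_value(self):
        assert inet.homeostatic_w_inh(0.0, 0.5, 1.0, -4, 4) == pytest.approx(-0.25 * 8)

    def test_w_inh_vanishes_for_insensitive_unit(self):
        w = inet.homeostatic_w_inh(50.0, 1.0, 1.0, -4, 4)
        assert -1e-6 < w < 0


class TestResolveWeights:
    def test_mode_none_passthrough(self):
        spec = inet.CircuitSpec(
            exc_units=(LogisticUnit(a=0.0, b=1.0),),
            inh_unit=LogisticUnit(a=0.0, b=0.5, asymptote=2.0),
            w_exc=(1.0,),
            w_inh=(-1.0,),
        )
        w_exc, w_inh = inet.resolve_weights(spec)
        assert tuple(w_exc) == (1.0,) and tuple(w_inh) == (-1.0,)

    def test_excitatory_mode_profile(self, spec_exc):
        w_exc, w_inh = inet.resolve_weights(spec_exc)
        assert np.all(np.diff(w_exc) > 0)  # increasing with a_k
        assert np.all(w_exc > 0)
        np.testing.assert_array_equal(w_inh, -np.ones(spec_exc.n_units))

    def test_inhibitory_mode_profile(self, spec_inh):
        w_exc, w_inh = inet.resolve_weights(spec_inh)
        np.testing.assert_array_equal(w_exc, np.ones(spec_inh.n_units))
        assert np.all(np.diff(np.abs(w_inh)) < 0)  # |w_inh| decreasing with a_k

    def test_positivity_violation_names_the_unit(self, spec_exc):
        import dataclasses

        bad = dataclasses.replace(spec_exc, d=0.0)  # d below every s(a_k)
        with pytest.raises(WeightPositivityError, match="unit 0"):
            inet.resolve_weights(bad)


class TestAlignedConstruction:
    def test_reproduces_alignment_weights(self, spec_exc):
        # the construction solves (c0, c1, alpha, d) so that the homeostatic
        # rule yields w_exc[k] = inh'(a_k) / b exactly
        w_exc, _ = inet.resolve_weights(spec_exc)
        u = spec_exc.inh_unit
        for k, a in enumerate(spec_exc.a_values):
            sig = expit(4 * u.b * (a - u.a))
            slope = 4 * u.b * u.asymptote * sig * (1 - sig)
            assert w_exc[k] == pytest.approx(slope / spec_exc.exc_units[k].b, rel=1e-9)

    def test_peak_ordering_in_both_modes(self, spec_exc, spec_inh, grid):
        for spec in (spec_exc, spec_inh):
            peaks = [
                inet.curve_shape(c).peak_intensity
                for c in inet.tuning_curves(spec, grid)
            ]
            assert np.all(np.diff(peaks) > 0)

    def test_either_mode_creates_a_crossing(self, spec_exc, spec_inh, grid):
        for spec in (spec_exc, spec_inh):
            curves = inet.tuning_curves(spec, grid)
            crossing = any(
                np.any(curves[j].values > curves[k].values + 1e-9)
                and np.any(curves[k].values > curves[j].values + 1e-9)
                for j in range(len(curves))
                for k in range(j + 1, len(curves))
            )
            assert crossing

    def test_infeasible_anchors_rejected(self):
        with pytest.raises(ValueError):
            inet.aligned_circuit(b_inh=0.2)  # alignment needs b_inh > b/2
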