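"""Input- and intermediate-layer response functions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import intensitynet as inet
from intensitynet import CircuitSpec, LogisticUnit


class TestLogisticResponses:
    def test_half_activation_at_turning_point(self):
        unit = LogisticUnit(a=0.0, b=1.0)
        assert inet.exc_response(unit, 0.0) == pytest.approx(0.5)

    def test_saturates_at_asymptote(self):
        unit = LogisticUnit(a=0.0, b=1.0)
        assert inet.exc_response(unit, 100.0) == pytest.approx(1.0, abs=1e-12)
        inh = LogisticUnit(a=0.0, b=0.5, asymptote=2.0)
        assert inet.inh_response(inh, -100.0) == pytest.approx(0.0, abs=1e-12)

    def test_inhibitory_half_asymptote_at_turning_point(self):
        unit = LogisticUnit(a=0.0, b=0.5, asymptote=1.2)
        assert inet.inh_response(unit, 0.0) == pytest.approx(0.6)

    def test_inhibitory_is_scaled_excitatory(self):
        i = np.linspace(-5, 5, 201)
        inh = LogisticUnit(a=0.7, b=0.3, asymptote=1.8)
        exc = LogisticUnit(a=0.7, b=0.3, asymptote=1.0)
        np.testing.assert_allclose(
            inet.inh_response(inh, i), 1.8 * inet.exc_response(exc, i), rtol=1e-14
        )

    @settings(derandomize=True, max_examples=60)
    @given(
        a=st.floats(-5, 5),
        b=st.floats(0.1, 1.8),
        delta=st.floats(-4, 4),
    )
    def test_bounds_and_monotonicity(self, a, b, delta):
        # offsets kept inside the range where the logistic is not yet
        # saturated to 1.0 in double precision
        unit = LogisticUnit(a=a, b=b)
        i = a + delta
        r = inet.exc_response(unit, i)
        assert 0.0 < r < 1.0
        assert inet.exc_response(unit, i + 0.1) > r

    @settings(derandomize=True, max_examples=60)
    @given(a=st.floats(-5, 5), b=st.floats(0.1, 5))
    def test_slope_at_turning_point_equals_b(self, a, b):
        # the factor 4 in the exponent makes b exactly the central slope
        unit = LogisticUnit(a=a, b=b)
        h = 1e-6
        fd = (inet.exc_response(unit, a + h) - inet.exc_response(unit, a - h)) / (2 * h)
        assert fd == pytest.approx(b, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            LogisticUnit(a=0.0, b=-1.0)
        with pytest.raises(ValueError):
            LogisticUnit(a=0.0, b=1.0, asymptote=0.0)
        unit = LogisticUnit(a=0.0, b=1.0)
        with pytest.raises(ValueError):
            inet.exc_response(unit, np.nan)
        with pytest.raises(ValueError):
            inet.exc_response(LogisticUnit(a=0, b=1, asymptote=2.0), 0.0)
        with pytest.raises(ValueError):
            inet.inh_response(unit, 0.0)


def _manual_spec(w_exc, w_inh, mode="none"):
    return CircuitSpec(
        exc_units=(LogisticUnit(a=0.0, b=1.0),),
        inh_unit=LogisticUnit(a=0.0, b=0.5, asymptote=2.0),
        w_exc=w_exc,
        w_inh=w_inh,
        homeostasis_mode=mode,
    )


class TestIntermediateResponse:
    def test_rectifies_negative_drive(self):
        spec = _manual_spec((1.0,), (-1.0,))
        # at i = 0: exc = 0.5, inh = 1.0 -> drive negative -> rectified to 0
        assert inet.intermediate_response(spec, 0, 0.0) == 0.0

    def test_linear_regime_matches_weighted_sum(self):
        spec = _manual_spec((1.0,), (-0.2,))
        i = 1.3
        expected = inet.exc_response(spec.exc_units[0], i) - 0.2 * inet.inh_response(
            spec.inh_unit, i
        )
        assert inet.intermediate_response(spec, 0, i) == pytest.approx(expected)

    def test_index_out_of_range(self):
        spec = _manual_spec((1.0,), (-1.0,))
        with pytest.raises(IndexError):
            inet.intermediate_response(spec, 1, 0.0)

    def test_bell_shape_with_default_circuit(self, spec_none, grid):
        # uniform weights, b > b_inh, inh_max > 1: every curve vanishes at
        # both grid ends and is positive somewhere in between
        for curve in inet.tuning_curves(spec_none, grid):
            assert curve.values[0] == 0.0
            assert curve.values[-1] == 0.0
            assert curve.values.max() > 0.0


class TestTuningCurves:
    def test_nested_without_homeostasis(self, spec_none, grid):
        # shared inhibition + shifted excitation: the more sensitive unit's
        # curve dominates pointwise
        curves = inet.tuning_curves(spec_none, grid)
        for lo, hi in zip(curves, curves[1:]):
            assert np.all(lo.values >= hi.values - 1e-12)

    def test_homeostasis_breaks_nesting(self, spec_exc, grid):
        curves = inet.tuning_curves(spec_exc, grid)
        report = inet.nestedness(curves)
        assert not report.fully_nested

    def test_single_unit_without_inhibition_is_monotonic(self, grid):
        spec = CircuitSpec(
            exc_units=(LogisticUnit(a=0.0, b=1.0),),
            inh_unit=LogisticUnit(a=0.0, b=0.5, asymptote=2.0),
            w_exc=(0.7,),
            w_inh=(0.0,),
        )
        (curve,) = inet.tuning_curves(spec, grid)
        np.testing.assert_allclose(
            curve.values, 0.7 * inet.exc_response(spec.exc_units[0], grid), rtol=1e-14
        )
        assert np.all(np.diff(curve.values) > 0)

    def test_grid_validation(self, spec_none):
        with pytest.raises(ValueError):
            inet.tuning_curves(spec_none, [])
        with pytest.raises(ValueError):
            inet.tuning_curves(spec_none, [0.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            inet.tuning_curves(spec_none, np.linspace(-1, 1, 50))  # span too small


class TestCircuitSpecValidation:
    def test_inhibition_must_be_shallower(self):
        with pytest.raises(ValueError):
            CircuitSpec(
                exc_units=(LogisticUnit(a=0.0, b=0.4),),
                inh_unit=LogisticUnit(a=0.0, b=0.5, asymptote=2.0),
                w_exc=(1.0,),
                w_inh=(-1.0,),
            )

    def test_inh_max_above_one(self):
        with pytest.raises(ValueError):
            CircuitSpec(
                exc_units=(LogisticUnit(a=0.0, b=1.0),),
                inh_unit=LogisticUnit(a=0.0, b=0.5, asymptote=0.9),
                w_exc=(1.0,),
                w_inh=(-1.0,),
            )

    def test_weight_length_mismatch(self):
        with pytest.raises(ValueError):
            CircuitSpec(
                exc_units=(LogisticUnit(a=0.0, b=1.0),),
                inh_unit=LogisticUnit(a=0.0, b=0.5, asymptote=2.0),
                w_exc=(1.0, 1.0),
                w_inh=(-1.0,),
            )
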