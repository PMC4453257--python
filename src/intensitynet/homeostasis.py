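"""Homeostatic synaptic weight rules and the aligned default circuit.

Homeostatic plasticity is modelled as a static mean effect: instead of
simulating the weight change caused by every stimulus presentation, each
synapse is scaled once according to how often its presynaptic excitatory
neuron is driven.  The drive proxy is the sensitivity integral of the unit's
logistic response over a reference exposure range [c0, c1],

    s(a) = Integral_{c0}^{c1} exc(i) di
         = (1/4b) ln[(1 + e^{4b(c1-a)}) / (1 + e^{4b(c0-a)})],

which approaches c1 - c0 for a -> -inf and 0 for a -> +inf.  Two scenarios
are supported:

- excitatory scaling: w_inh = -1 uniformly, w_exc(a) = -alpha (s(a) - d)
  (sensitive units get weaker excitatory synapses; d must keep w_exc > 0);
- inhibitory scaling: w_exc = 1 uniformly, w_inh(a) = -alpha_tilde s(a)
  (sensitive units get stronger local inhibition).

Either rule breaks the pointwise nesting of the intermediate tuning curves
and thereby makes intensity-specific memories possible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .circuit import (
    MODE_EXCITATORY,
    MODE_INHIBITORY,
    MODE_NONE,
    CircuitSpec,
    LogisticUnit,
)

__all__ = [
    "SensitivityScore",
    "WeightPositivityError",
    "sensitivity",
    "homeostatic_w_exc",
    "homeostatic_w_inh",
    "resolve_weights",
    "aligned_circuit",
    "default_circuit",
]


class WeightPositivityError(ValueError):
    """Raised when the excitatory homeostatic rule yields a weight <= 0."""


@dataclass(frozen=True)
class SensitivityScore:
    """Sensitivity integral of a logistic unit over [c0, c1].

    ``s`` lies strictly between 0 and ``c1 - c0`` and decreases strictly
    with the turning point ``a``.
    """

    a: float
    s: float


def _sensitivity_value(a: float, b: float, c0: float, c1: float) -> float:
    # softplus formulation of the closed form; immune to exp overflow
    return (np.logaddexp(0.0, 4.0 * b * (c1 - a)) - np.logaddexp(0.0, 4.0 * b * (c0 - a))) / (
        4.0 * b
    )


def sensitivity(a: float, b: float, c0: float, c1: float) -> SensitivityScore:
    """Closed-form sensitivity integral of a logistic unit.

    Equals the integral of ``1/(exp(-4b(i-a)) + 1)`` over ``[c0, c1]``
    (matches adaptive quadrature to better than 1e-8).
    """
    if not c0 < c1:
        raise ValueError("c0 < c1 is required")
    if not b > 0:
        raise ValueError("b must be > 0")
    return SensitivityScore(a=float(a), s=float(_sensitivity_value(a, b, c0, c1)))


def homeostatic_w_exc(
    a: float, alpha: float, d: float, b: float, c0: float, c1: float
) -> float:
    """Excitatory-scaling rule ``w_exc(a) = -alpha (s(a) - d)``.

    Strictly increasing in ``a``: the less sensitive an input neuron, the
    stronger its synapse onto the intermediate layer.  Positivity of the
    result is enforced where units are configured, in :func:`resolve_weights`.
    """
    if not alpha > 0:
        raise ValueError("alpha must be > 0")
    return -alpha * (sensitivity(a, b, c0, c1).s - d)


def homeostatic_w_inh(
    a: float, alpha_tilde: float, b: float, c0: float, c1: float
) -> float:
    """Inhibitory-scaling rule ``w_inh(a) = -alpha_tilde s(a)``.

    The magnitude decreases strictly with ``a``: the smaller the excitatory
    drive of an intermediate neuron, the weaker its inhibitory input.
    """
    if not alpha_tilde > 0:
        raise ValueError("alpha_tilde must be > 0")
    return -alpha_tilde * sensitivity(a, b, c0, c1).s


def resolve_weights(spec: CircuitSpec) -> tuple[np.ndarray, np.ndarray]:
    """Effective (w_exc, w_inh) vectors for ``spec.homeostasis_mode``."""
    mode = spec.homeostasis_mode
    if mode == MODE_NONE:
        return np.array(spec.w_exc), np.array(spec.w_inh)
    k_range = range(spec.n_units)
    if mode == MODE_EXCITATORY:
        w_exc = np.array(
            [
                homeostatic_w_exc(
                    spec.exc_units[k].a,
                    spec.alpha,
                    spec.d,
                    spec.exc_units[k].b,
                    spec.c0,
                    spec.c1,
                )
                for k in k_range
            ]
        )
        bad = np.flatnonzero(w_exc <= 0)
        if bad.size:
            k = int(bad[0])
            raise WeightPositivityError(
                f"homeostatic w_exc <= 0 for unit {k} (a={spec.exc_units[k].a}); "
                "increase d so that w_exc(a) > 0 for every configured unit"
            )
        return w_exc, -np.ones(spec.n_units)
    if mode == MODE_INHIBITORY:
        w_inh = np.array(
            [
                homeostatic_w_inh(
                    spec.exc_units[k].a,
                    spec.alpha_tilde,
                    spec.exc_units[k].b,
                    spec.c0,
                    spec.c1,
                )
                for k in k_range
            ]
        )
        return np.ones(spec.n_units), w_inh
    raise ValueError(f"unknown homeostasis mode {mode!r}")  # pragma: no cover


# ---------------------------------------------------------------------------
# Aligned default circuit
# ---------------------------------------------------------------------------
#
# The structural constraints (b > b_inh, inh_max > 1, a_k spaced one log
# unit) leave the actual parameter values open.  The defaults below are fixed
# by a peak-alignment construction: in the excitatory-scaling scenario we
# require each intermediate tuning curve to peak exactly at its unit's
# turning point a_k.  At i = a_k the excitatory response has slope b, so the
# stationarity condition reads
#
#     w_exc[k] * b = inh'(a_k),
#
# and positivity of the curve at the peak additionally demands
# inh'(a)/inh(a) > 2b there, i.e. b_inh > b/2 with the inhibitory turning
# point well to the right of the a_k.  Given anchors (a_inh, b_inh, inh_max)
# satisfying this, the construction solves for (c0, c1, alpha, d) such that
# the homeostatic rule reproduces the aligned weights exactly, and sets
# alpha_tilde so that the inhibitory-scaling scenario aligns its least
# sensitive unit the same way.  Trained this way, the output neuron's recall
# curve peaks at the trained intensity because each training intensity
# recruits essentially one intermediate channel.


def _inh_slope(i: float, b_inh: float, a_inh: float, inh_max: float) -> float:
    sig = 1.0 / (1.0 + np.exp(-4.0 * b_inh * (i - a_inh)))
    return 4.0 * b_inh * inh_max * sig * (1.0 - sig)


def aligned_circuit(
    mode: str = MODE_NONE,
    K: int = 3,
    a_step: float = 1.0,
    b: float = 1.0,
    a_inh: float = 2.0,
    b_inh: float = 0.6,
    inh_max: float = 2.5,
    s_width: float = 1.5,
) -> CircuitSpec:
    """Default circuit fixed by the peak-alignment construction.

    Parameters
    ----------
    mode : str
        Homeostasis mode of the returned spec.
    K : int
        Number of excitatory input / intermediate neurons (>= 2).
    a_step : float
        Spacing of the excitatory turning points (log10 units); the a_k are
        centred on zero, e.g. (-1, 0, 1) for K=3, a_step=1.
    b, a_inh, b_inh, inh_max : float
        Input-layer anchors.  Alignment requires b_inh > b/2 and an
        inhibitory turning point to the right of the a_k.
    s_width : float
        Width c1 - c0 of the sensitivity-integration range; c0 is solved so
        the homeostatic rule reproduces the aligned weights.
    """
    if K < 2:
        raise ValueError("the aligned construction needs K >= 2")
    if not b_inh < b:
        raise ValueError("b_inh < b is required")
    if not inh_max > 1:
        raise ValueError("inh_max > 1 is required")
    a_vals = a_step * (np.arange(K) - (K - 1) / 2.0)
    # aligned excitatory-mode weights: w_k = inh'(a_k) / b
    w_aligned = np.array([_inh_slope(a, b_inh, a_inh, inh_max) for a in a_vals]) / b
    # sanity: positive curve value at the aligned peak
    inh_at = inh_max / (1.0 + np.exp(-4.0 * b_inh * (a_vals - a_inh)))
    if np.any(0.5 * w_aligned <= inh_at):
        raise ValueError(
            "alignment infeasible for these anchors: need inh'(a)/inh(a) > 2b "
            "at every excitatory turning point (use b_inh > b/2 and a_inh "
            "well above max a_k)"
        )

    def s_of(a: float, c0: float) -> float:
        return _sensitivity_value(a, b, c0, c0 + s_width)

    target = (w_aligned[-1] - w_aligned[0]) / (w_aligned[1] - w_aligned[0])

    def mismatch(c0: float) -> float:
        s0 = s_of(a_vals[0], c0)
        return (s0 - s_of(a_vals[-1], c0)) / (s0 - s_of(a_vals[1], c0)) - target

    # Bracket where the s-differences stay numerically representable:
    # for c0 far above max(a_k) the integrals all saturate at s_width and
    # their differences vanish in float arithmetic.
    lo, hi = a_vals[0] - 20.0, a_vals[-1] + 7.0
    if not mismatch(lo) * mismatch(hi) < 0:
        raise ValueError("alignment construction failed: no c0 bracket")
    c0 = brentq(mismatch, lo, hi, xtol=1e-13)
    c1 = c0 + s_width
    s_vals = np.array([s_of(a, c0) for a in a_vals])
    alpha = (w_aligned[1] - w_aligned[0]) / (s_vals[0] - s_vals[1])
    d = s_vals[0] + w_aligned[0] / alpha
    alpha_tilde = b / (s_vals[-1] * _inh_slope(a_vals[-1], b_inh, a_inh, inh_max))
    return CircuitSpec(
        exc_units=tuple(LogisticUnit(a=float(a), b=b) for a in a_vals),
        inh_unit=LogisticUnit(a=a_inh, b=b_inh, asymptote=inh_max),
        w_exc=(1.0,) * K,
        w_inh=(-1.0,) * K,
        homeostasis_mode=mode,
        alpha=float(alpha),
        alpha_tilde=float(alpha_tilde),
        d=float(d),
        c0=float(c0),
        c1=float(c1),
    )


#: Alias: the package default circuit is the aligned construction.
default_circuit = aligned_circuit
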