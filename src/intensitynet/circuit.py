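"""Input and intermediate layers of the feed-forward intensity-coding circuit.

The model is a three-layer rate circuit.  The input layer holds K excitatory
neurons with monotonic logistic intensity-response functions

    exc_k(i) = 1 / (exp(-4 b (i - a_k)) + 1)

shifted along the (log10) intensity axis by their turning points ``a_k``, plus
a single inhibitory neuron

    inh(i) = inh_max / (exp(-4 b_inh (i - a_inh)) + 1)

that is shallower than the excitatory units (``b_inh < b``) and has asymptote
``inh_max > 1``.  The factor 4 in the exponents makes ``b`` exactly the slope
of the curve at its turning point.  Each intermediate-layer neuron receives
one excitatory input and the shared inhibitory input and rectifies the
weighted sum,

    inter_k(i) = Rect(w_exc[k] exc_k(i) + w_inh[k] inh(i)),

which converts the monotonic input code into bell-shaped intensity tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import expit

__all__ = [
    "MODE_NONE",
    "MODE_EXCITATORY",
    "MODE_INHIBITORY",
    "HOMEOSTASIS_MODES",
    "LogisticUnit",
    "CircuitSpec",
    "TuningCurve",
    "exc_response",
    "inh_response",
    "intermediate_response",
    "tuning_curves",
    "default_grid",
]

MODE_NONE = "none"
MODE_EXCITATORY = "excitatory"
MODE_INHIBITORY = "inhibitory"
HOMEOSTASIS_MODES = (MODE_NONE, MODE_EXCITATORY, MODE_INHIBITORY)

#: Default evaluation grid: log10 intensity from -6 to 6 in steps of 0.01.
#: Wide enough that every intermediate response is exactly zero at both ends
#: under the default circuit.
DEFAULT_GRID_MIN = -6.0
DEFAULT_GRID_MAX = 6.0
DEFAULT_GRID_STEP = 0.01


def default_grid(
    lo: float = DEFAULT_GRID_MIN,
    hi: float = DEFAULT_GRID_MAX,
    step: float = DEFAULT_GRID_STEP,
) -> np.ndarray:
    """Uniform log10-intensity grid, endpoints inclusive."""
    n = int(round((hi - lo) / step))
    return lo + step * np.arange(n + 1)


@dataclass(frozen=True)
class LogisticUnit:
    """One monotonic input neuron.

    Parameters
    ----------
    a : float
        Turning-point intensity (log10 units).  A more negative ``a`` means a
        more sensitive neuron.
    b : float
        Slope of the response at the turning point (response units per log10
        intensity).  Must be positive.
    asymptote : float
        Maximal response.  1 for excitatory units; > 1 for the inhibitory
        unit, where it plays the role of ``inh_max``.
    """

    a: float
    b: float
    asymptote: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.a):
            raise ValueError("turning point a must be finite")
        if not (np.isfinite(self.b) and self.b > 0):
            raise ValueError("slope b must be finite and > 0")
        if not (np.isfinite(self.asymptote) and self.asymptote > 0):
            raise ValueError("asymptote must be finite and > 0")

    def response(self, i):
        """Logistic response at intensity ``i`` (scalar or array)."""
        i = _check_intensity(i)
        return self.asymptote * expit(4.0 * self.b * (i - self.a))


def _check_intensity(i):
    arr = np.asarray(i, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("intensity must be finite")
    return arr if arr.ndim else float(arr)


def exc_response(unit: LogisticUnit, i):
    """Excitatory input response ``1 / (exp(-4 b (i - a)) + 1)``.

    ``unit`` must have asymptote 1.  The value lies strictly in (0, 1) and is
    strictly increasing in ``i``.
    """
    if unit.asymptote != 1.0:
        raise ValueError("excitatory units must have asymptote 1")
    return unit.response(i)


def inh_response(unit: LogisticUnit, i):
    """Inhibitory input response ``inh_max / (exp(-4 b_inh (i - a_inh)) + 1)``.

    ``unit.asymptote`` is ``inh_max`` and must exceed 1; the value lies
    strictly in (0, inh_max).
    """
    if not unit.asymptote > 1.0:
        raise ValueError("the inhibitory unit must have asymptote (inh_max) > 1")
    return unit.response(i)


@dataclass(frozen=True)
class CircuitSpec:
    """Full parameterization of the three-layer circuit.

    ``w_exc``/``w_inh`` are the stored per-intermediate-neuron weights; the
    *effective* weights additionally depend on ``homeostasis_mode`` and are
    produced by :func:`intensitynet.homeostasis.resolve_weights`:

    - ``none``: stored weights used as given.
    - ``excitatory``: ``w_inh = -1`` uniformly; ``w_exc[k] = -alpha (s(a_k) - d)``
      with the sensitivity integral ``s`` over ``[c0, c1]``.
    - ``inhibitory``: ``w_exc = 1`` uniformly; ``w_inh[k] = -alpha_tilde s(a_k)``.
    """

    exc_units: tuple[LogisticUnit, ...]
    inh_unit: LogisticUnit
    w_exc: tuple[float, ...]
    w_inh: tuple[float, ...]
    homeostasis_mode: str = MODE_NONE
    alpha: float = 1.0
    alpha_tilde: float = 1.0
    d: float = 0.0
    c0: float = -4.0
    c1: float = 4.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "exc_units", tuple(self.exc_units))
        object.__setattr__(self, "w_exc", tuple(float(w) for w in self.w_exc))
        object.__setattr__(self, "w_inh", tuple(float(w) for w in self.w_inh))
        if len(self.exc_units) == 0:
            raise ValueError("at least one excitatory unit is required")
        if not (len(self.w_exc) == len(self.w_inh) == len(self.exc_units)):
            raise ValueError("w_exc, w_inh and exc_units must have equal length")
        for unit in self.exc_units:
            if unit.asymptote != 1.0:
                raise ValueError("excitatory units must have asymptote 1")
        if not self.inh_unit.asymptote > 1.0:
            raise ValueError("inh_max > 1 is required")
        for unit in self.exc_units:
            if not unit.b > self.inh_unit.b:
                raise ValueError(
                    "the inhibitory response must be less steep than every "
                    "excitatory response (b > b_inh)"
                )
        if self.homeostasis_mode not in HOMEOSTASIS_MODES:
            raise ValueError(f"unknown homeostasis mode {self.homeostasis_mode!r}")
        if any(w < 0 for w in self.w_exc):
            raise ValueError("stored excitatory weights must be >= 0")
        if any(w > 0 for w in self.w_inh):
            raise ValueError("stored inhibitory weights must be <= 0")
        if not (self.alpha > 0 and self.alpha_tilde > 0):
            raise ValueError("alpha and alpha_tilde must be > 0")
        if not self.c0 < self.c1:
            raise ValueError("c0 < c1 is required")

    @property
    def n_units(self) -> int:
        return len(self.exc_units)

    @property
    def a_values(self) -> np.ndarray:
        return np.array([u.a for u in self.exc_units])

    @property
    def inh_max(self) -> float:
        return self.inh_unit.asymptote


def _resolved(spec: CircuitSpec):
    # lazy import: the weight rules live in the homeostasis module
    from .homeostasis import resolve_weights

    return resolve_weights(spec)


def intermediate_response(spec: CircuitSpec, k: int, i):
    """Rectified response of intermediate neuron ``k`` at intensity ``i``.

    ``inter_k(i) = Rect(w_exc[k] exc_k(i) + w_inh[k] inh(i))`` with the
    effective weights resolved for ``spec.homeostasis_mode``; ``Rect(x<0)=0``,
    ``Rect(x>=0)=x``.
    """
    if not (isinstance(k, (int, np.integer)) and 0 <= k < spec.n_units):
        raise IndexError(f"neuron index {k} out of range [0, {spec.n_units})")
    w_exc, w_inh = _resolved(spec)
    drive = w_exc[k] * exc_response(spec.exc_units[k], i) + w_inh[k] * inh_response(
        spec.inh_unit, i
    )
    return np.maximum(0.0, drive)


@dataclass(frozen=True)
class TuningCurve:
    """Responses of one neuron over an intensity grid."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        if grid.shape != values.shape or grid.ndim != 1:
            raise ValueError("grid and values must be 1-d arrays of equal length")
        if grid.size == 0:
            raise ValueError("empty tuning curve")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("tuning-curve values must be >= 0")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "values", values)


def _check_grid(grid) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size == 0:
        raise ValueError("grid must be a non-empty 1-d array")
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid must be finite")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be strictly increasing")
    return grid


def tuning_curves(spec: CircuitSpec, grid) -> list[TuningCurve]:
    """Evaluate every intermediate neuron on ``grid``.

    The grid must be strictly increasing and span at least
    ``[min a_k - 3, max a_k + 3]`` so the flanks of every curve are covered.
    """
    grid = _check_grid(grid)
    a = spec.a_values
    if grid[0] > a.min() - 3.0 or grid[-1] < a.max() + 3.0:
        raise ValueError(
            "grid must span [min a_k - 3, max a_k + 3] = "
            f"[{a.min() - 3.0}, {a.max() + 3.0}]"
        )
    w_exc, w_inh = _resolved(spec)
    inh = inh_response(spec.inh_unit, grid)
    curves = []
    for k, unit in enumerate(spec.exc_units):
        drive = w_exc[k] * exc_response(unit, grid) + w_inh[k] * inh
        curves.append(TuningCurve(grid, np.maximum(0.0, drive)))
    return curves
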