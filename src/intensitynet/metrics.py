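"""Shape metrics for tuning curves and test batteries.

Quantifies what the model figures show qualitatively: where a curve peaks,
how wide it is (FWHM), whether it is monotonic, whether a family of curves is
pointwise nested, and how specifically a trained circuit recalls the trained
intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .circuit import TuningCurve
from .training import TestResult

__all__ = [
    "CurveShape",
    "NestednessReport",
    "curve_shape",
    "nestedness",
    "specificity_score",
    "fwhm_of",
]

#: Absolute tolerance for pointwise dominance comparisons.
DOMINANCE_TOL = 1e-12


@dataclass(frozen=True)
class CurveShape:
    peak_intensity: float
    peak_value: float
    fwhm: Optional[float]
    is_monotonic: bool
    support: Optional[tuple[float, float]]


def fwhm_of(grid: np.ndarray, values: np.ndarray) -> Optional[float]:
    """Full width at half maximum of the connected region around the peak.

    Half-max crossings are located by linear interpolation between grid
    points; returns ``None`` when the half-max level is not crossed on both
    sides of the peak within the grid (e.g. monotonic curves).
    """
    m = values.max()
    if m <= 0:
        return None
    p = int(np.argmax(values))
    half = m / 2.0
    left = np.flatnonzero(values[:p] < half)
    right = np.flatnonzero(values[p:] < half)
    if left.size == 0 or right.size == 0:
        return None
    l = int(left[-1])          # last point below half before the peak
    r = int(p + right[0])      # first point below half after the peak
    x_l = grid[l] + (half - values[l]) / (values[l + 1] - values[l]) * (
        grid[l + 1] - grid[l]
    )
    x_r = grid[r - 1] + (half - values[r - 1]) / (values[r] - values[r - 1]) * (
        grid[r] - grid[r - 1]
    )
    return float(x_r - x_l)


def curve_shape(curve: TuningCurve) -> CurveShape:
    """Peak location/value, FWHM, monotonicity and support of one curve.

    Peak ties break toward the lowest intensity.  An all-zero curve yields
    peak value 0 with undefined FWHM and empty support.
    """
    grid, values = curve.grid, curve.values
    j = int(np.argmax(values))
    peak_value = float(values[j])
    pos = np.flatnonzero(values > 0)
    support = (float(grid[pos[0]]), float(grid[pos[-1]])) if pos.size else None
    return CurveShape(
        peak_intensity=float(grid[j]),
        peak_value=peak_value,
        fwhm=fwhm_of(grid, values),
        is_monotonic=bool(np.all(np.diff(values) >= -DOMINANCE_TOL)),
        support=support,
    )


@dataclass(frozen=True)
class NestednessReport:
    """Pointwise-dominance relations of a curve family.

    ``pair_dominance[(j, k)]`` is True when curve ``j`` dominates curve ``k``
    everywhere on the grid (within tolerance).  The family is fully nested
    iff every pair is comparable; pointwise dominance is transitive, so
    pairwise comparability already yields a total chain.
    """

    pair_dominance: dict[tuple[int, int], bool]
    fully_nested: bool


def nestedness(curves: Sequence[TuningCurve]) -> NestednessReport:
    if len(curves) < 2:
        raise ValueError("nestedness needs at least two curves")
    grid = curves[0].grid
    for c in curves[1:]:
        if c.grid.shape != grid.shape or not np.array_equal(c.grid, grid):
            raise ValueError("all curves must share a common grid")
    dom: dict[tuple[int, int], bool] = {}
    for j in range(len(curves)):
        for k in range(len(curves)):
            if j == k:
                continue
            dom[(j, k)] = bool(
                np.all(curves[j].values >= curves[k].values - DOMINANCE_TOL)
            )
    fully = all(
        dom[(j, k)] or dom[(k, j)]
        for j in range(len(curves))
        for k in range(j + 1, len(curves))
    )
    return NestednessReport(pair_dominance=dom, fully_nested=fully)


def specificity_score(battery: Sequence[TestResult]) -> float:
    """Worst-case mismatch between recall peak and trained intensity.

    ``max_j |peak_intensity_j - i_training_j|`` over the battery (log10
    units); lower is more intensity-specific.
    """
    battery = list(battery)
    if not battery:
        raise ValueError("empty battery")
    return float(max(abs(r.peak_intensity - r.i_training) for r in battery))
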