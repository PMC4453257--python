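"""Parameter-robustness sweep: where does intensity-specific learning survive?

Sweeps circuit parameters over a grid, runs the train/test battery at each
point and marks the point as passing when the specificity score (worst
mismatch between recall peak and trained intensity) stays below a threshold.
Grid points violating model constraints (b_inh >= b, inh_max <= 1, or a
non-positive homeostatic w_exc) are recorded as skipped, not failed.  The
model is deterministic, so identical sweep specs yield identical results.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .circuit import (
    MODE_EXCITATORY,
    MODE_INHIBITORY,
    CircuitSpec,
    LogisticUnit,
    default_grid,
)
from .homeostasis import WeightPositivityError, aligned_circuit
from .metrics import specificity_score
from .training import run_experiment_battery

__all__ = ["SWEEPABLE", "SweepSpec", "SweepResult", "run_sweep", "default_sweep"]

SWEEPABLE = ("b", "b_inh", "inh_max", "alpha", "alpha_tilde", "d", "a_step", "K")


@dataclass(frozen=True)
class SweepSpec:
    """Sweep design: parameter ranges, mode, battery and pass criterion.

    ``ranges`` maps parameter names (subset of :data:`SWEEPABLE`) to value
    sequences; unswept parameters keep the values of ``base``.  The total
    number of grid points must not exceed ``max_points``.
    """

    ranges: Mapping[str, Sequence[float]]
    mode: str = MODE_EXCITATORY
    base: CircuitSpec | None = None
    training_intensities: tuple[float, ...] = (-1.0, 0.0, 1.0)
    grid_min: float = -6.0
    grid_max: float = 6.0
    grid_step: float = 0.01
    threshold: float = 1.0
    max_points: int = 10_000

    def __post_init__(self) -> None:
        if not self.ranges:
            raise ValueError("empty sweep: at least one parameter range required")
        for name, vals in self.ranges.items():
            if name not in SWEEPABLE:
                raise ValueError(f"unknown sweep parameter {name!r}")
            if len(list(vals)) == 0:
                raise ValueError(f"empty range for parameter {name!r}")
        n = int(np.prod([len(list(v)) for v in self.ranges.values()]))
        if n > self.max_points:
            raise ValueError(f"sweep has {n} points, exceeding the cap {self.max_points}")


@dataclass(frozen=True)
class SweepResult:
    records: pd.DataFrame
    pass_fraction: float


def _circuit_for(base: CircuitSpec, mode: str, params: dict) -> CircuitSpec:
    K = int(params.get("K", base.n_units))
    a_step = float(params.get("a_step", np.diff(base.a_values).mean() if base.n_units > 1 else 1.0))
    b = float(params.get("b", base.exc_units[0].b))
    b_inh = float(params.get("b_inh", base.inh_unit.b))
    inh_max = float(params.get("inh_max", base.inh_unit.asymptote))
    a_vals = a_step * (np.arange(K) - (K - 1) / 2.0)
    return CircuitSpec(
        exc_units=tuple(LogisticUnit(a=float(a), b=b) for a in a_vals),
        inh_unit=LogisticUnit(a=base.inh_unit.a, b=b_inh, asymptote=inh_max),
        w_exc=(1.0,) * K,
        w_inh=(-1.0,) * K,
        homeostasis_mode=mode,
        alpha=float(params.get("alpha", base.alpha)),
        alpha_tilde=float(params.get("alpha_tilde", base.alpha_tilde)),
        d=float(params.get("d", base.d)),
        c0=base.c0,
        c1=base.c1,
    )


def run_sweep(spec: SweepSpec) -> SweepResult:
    """Evaluate the battery at every grid point of the sweep."""
    base = spec.base if spec.base is not None else aligned_circuit(mode=spec.mode)
    grid = default_grid(spec.grid_min, spec.grid_max, spec.grid_step)
    names = sorted(spec.ranges)
    records = []
    for combo in itertools.product(*(spec.ranges[n] for n in names)):
        params = dict(zip(names, combo))
        row = dict(params)
        row["mode"] = spec.mode
        try:
            circuit = _circuit_for(base, spec.mode, params)
            battery = run_experiment_battery(
                circuit, spec.training_intensities, grid, shock=True
            )
            if any(r.peak_value <= 0 for r in battery):
                # silent output: no memory formed at some training intensity
                row.update(score=np.nan, status="fail", reason="silent output")
            else:
                score = specificity_score(battery)
                row.update(
                    score=score,
                    status="pass" if score <= spec.threshold else "fail",
                    reason="",
                )
        except (ValueError, WeightPositivityError) as err:
            row.update(score=np.nan, status="skipped", reason=str(err))
        records.append(row)
    frame = pd.DataFrame.from_records(records)
    evaluated = frame[frame["status"] != "skipped"]
    frac = float((evaluated["status"] == "pass").mean()) if len(evaluated) else 0.0
    return SweepResult(records=frame, pass_fraction=frac)


def default_sweep(mode: str = MODE_EXCITATORY) -> SweepSpec:
    """Coarse default design: -10%/0/+10% on the input-layer parameters."""
    base = aligned_circuit(mode=mode)
    b = base.exc_units[0].b
    b_inh = base.inh_unit.b
    inh_max = base.inh_unit.asymptote
    return SweepSpec(
        ranges={
            "b": tuple(b * f for f in (0.9, 1.0, 1.1)),
            "b_inh": tuple(b_inh * f for f in (0.9, 1.0, 1.1)),
            "inh_max": tuple(inh_max * f for f in (0.9, 1.0, 1.1)),
        },
        mode=mode,
        base=base,
    )
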