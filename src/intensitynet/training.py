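"""Associative odour-shock training and intensity-series testing.

The output neuron reads out the intermediate layer through plastic synapses,

    out(i) = sum_k w_training[k] * inter_k(i),

with all ``w_training`` zero before training.  A single paired trial changes
them by

    delta w_training[k] = Theta(shock) * inter_k(i_training),

where ``Theta`` is the Heaviside step (0 for x <= 0, 1 otherwise): the
reinforcement signal gates a weight increase proportional to the presynaptic
activity at the trained intensity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .circuit import CircuitSpec, TuningCurve, _check_grid, tuning_curves
from .homeostasis import resolve_weights

__all__ = ["TrainingState", "TestResult", "train", "test", "run_experiment_battery"]


@dataclass(frozen=True)
class TrainingState:
    """Learned output-synapse weights after one training trial."""

    w_training: np.ndarray
    i_training: float
    shock: bool

    def __post_init__(self) -> None:
        w = np.asarray(self.w_training, dtype=float)
        if w.ndim != 1:
            raise ValueError("w_training must be a 1-d vector")
        if np.any(w < 0):
            raise ValueError("training weights must be >= 0")
        object.__setattr__(self, "w_training", w)


@dataclass(frozen=True)
class TestResult:
    """Output-neuron activity over a test-intensity series."""

    grid: np.ndarray
    out: np.ndarray
    peak_intensity: float
    peak_value: float
    i_training: float


def _intermediate_matrix(spec: CircuitSpec, grid: np.ndarray) -> np.ndarray:
    w_exc, w_inh = resolve_weights(spec)
    from .circuit import exc_response, inh_response

    inh = inh_response(spec.inh_unit, grid)
    rows = [
        np.maximum(0.0, w_exc[k] * exc_response(unit, grid) + w_inh[k] * inh)
        for k, unit in enumerate(spec.exc_units)
    ]
    return np.vstack(rows)


def train(spec: CircuitSpec, i_training: float, shock: bool) -> TrainingState:
    """One associative trial starting from all-zero weights.

    With ``shock`` the weights become exactly ``inter_k(i_training)``;
    without it (unpaired control) they stay zero.
    """
    i_training = float(i_training)
    if not np.isfinite(i_training):
        raise ValueError("training intensity must be finite")
    gate = 1.0 if shock else 0.0
    inter = _intermediate_matrix(spec, np.array([i_training]))[:, 0]
    return TrainingState(w_training=gate * inter, i_training=i_training, shock=bool(shock))


def test(spec: CircuitSpec, state: TrainingState, grid) -> TestResult:
    """Present a test-intensity series and read out the output neuron.

    ``out(i)`` is linear in the training-weight vector.  The peak is located
    by grid argmax; ties break toward the lowest intensity.
    """
    grid = _check_grid(grid)
    if state.w_training.size != spec.n_units:
        raise ValueError(
            f"training state has {state.w_training.size} weights but the "
            f"circuit has {spec.n_units} intermediate neurons"
        )
    inter = _intermediate_matrix(spec, grid)
    out = state.w_training @ inter
    j = int(np.argmax(out))  # first (lowest-intensity) maximum
    return TestResult(
        grid=grid,
        out=out,
        peak_intensity=float(grid[j]),
        peak_value=float(out[j]),
        i_training=state.i_training,
    )


def run_experiment_battery(
    spec: CircuitSpec,
    training_intensities: Sequence[float],
    grid,
    shock: bool = True,
) -> list[TestResult]:
    """Independent train/test experiments, weights reset to zero between them."""
    training_intensities = list(training_intensities)
    if not training_intensities:
        raise ValueError("at least one training intensity is required")
    results = []
    for i_tr in training_intensities:
        state = train(spec, i_tr, shock=shock)
        results.append(test(spec, state, grid))
    return results
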