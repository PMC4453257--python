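"""Conditioned-avoidance-score (CAS) generalization analysis.

Behavioural intensity-generalization experiments train animals at one odour
intensity and test conditioned avoidance across a series of test intensities.
The pipeline here mirrors the standard analysis of such data:

1. normalize each odour's curve: test intensities are divided by the training
   intensity and median CASs by the value at matching train/test intensity,
   so every curve passes through (1, 1);
2. fit a Gaussian to the normalized curve (by default on log10 of the
   intensity ratio, since intensity is treated logarithmically throughout)
   and report its half width at half maximum, HWHM = sigma * sqrt(2 ln 2).

A synthetic-table generator with Gaussian ground truth plus noise makes the
pipeline testable without animal data; its default HWHM of 1.1 decades is a
plausible fly-scale width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "CAS_COLUMNS",
    "HWHM_PER_SIGMA",
    "CASTable",
    "GaussianFit",
    "SyntheticCASConfig",
    "NormalizationError",
    "GaussianFitError",
    "normalize_cas",
    "fit_gaussian",
    "generate_cas",
]

CAS_COLUMNS = ("odour", "i_training", "i_test", "median_cas", "n")

#: HWHM of a Gaussian in units of its sigma.
HWHM_PER_SIGMA = math.sqrt(2.0 * math.log(2.0))

#: A CAS table is a pandas DataFrame with the columns in CAS_COLUMNS:
#: one row per (odour, test intensity); intensities on the concentration
#: scale; median_cas dimensionless in [-100, 100]; n = sample count.
CASTable = pd.DataFrame


class NormalizationError(ValueError):
    """Missing or zero matched-intensity record during normalization."""


class GaussianFitError(RuntimeError):
    """Gaussian fit did not converge; carries the optimizer diagnostics."""


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CAS_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"CAS table lacks columns {missing}")
    if (table["n"] < 1).any():
        raise ValueError("sample counts n must be >= 1")
    return table


def normalize_cas(table: CASTable) -> CASTable:
    """Normalize a CAS table along both axes, odour by odour.

    Test intensities are divided by the training intensity and median CASs by
    the matched-intensity value, mapping the matched record to (1, 1).  The
    output uses the same schema (``i_training`` becomes 1.0), so normalizing
    twice is the identity.
    """
    _check_table(table)
    out_rows = []
    for odour, group in table.groupby("odour", sort=False):
        matched = group[np.isclose(group["i_test"], group["i_training"])]
        if len(matched) != 1:
            raise NormalizationError(
                f"odour {odour!r}: expected exactly one record with "
                f"i_test == i_training, found {len(matched)}"
            )
        y0 = float(matched["median_cas"].iloc[0])
        if y0 == 0.0:
            raise NormalizationError(f"odour {odour!r}: matched-intensity CAS is zero")
        g = group.copy()
        g["i_test"] = group["i_test"] / group["i_training"]
        g["median_cas"] = group["median_cas"] / y0
        g["i_training"] = 1.0
        out_rows.append(g)
    return pd.concat(out_rows, ignore_index=True)


@dataclass(frozen=True)
class GaussianFit:
    """Least-squares Gaussian ``A exp(-(x - mu)^2 / (2 sigma^2))``."""

    amplitude: float
    mean: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")

    @property
    def hwhm(self) -> float:
        return self.sigma * HWHM_PER_SIGMA


def _gauss(x, A, mu, sigma):
    return A * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def fit_gaussian(table: CASTable, log_axis: bool = True) -> GaussianFit:
    """Fit a Gaussian to a normalized CAS table.

    Parameters
    ----------
    table : CASTable
        Output of :func:`normalize_cas` (intensity ratios on the x axis,
        CAS ratios on the y axis).
    log_axis : bool
        Fit on ``x = log10(i_test / i_training)`` (default) or on the raw
        ratio.  The reported HWHM is in the units of the chosen axis.
    """
    _check_table(table)
    x = np.asarray(table["i_test"] / table["i_training"], dtype=float)
    y = np.asarray(table["median_cas"], dtype=float)
    if log_axis:
        if np.any(x <= 0):
            raise ValueError("intensity ratios must be positive for the log axis")
        x = np.log10(x)
    if np.unique(x).size < 3:
        raise ValueError("at least 3 distinct test intensities are required")
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=[1.0, 0.0, 1.0],
            bounds=([0.0, -10.0, 1e-3], [10.0, 10.0, 10.0]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise GaussianFitError(f"Gaussian fit failed to converge: {err}") from err
    return GaussianFit(amplitude=float(popt[0]), mean=float(popt[1]), sigma=float(popt[2]))


@dataclass(frozen=True)
class SyntheticCASConfig:
    """Generator settings for synthetic CAS tables.

    ``noise_sd`` is expressed as a fraction of ``|peak_cas|``, i.e. it is the
    additive noise standard deviation on the peak-normalized scale.
    ``test_intensity_offsets`` are log10 offsets of the test intensities from
    the training intensity; the matched record (offset 0) is always included.
    """

    true_hwhm: float = 1.1
    peak_cas: float = -30.0
    noise_sd: float = 0.05
    test_intensity_offsets: tuple[float, ...] = (-2.0, -1.0, -0.5, 0.5, 1.0, 2.0)
    seed: int = 0
    i_training: float = 1e-3
    odour: str = "synthetic"
    n_per_group: int = 24

    def __post_init__(self) -> None:
        if not self.true_hwhm > 0:
            raise ValueError("true_hwhm must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.peak_cas == 0:
            raise ValueError("peak_cas must be nonzero")


def generate_cas(config: SyntheticCASConfig) -> CASTable:
    """Deterministic (seeded) CAS table with Gaussian intensity tuning.

    Median CAS at log10 offset ``x`` from the training intensity is
    ``peak_cas * exp(-x^2 / (2 sigma_true^2)) + noise`` with
    ``sigma_true = true_hwhm / sqrt(2 ln 2)`` and noise of standard deviation
    ``noise_sd * |peak_cas|``.
    """
    rng = np.random.default_rng(config.seed)
    offsets = np.concatenate([[0.0], np.asarray(config.test_intensity_offsets, float)])
    sigma_true = config.true_hwhm / HWHM_PER_SIGMA
    cas = config.peak_cas * np.exp(-(offsets**2) / (2.0 * sigma_true**2))
    cas = cas + rng.normal(0.0, config.noise_sd * abs(config.peak_cas), offsets.size)
    return pd.DataFrame(
        {
            "odour": config.odour,
            "i_training": config.i_training,
            "i_test": config.i_training * 10.0**offsets,
            "median_cas": cas,
            "n": config.n_per_group,
        }
    )
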