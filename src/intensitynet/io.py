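"""Run configuration, validation, logging and tabular/JSON writers."""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .circuit import (
    DEFAULT_GRID_MAX,
    DEFAULT_GRID_MIN,
    DEFAULT_GRID_STEP,
    HOMEOSTASIS_MODES,
    CircuitSpec,
    LogisticUnit,
    MODE_NONE,
)
from .homeostasis import aligned_circuit

__all__ = [
    "ConfigError",
    "ConfigSchemaError",
    "ConfigConstraintError",
    "RunConfig",
    "load_config",
    "save_config",
    "write_table",
    "read_table",
    "get_logger",
]

logger = logging.getLogger("intensitynet")


def get_logger(verbosity: int = 1) -> logging.Logger:
    """Package logger; verbosity 0 = warnings, 1 = info, 2+ = debug."""
    level = {0: logging.WARNING, 1: logging.INFO}.get(verbosity, logging.DEBUG)
    if not logger.handlers:
        handler = logging.StreamHandler()
        handler.setFormatter(logging.Formatter("%(name)s: %(message)s"))
        logger.addHandler(handler)
    logger.setLevel(level)
    return logger


class ConfigError(Exception):
    """Base class for configuration problems."""


class ConfigSchemaError(ConfigError):
    """Unknown keys or wrong value types in a config file."""


class ConfigConstraintError(ConfigError):
    """A model constraint is violated by the configured values."""


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration with defaults filled.

    Circuit parameters left at ``None`` are completed by the aligned default
    construction (see :func:`intensitynet.homeostasis.aligned_circuit`);
    setting all of ``alpha, alpha_tilde, d, c0, c1`` overrides it.
    """

    mode: str = MODE_NONE
    K: int = 3
    a_step: float = 1.0
    b: float = 1.0
    a_inh: float = 2.0
    b_inh: float = 0.6
    inh_max: float = 2.5
    s_width: float = 1.5
    alpha: float | None = None
    alpha_tilde: float | None = None
    d: float | None = None
    c0: float | None = None
    c1: float | None = None
    grid_min: float = DEFAULT_GRID_MIN
    grid_max: float = DEFAULT_GRID_MAX
    grid_step: float = DEFAULT_GRID_STEP
    training_intensities: tuple[float, ...] = (-1.0, 0.0, 1.0)
    out_dir: str = "."
    verbosity: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in HOMEOSTASIS_MODES:
            raise ConfigConstraintError(
                f"mode must be one of {HOMEOSTASIS_MODES}, got {self.mode!r}"
            )
        if self.K < 1:
            raise ConfigConstraintError("K >= 1 is required")
        if not self.b > 0:
            raise ConfigConstraintError("b > 0 is required")
        if not self.b_inh < self.b:
            raise ConfigConstraintError("b_inh < b is required")
        if not self.inh_max > 1:
            raise ConfigConstraintError("inh_max > 1 is required")
        if not self.grid_step > 0:
            raise ConfigConstraintError("grid_step > 0 is required")
        if not self.grid_min < self.grid_max:
            raise ConfigConstraintError("grid_min < grid_max is required")
        overrides = (self.alpha, self.alpha_tilde, self.d, self.c0, self.c1)
        if any(v is not None for v in overrides) and any(v is None for v in overrides):
            raise ConfigConstraintError(
                "alpha, alpha_tilde, d, c0 and c1 must be given together "
                "(or all left unset to use the aligned defaults)"
            )
        if self.c0 is not None and not self.c0 < self.c1:
            raise ConfigConstraintError("c0 < c1 is required")

    def to_circuit(self) -> CircuitSpec:
        if self.alpha is None:
            return aligned_circuit(
                mode=self.mode,
                K=self.K,
                a_step=self.a_step,
                b=self.b,
                a_inh=self.a_inh,
                b_inh=self.b_inh,
                inh_max=self.inh_max,
                s_width=self.s_width,
            )
        a_vals = self.a_step * (np.arange(self.K) - (self.K - 1) / 2.0)
        return CircuitSpec(
            exc_units=tuple(LogisticUnit(a=float(a), b=self.b) for a in a_vals),
            inh_unit=LogisticUnit(a=self.a_inh, b=self.b_inh, asymptote=self.inh_max),
            w_exc=(1.0,) * self.K,
            w_inh=(-1.0,) * self.K,
            homeostasis_mode=self.mode,
            alpha=self.alpha,
            alpha_tilde=self.alpha_tilde,
            d=self.d,
            c0=self.c0,
            c1=self.c1,
        )

    def grid(self) -> np.ndarray:
        n = int(round((self.grid_max - self.grid_min) / self.grid_step))
        return self.grid_min + self.grid_step * np.arange(n + 1)

    def provenance(self) -> dict[str, Any]:
        """All resolved values, suitable for output headers."""
        prov = dataclasses.asdict(self)
        prov["training_intensities"] = list(self.training_intensities)
        return prov


_FIELD_TYPES = {f.name: f for f in dataclasses.fields(RunConfig)}


def load_config(path) -> RunConfig:
    """Load and validate a YAML key-value config file.

    Raises ``FileNotFoundError`` for a missing file, ``ConfigSchemaError``
    for unknown keys or malformed values and ``ConfigConstraintError`` when
    a model constraint (e.g. ``inh_max > 1``) is violated.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as err:
        raise ConfigSchemaError(f"config is not valid YAML: {err}") from err
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigSchemaError("config must be a mapping of key: value pairs")
    unknown = set(raw) - set(_FIELD_TYPES)
    if unknown:
        raise ConfigSchemaError(f"unknown config keys: {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    for key, value in raw.items():
        if key == "training_intensities":
            try:
                kwargs[key] = tuple(float(v) for v in value)
            except (TypeError, ValueError) as err:
                raise ConfigSchemaError(
                    f"training_intensities must be a list of numbers: {err}"
                ) from err
        elif key in ("mode", "out_dir"):
            if not isinstance(value, str):
                raise ConfigSchemaError(f"{key} must be a string")
            kwargs[key] = value
        elif key in ("K", "verbosity", "seed"):
            if not isinstance(value, int):
                raise ConfigSchemaError(f"{key} must be an integer")
            kwargs[key] = value
        else:
            if value is not None and not isinstance(value, (int, float)):
                raise ConfigSchemaError(f"{key} must be a number")
            kwargs[key] = None if value is None else float(value)
    cfg = RunConfig(**kwargs)
    get_logger(cfg.verbosity).info("loaded config %s: %s", path, cfg.provenance())
    return cfg


def save_config(cfg: RunConfig, path) -> None:
    """Write the fully resolved configuration; reloading reproduces it."""
    Path(path).write_text(yaml.safe_dump(cfg.provenance(), sort_keys=True))


def _fmt(value) -> str:
    if isinstance(value, (float, np.floating)):
        return repr(float(value))  # repr round-trips float64 exactly
    return str(value)


def write_table(records, path, provenance: Mapping[str, Any] | None = None) -> None:
    """Write records as TSV with provenance comment lines.

    ``records`` may be a DataFrame or a sequence of homogeneous mappings.
    Floats are written with ``repr`` so a read-back is bitwise identical.
    """
    if isinstance(records, pd.DataFrame):
        columns = list(records.columns)
        rows = records.itertuples(index=False)
    else:
        records = list(records)
        columns = list(records[0].keys()) if records else []
        rows = (tuple(r[c] for c in columns) for r in records)
    lines = []
    for key, value in (provenance or {}).items():
        lines.append(f"# {key} = {value}")
    lines.append("\t".join(columns))
    for row in rows:
        lines.append("\t".join(_fmt(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_table(path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (comments stripped)."""
    return pd.read_csv(path, sep="\t", comment="#")
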