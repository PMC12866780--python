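"""File formats, unit handling, shared domain types, configuration and logging.

All quantities are held in SI units internally (s, m, N, Pa).  Tabular data
travels as RFC-4180 CSV whose column names carry an explicit unit suffix
(``time_s``, ``force_mN``, ``deflection_um`` ...); columns with no declared
unit are rejected rather than guessed, because silent unit errors dominate
this domain.  Scalar metadata (specimen id, undeformed geometry) rides in
leading ``# key: value`` comment lines of the same file.
"""

from __future__ import annotations

import io as _stdio
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml


# --------------------------------------------------------------------------
# errors
# --------------------------------------------------------------------------

class FormatError(ValueError):
    """Malformed or physically inconsistent input data."""


class ConfigurationError(ValueError):
    """Invalid configuration (units, bands, protocol ...)."""


class DomainError(ValueError):
    """A formula was evaluated outside its domain of validity."""


class DegenerateDesignError(ValueError):
    """The data cannot identify the requested parameter (e.g. all-zero design)."""


class FitError(RuntimeError):
    """A nonlinear fit failed to converge from every starting point."""


# --------------------------------------------------------------------------
# logging
# --------------------------------------------------------------------------

def get_logger(name: str = "histomech") -> logging.Logger:
    return logging.getLogger(name)


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper(), logging.INFO),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


log = get_logger(__name__)


# --------------------------------------------------------------------------
# units
# --------------------------------------------------------------------------

#: multiplicative factor that converts a declared unit into its SI base unit
UNIT_FACTORS: dict[str, float] = {
    "s": 1.0, "ms": 1e-3, "min": 60.0,
    "m": 1.0, "mm": 1e-3, "um": 1e-6,
    "N": 1.0, "mN": 1e-3, "uN": 1e-6,
    "Pa": 1.0, "kPa": 1e3,
}

#: which units are dimensionally admissible for each recognised field
FIELD_UNITS: dict[str, tuple[str, ...]] = {
    "time": ("s", "ms", "min"),
    "deflection": ("m", "mm", "um"),
    "force": ("N", "mN", "uN"),
    "height": ("m", "mm", "um"),
    "radius": ("m", "mm", "um"),
    "stress": ("Pa", "kPa"),
}

#: canonical SI suffix used when writing
SI_SUFFIX: dict[str, str] = {
    "time": "s", "deflection": "m", "force": "N",
    "height": "m", "radius": "m", "stress": "Pa",
}


def parse_column_unit(column: str, units_config: Mapping[str, str] | None = None
                      ) -> tuple[str, float]:
    """Resolve a CSV column name to ``(field, si_factor)``.

    The unit comes from the ``<field>_<unit>`` suffix, or from
    ``units_config[column]`` / ``units_config[field]`` for suffix-less
    columns.  Undeclared units raise :class:`FormatError`.
    """
    units_config = units_config or {}
    base, _, suffix = column.rpartition("_")
    if base in FIELD_UNITS and suffix in UNIT_FACTORS:
        if suffix not in FIELD_UNITS[base]:
            raise FormatError(
                f"column {column!r}: unit {suffix!r} is not valid for {base!r}")
        return base, UNIT_FACTORS[suffix]
    name = column.strip()
    if name in FIELD_UNITS:
        unit = units_config.get(name)
        if unit is None:
            raise FormatError(
                f"column {name!r} declares no unit suffix and none is configured")
        if unit not in FIELD_UNITS[name]:
            raise FormatError(f"unit {unit!r} is not valid for {name!r}")
        return name, UNIT_FACTORS[unit]
    raise FormatError(f"unrecognised column {column!r}")


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class MechanicalTimeSeries:
    """One specimen test: time-stamped force/deflection plus optional geometry.

    ``height``/``radius`` are per-frame current geometry (side-camera frames
    in unconfined compression); ``H0``/``R0`` are the undeformed height and
    radius.  Compressive force is stored as a positive load magnitude; the
    sign convention (compressive Cauchy stress negative) is applied where
    stress is computed.
    """

    time: np.ndarray
    deflection: np.ndarray | None = None
    force: np.ndarray | None = None
    height: np.ndarray | None = None
    radius: np.ndarray | None = None
    specimen_id: str = "specimen"
    H0: float | None = None
    R0: float | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        for name in ("deflection", "force", "height", "radius"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.time.shape:
                    raise FormatError(f"{name} length does not match time")
                setattr(self, name, v)
        if self.time.ndim != 1 or len(self.time) == 0:
            raise FormatError("time must be a non-empty 1-D array")
        if not np.all(np.diff(self.time) > 0):
            raise FormatError("time must be strictly increasing")
        if self.deflection is None and self.force is None:
            raise FormatError("at least one of deflection/force is required")
        for name in ("H0", "R0"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise FormatError(f"{name} must be positive")
        for name in ("height", "radius"):
            v = getattr(self, name)
            if v is not None and not np.all(v > 0):
                raise FormatError(f"all {name} frames must be positive")

    @property
    def n_samples(self) -> int:
        return len(self.time)


@dataclass
class CantileverSpec:
    """End-loaded Euler-Bernoulli force-sensing microbeam.

    Default beam modulus 411 GPa; typical lengths 57-59 mm; the diameter sets
    force resolution (small for indentation, large for compression).  When the
    instrument's calibrated stiffness (N/m) is known it may be supplied
    directly and bypasses the beam formula.
    """

    beam_modulus: float = 411e9
    beam_length: float = 58e-3
    beam_diameter: float = 0.3048e-3
    stiffness: float | None = None  # N/m override

    def __post_init__(self) -> None:
        for name in ("beam_modulus", "beam_length", "beam_diameter"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be positive")
        if self.stiffness is not None and not self.stiffness > 0:
            raise ConfigurationError("stiffness must be positive")

    @property
    def second_moment(self) -> float:
        """Area moment of inertia of the circular cross-section, pi*Phi^4/64."""
        return np.pi * self.beam_diameter ** 4 / 64.0

    @property
    def effective_stiffness(self) -> float:
        if self.stiffness is not None:
            return self.stiffness
        return 3.0 * self.beam_modulus * self.second_moment / self.beam_length ** 3


def beam_force(deflection, spec: CantileverSpec):
    """Force (N) exerted on an end-loaded cantilever deflected by ``deflection`` (m).

    F = 3 E_b I delta / L^3 with I = pi Phi^4 / 64, or ``k * delta`` when a
    calibrated stiffness is supplied.  Linear in deflection.
    """
    return spec.effective_stiffness * np.asarray(deflection, dtype=float)


@dataclass
class StepProtocol:
    """Stepped loading protocol: ``n_steps`` increments of ``step_magnitude``
    (fraction of initial height) each followed by a ``hold_duration`` (s) hold.

    ``ramp_rate`` (fraction/s) renders finite-speed ramps; ``None`` means
    instantaneous steps.
    """

    n_steps: int
    step_magnitude: float
    hold_duration: float
    ramp_rate: float | None = None

    def __post_init__(self) -> None:
        if self.n_steps < 1:
            raise ConfigurationError("n_steps must be >= 1")
        if not 0 < self.step_magnitude < 1:
            raise ConfigurationError("step_magnitude must be in (0, 1)")
        if not self.hold_duration > 0:
            raise ConfigurationError("hold_duration must be positive")
        if self.ramp_rate is not None and not self.ramp_rate > 0:
            raise ConfigurationError("ramp_rate must be positive")

    @property
    def total_deformation(self) -> float:
        """Cumulative imposed deformation as a fraction of initial height."""
        return self.n_steps * self.step_magnitude

    @property
    def ramp_duration(self) -> float:
        if self.ramp_rate is None:
            return 0.0
        return self.step_magnitude / self.ramp_rate

    def hold_windows(self) -> list[tuple[float, float]]:
        """``[(start, end)]`` of each hold phase, 0-indexed by step."""
        r, h = self.ramp_duration, self.hold_duration
        return [((i + 1) * r + i * h, (i + 1) * r + (i + 1) * h)
                for i in range(self.n_steps)]

    @property
    def span(self) -> float:
        return self.n_steps * (self.ramp_duration + self.hold_duration)

    def cumulative_strain(self, step: int) -> float:
        """Imposed deformation fraction after ``step`` (1-based) steps."""
        return step * self.step_magnitude


#: printed local-indentation protocol: 5 x 1% steps, 1-min holds
INDENTATION_PROTOCOL = StepProtocol(n_steps=5, step_magnitude=0.01,
                                    hold_duration=60.0)
#: printed unconfined-compression protocol: 8 x 2.5% steps (20% total), 2-min holds
COMPRESSION_PROTOCOL = StepProtocol(n_steps=8, step_magnitude=0.025,
                                    hold_duration=120.0)


# --------------------------------------------------------------------------
# CSV round trip
# --------------------------------------------------------------------------

_META_SCALARS = ("H0", "R0")


def read_mech_csv(path, units_config: Mapping[str, str] | None = None
                  ) -> MechanicalTimeSeries:
    """Read a mechanical time series CSV into SI units.

    Leading ``# key: value`` lines carry ``specimen_id`` and the undeformed
    geometry as e.g. ``H0_mm``.  Column units come from name suffixes or
    from ``units_config``.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, newline="") as fh:
        for line in fh:
            if line.startswith("#"):
                key, _, value = line[1:].partition(":")
                meta[key.strip()] = value.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: no tabular content")
    df = pd.read_csv(_stdio.StringIO("".join(body_lines)))

    columns: dict[str, np.ndarray] = {}
    for col in df.columns:
        fld, factor = parse_column_unit(col, units_config)
        if fld in columns:
            raise FormatError(f"duplicate column for field {fld!r}")
        columns[fld] = df[col].to_numpy(dtype=float) * factor
    if "time" not in columns:
        raise FormatError("a time column is required")

    scalars: dict[str, float | None] = {k: None for k in _META_SCALARS}
    for key, value in meta.items():
        if key == "specimen_id":
            continue
        base, _, suffix = key.rpartition("_")
        if base in _META_SCALARS:
            if suffix not in FIELD_UNITS["height"]:
                raise FormatError(f"metadata {key!r}: unrecognised unit")
            scalars[base] = float(value) * UNIT_FACTORS[suffix]
    return MechanicalTimeSeries(
        time=columns["time"],
        deflection=columns.get("deflection"),
        force=columns.get("force"),
        height=columns.get("height"),
        radius=columns.get("radius"),
        specimen_id=meta.get("specimen_id", path.stem),
        H0=scalars["H0"],
        R0=scalars["R0"],
    )


def write_mech_csv(series: MechanicalTimeSeries, path) -> None:
    """Write a series as CSV in SI units with unit-suffixed column names."""
    path = Path(path)
    cols: dict[str, np.ndarray] = {"time_s": series.time}
    for fld in ("deflection", "force", "height", "radius"):
        v = getattr(series, fld)
        if v is not None:
            cols[f"{fld}_{SI_SUFFIX[fld]}"] = v
    with open(path, "w", newline="") as fh:
        fh.write(f"# specimen_id: {series.specimen_id}\n")
        if series.H0 is not None:
            fh.write(f"# H0_m: {series.H0:.17g}\n")
        if series.R0 is not None:
            fh.write(f"# R0_m: {series.R0:.17g}\n")
        pd.DataFrame(cols).to_csv(fh, index=False, float_format="%.17g")


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def load_config(path) -> dict:
    """Load a YAML configuration file into a plain dict (empty file -> {})."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if cfg is None:
        return {}
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a YAML mapping")
    return cfg


def protocol_from_config(cfg: Mapping) -> StepProtocol:
    return StepProtocol(
        n_steps=int(cfg["n_steps"]),
        step_magnitude=float(cfg["step_magnitude"]),
        hold_duration=float(cfg["hold_duration"]),
        ramp_rate=(float(cfg["ramp_rate"]) if cfg.get("ramp_rate") else None),
    )
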