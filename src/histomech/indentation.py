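"""Local Young's modulus from stepped flat-punch indentation (Sneddon).

For a rigid flat-ended cylindrical punch of radius R on an elastic
half-space, the force-indentation relation is linear:

    F = E * (2 R / (1 - nu^2)) * delta

The steady-state force of each hold phase is plotted against the cumulative
imposed indentation delta and the unknown Young's modulus E follows from the
slope of the through-origin least-squares line (the relation has no offset
term).  Defaults match a 38.1 um punch and incompressibility (nu = 0.5).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io import (DegenerateDesignError, FormatError, MechanicalTimeSeries,
                 StepProtocol, get_logger)

log = get_logger(__name__)

DEFAULT_PUNCH_RADIUS = 38.1e-6  # m
DEFAULT_POISSON = 0.5
DEFAULT_WINDOW_FRACTION = 0.2
#: beyond this imposed deformation the small-strain assumption degrades
SMALL_STRAIN_LIMIT = 0.05


@dataclass
class IndentationStep:
    """Cumulative indentation (m) and steady-state hold force (N)."""

    delta: float
    steady_force: float

    def __post_init__(self) -> None:
        if self.delta < 0:
            raise FormatError("indentation must be non-negative")


@dataclass
class SneddonFit:
    E_local: float
    R: float
    nu: float
    residual: float  # RMS force residual, N
    n_steps: int
    clamped: bool = False  #: negative fitted slope clamped to E = 0


def extract_steady_states(series: MechanicalTimeSeries, protocol: StepProtocol,
                          window_fraction: float = DEFAULT_WINDOW_FRACTION
                          ) -> list[IndentationStep]:
    """One (delta, steady force) pair per hold phase.

    Steady force is the mean force over the final ``window_fraction`` of each
    hold (tail averaging suppresses residual relaxation); delta is the
    cumulative imposed indentation ``i * step_magnitude * H0``.
    """
    if not 0 < window_fraction <= 1:
        raise FormatError("window_fraction must be in (0, 1]")
    if series.force is None:
        raise FormatError("a force channel is required")
    if series.H0 is None:
        raise FormatError("initial height H0 is required to form indentations")
    if protocol.total_deformation > SMALL_STRAIN_LIMIT + 1e-12:
        warnings.warn(
            f"protocol imposes {protocol.total_deformation:.1%} deformation, "
            f"outside the small-deformation regime (<= {SMALL_STRAIN_LIMIT:.0%})",
            stacklevel=2)

    steps, missing = [], []
    for i, (lo, hi) in enumerate(protocol.hold_windows(), start=1):
        # half-open window: a sample at exactly the boundary belongs to the
        # next step (it already carries the next step's load)
        last = hi >= protocol.span - 1e-12
        win = (series.time >= hi - window_fraction * protocol.hold_duration) \
            & ((series.time <= hi) if last else (series.time < hi))
        if not np.any(win):
            missing.append(i)
            continue
        steps.append(IndentationStep(
            delta=protocol.cumulative_strain(i) * series.H0,
            steady_force=float(np.mean(series.force[win]))))
    if missing:
        raise FormatError(f"series does not cover holds {missing}")
    return steps


def fit_sneddon(steps, R: float = DEFAULT_PUNCH_RADIUS,
                nu: float = DEFAULT_POISSON) -> SneddonFit:
    """Least-squares Sneddon fit through the origin of F vs delta.

    E = slope * (1 - nu^2) / (2 R).  A negative fitted slope is clamped to
    E = 0 with a warning and the ``clamped`` flag set.
    """
    if not (0 < nu < 1):
        raise FormatError("nu must be in (0, 1)")
    if not R > 0:
        raise FormatError("punch radius must be positive")
    delta = np.array([s.delta for s in steps], dtype=float)
    force = np.array([s.steady_force for s in steps], dtype=float)
    if len(delta) < 2 or len(np.unique(delta)) < 2:
        raise DegenerateDesignError("need >= 2 steps with distinct indentations")
    if not np.any(delta > 0):
        raise DegenerateDesignError("all indentations are zero")

    slope = float(np.sum(force * delta) / np.sum(delta ** 2))
    clamped = False
    if slope < 0:
        warnings.warn("negative fitted slope; clamping E_local to 0", stacklevel=2)
        slope, clamped = 0.0, True
    residual = float(np.sqrt(np.mean((force - slope * delta) ** 2)))
    return SneddonFit(E_local=slope * (1.0 - nu ** 2) / (2.0 * R), R=R, nu=nu,
                      residual=residual, n_steps=len(delta), clamped=clamped)


def fit_indentation_series(series: MechanicalTimeSeries, protocol: StepProtocol,
                           R: float = DEFAULT_PUNCH_RADIUS,
                           nu: float = DEFAULT_POISSON,
                           window_fraction: float = DEFAULT_WINDOW_FRACTION
                           ) -> SneddonFit:
    """Convenience pipeline: steady states -> Sneddon fit."""
    return fit_sneddon(extract_steady_states(series, protocol, window_fraction),
                       R=R, nu=nu)
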