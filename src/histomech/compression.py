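"""Unconfined-compression analysis: strains, Cauchy stress, Poisson ratio and
the neo-Hookean equilibrium fit.

Strains follow the engineering definitions on measured geometry,
eps_rr = r_c/R0 - 1 and eps_zz = h_c/H0 - 1 (negative in compression), with
stretches lambda = 1 + eps.  Axial Cauchy stress is sigma = F / (pi r_c^2),
negative for compressive load.  The Poisson ratio is the negative slope of
the through-origin line of eps_rr on eps_zz.  Equilibrium stresses are fitted
with the one-parameter neo-Hookean strain energy W = (c/2)(I_C - 3); under
unconfined compression with traction-free lateral faces

    sigma_zz = c * (lambda_z^2 - lambda_r^2)

using the measured lateral stretch, or lambda_r = lambda_z^(-1/2) when the
radius is unmeasured (incompressible kinematics), which gives the classical
sigma = c (lambda^2 - 1/lambda).  The global Young's modulus for comparison
with indentation is E = 2 c (1 + nu), i.e. E = 3c in the incompressible limit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (DegenerateDesignError, FormatError, MechanicalTimeSeries,
                 StepProtocol, get_logger)

log = get_logger(__name__)


@dataclass
class StrainState:
    eps_rr: float
    eps_zz: float

    @property
    def lambda_z(self) -> float:
        return 1.0 + self.eps_zz

    @property
    def lambda_r(self) -> float:
        return 1.0 + self.eps_rr

    @property
    def first_invariant(self) -> float:
        """I_C = lambda_z^2 + 2 lambda_r^2 (first Cauchy-Green invariant)."""
        return self.lambda_z ** 2 + 2.0 * self.lambda_r ** 2

    def __post_init__(self) -> None:
        if not (self.lambda_z > 0 and self.lambda_r > 0):
            raise FormatError("stretches must be positive")


@dataclass
class EquilibriumPoint:
    state: StrainState
    sigma: float  # Pa, negative in compression


@dataclass
class PoissonFit:
    nu: float
    slope: float
    clamped: bool = False


@dataclass
class NeoHookeanFit:
    c: float
    nu: float
    residual: float  # RMS stress residual, Pa
    clamped: bool = False
    used_measured_radial: bool = True

    @property
    def E_global(self) -> float:
        return 2.0 * self.c * (1.0 + self.nu)


def compute_strain_stress(series: MechanicalTimeSeries) -> pd.DataFrame:
    """Per-frame strain state and axial Cauchy stress.

    Requires geometry frames and force; compressive load (positive force
    magnitude) maps to negative sigma.
    """
    for fld in ("height", "radius", "force"):
        if getattr(series, fld) is None:
            raise FormatError(f"{fld} frames are required")
    if series.H0 is None or series.R0 is None:
        raise FormatError("H0 and R0 are required")
    if np.any(series.radius <= 0):
        raise FormatError("current radius must be positive")
    eps_rr = series.radius / series.R0 - 1.0
    eps_zz = series.height / series.H0 - 1.0
    sigma = -np.abs(series.force) / (np.pi * series.radius ** 2)
    sigma = np.where(series.force == 0, 0.0, sigma)
    return pd.DataFrame({
        "time_s": series.time,
        "eps_rr": eps_rr,
        "eps_zz": eps_zz,
        "lambda_z": 1.0 + eps_zz,
        "lambda_r": 1.0 + eps_rr,
        "I_C": (1.0 + eps_zz) ** 2 + 2.0 * (1.0 + eps_rr) ** 2,
        "sigma": sigma,
    })


def fit_poisson(states) -> PoissonFit:
    """nu = -slope of the through-origin least-squares line of eps_rr on eps_zz,
    clamped to (0, 0.5] with a flag when the estimate falls outside."""
    eps_rr = np.array([s.eps_rr for s in states], dtype=float)
    eps_zz = np.array([s.eps_zz for s in states], dtype=float)
    if len(eps_zz) < 2 or not np.any(eps_zz != 0):
        raise DegenerateDesignError("need >= 2 states with non-zero axial strain")
    slope = float(np.sum(eps_rr * eps_zz) / np.sum(eps_zz ** 2))
    nu = -slope
    clamped = False
    if nu <= 0:
        nu, clamped = max(nu, 0.0), True
        log.warning("Poisson estimate %.4g outside (0, 0.5]; clamped to %.2g",
                    -slope, nu)
    elif nu > 0.5:
        nu, clamped = 0.5, True
        log.warning("Poisson estimate %.4g > 0.5; clamped", -slope)
    return PoissonFit(nu=nu, slope=slope, clamped=clamped)


def fit_neo_hookean(points, nu: float = 0.5,
                    use_measured_radial: bool = True) -> NeoHookeanFit:
    """Least-squares neo-Hookean parameter c from equilibrium points.

    The model sigma = c * g(lambda) is linear in c, so the minimiser is the
    closed-form projection c = sum(sigma g) / sum(g^2) with
    g = lambda_z^2 - lambda_r^2 (measured radial stretch) or
    g = lambda_z^2 - 1/lambda_z (incompressible kinematics).  c is clamped
    at 0 with a flag if the projection is negative.
    """
    points = list(points)
    if len(points) < 2:
        raise DegenerateDesignError("need >= 2 equilibrium points")
    lz = np.array([p.state.lambda_z for p in points])
    if not np.any(lz != 1.0):
        raise DegenerateDesignError("all points are at the reference state")
    sigma = np.array([p.sigma for p in points], dtype=float)
    if use_measured_radial:
        lr = np.array([p.state.lambda_r for p in points])
        g = lz ** 2 - lr ** 2
    else:
        g = lz ** 2 - 1.0 / lz
    denom = float(np.sum(g ** 2))
    if denom == 0:
        raise DegenerateDesignError("degenerate stretch design (all g = 0)")
    c = float(np.sum(sigma * g) / denom)
    clamped = False
    if c < 0:
        log.warning("negative neo-Hookean stiffness %.4g; clamped to 0", c)
        c, clamped = 0.0, True
    residual = float(np.sqrt(np.mean((sigma - c * g) ** 2)))
    return NeoHookeanFit(c=c, nu=nu, residual=residual, clamped=clamped,
                         used_measured_radial=use_measured_radial)


def neo_hookean_stress(lambda_z, c: float, lambda_r=None):
    """Model axial Cauchy stress; incompressible kinematics when lambda_r is None."""
    lz = np.asarray(lambda_z, dtype=float)
    if lambda_r is None:
        return c * (lz ** 2 - 1.0 / lz)
    lr = np.asarray(lambda_r, dtype=float)
    return c * (lz ** 2 - lr ** 2)


def extract_equilibrium_points(frames: pd.DataFrame, protocol: StepProtocol,
                               window_fraction: float = 0.1
                               ) -> list[EquilibriumPoint]:
    """End-of-hold equilibrium points from a compute_strain_stress frame table."""
    t = frames["time_s"].to_numpy()
    points = []
    for i, (lo, hi) in enumerate(protocol.hold_windows(), start=1):
        # half-open: a sample at exactly the boundary belongs to the next step
        last = hi >= protocol.span - 1e-12
        win = (t >= hi - window_fraction * protocol.hold_duration) \
            & ((t <= hi) if last else (t < hi))
        if not np.any(win):
            raise FormatError(f"no samples in the tail of hold {i}")
        sub = frames.loc[win]
        points.append(EquilibriumPoint(
            state=StrainState(eps_rr=float(sub["eps_rr"].mean()),
                              eps_zz=float(sub["eps_zz"].mean())),
            sigma=float(sub["sigma"].mean())))
    return points


def fit_compression_series(series: MechanicalTimeSeries, protocol: StepProtocol,
                           use_measured_radial: bool = True,
                           window_fraction: float = 0.1) -> NeoHookeanFit:
    """Full pipeline: strains/stress -> Poisson fit -> neo-Hookean fit.

    The Poisson ratio is estimated from all geometry frames; the neo-Hookean
    stiffness from the end-of-hold equilibrium points.  Whether the measured
    lateral stretch enters the stress model is logged.
    """
    frames = compute_strain_stress(series)
    states = [StrainState(r, z) for r, z in
              zip(frames["eps_rr"], frames["eps_zz"]) if z != 0]
    pfit = fit_poisson(states)
    points = extract_equilibrium_points(frames, protocol, window_fraction)
    log.info("neo-Hookean stress model uses %s lateral stretch",
             "measured" if use_measured_radial else "incompressible")
    return fit_neo_hookean(points, nu=pfit.nu,
                           use_measured_radial=use_measured_radial)
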