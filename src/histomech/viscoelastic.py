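"""Modified nonlinear Maxwell-Wiechert model for stepped stress relaxation.

The model is a nonlinear (exponentially stiffening) equilibrium spring in
parallel with two Maxwell elements that share a spring stiffness ``c_m`` but
have distinct viscosities ``eta1 < eta2``.  For step ``i`` of a stepped
relaxation protocol the stress during the hold ``t_i <= t < t_(i+1)`` is

    sigma_i(t) = sigma_i0 + sum_j c_m * eps_s_ij(t)
    sigma_i0   = c_a * exp(c_b * eps_i) * eps_i
    eps_s_ij(t) = eta_j * eh_ij / (eta_j + eh_ij * c_m * (t - t_i))
    eh_ij       = eps_i - eps_(i-1) + eps_s_(i-1)j(t_i)

with eps_0 = 0 and eps_s_0j(t_1) = 0.  The spring-strain closed form is the
solution of the quadratic-decay law d(eps_s)/dt = -(c_m/eta_j) * eps_s**2, so
relaxation is hyperbolic (1/t), not exponential, and is only decaying for
positive spring strain.  The pipeline therefore works on compression strain
*magnitudes* (|eps_zz| >= 0); the Cauchy-stress sign is handled by callers.

Fitting follows a two-step procedure: the nonlinear-spring parameters
(c_a, c_b) are estimated first from the end-of-hold equilibrium stresses,
then the Maxwell parameters (c_m, eta1, eta2) from the transient response
with (c_a, c_b) frozen, using multi-start nonlinear least squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .io import (DomainError, FitError, FormatError, MechanicalTimeSeries,
                 StepProtocol, get_logger)

log = get_logger(__name__)

#: optimiser bounds, in the order (c_a, c_b, c_m, eta)
BOUNDS = {"c_a": (1.0, 1e6), "c_b": (-50.0, 50.0),
          "c_m": (1.0, 1e6), "eta": (1.0, 1e8)}
N_MULTISTART = 8
#: fraction of each hold averaged for the equilibrium (end-of-hold) stress
EQUILIBRIUM_WINDOW = 0.10


@dataclass
class ViscoParams:
    """The five material parameters.

    c_a (Pa): stiffness of the nonlinear equilibrium spring.
    c_b (-): strain-stiffening exponent coefficient.
    c_m (Pa): shared stiffness of the two Maxwell springs.
    eta1, eta2 (Pa*s): fast and slow dashpot viscosities (eta1 < eta2 is
    enforced by relabeling; the two elements are exchangeable).
    """

    c_a: float
    c_b: float
    c_m: float
    eta1: float
    eta2: float

    def __post_init__(self) -> None:
        for name in ("c_a", "eta1", "eta2"):
            if not getattr(self, name) > 0:
                raise FormatError(f"{name} must be positive")
        if self.c_m < 0:  # c_m = 0 is the purely elastic limit
            raise FormatError("c_m must be non-negative")
        if self.eta1 > self.eta2:
            self.eta1, self.eta2 = self.eta2, self.eta1

    @property
    def etas(self) -> tuple[float, float]:
        return (self.eta1, self.eta2)


def equilibrium_stress(eps, c_a: float, c_b: float):
    """Equilibrium (nonlinear spring) stress c_a * exp(c_b*eps) * eps."""
    eps = np.asarray(eps, dtype=float)
    return c_a * np.exp(c_b * eps) * eps


def spring_strain(t, t_i: float, eps_hat: float, c_m: float, eta: float):
    """Maxwell spring strain during a hold starting at ``t_i``.

    Closed form eta*eps_hat / (eta + eps_hat*c_m*(t - t_i)); solves
    d(eps_s)/dt = -(c_m/eta) eps_s^2 with eps_s(t_i) = eps_hat.  Raises
    :class:`DomainError` (reporting the critical time) if the denominator
    reaches zero within the requested times, which happens for negative
    eps_hat at t* = t_i + eta / (-eps_hat * c_m).
    """
    t = np.asarray(t, dtype=float)
    if not eta > 0:
        raise FormatError("eta must be positive")
    if np.any(t < t_i):
        raise DomainError("spring_strain requires t >= t_i")
    denom = eta + eps_hat * c_m * (t - t_i)
    if np.any(denom <= 0):
        t_crit = t_i + eta / (-eps_hat * c_m)
        raise DomainError(
            f"spring strain diverges at t = {t_crit:.6g} s (eps_hat = {eps_hat:.4g})")
    return eta * eps_hat / denom


def _hold_index(protocol: StepProtocol, times: np.ndarray) -> np.ndarray:
    """0-based step index for each sample time (instantaneous steps assumed)."""
    windows = protocol.hold_windows()
    if protocol.ramp_duration:
        raise FormatError("simulate_protocol assumes instantaneous steps")
    span = protocol.span
    if np.any(times < 0) or np.any(times > span):
        raise FormatError("sample times must lie within the protocol span")
    idx = np.minimum((times / protocol.hold_duration).astype(int),
                     protocol.n_steps - 1)
    return idx


def simulate_protocol(params: ViscoParams, protocol: StepProtocol,
                      sample_times) -> np.ndarray:
    """Stress magnitude trace sigma(t) for a stepped relaxation protocol.

    Steps are instantaneous; step ``i`` imposes cumulative strain magnitude
    ``i * step_magnitude``.  Returns sigma evaluated at ``sample_times``.
    """
    t = np.asarray(sample_times, dtype=float)
    idx = _hold_index(protocol, t)
    n = protocol.n_steps
    hold = protocol.hold_duration
    eps = protocol.step_magnitude * np.arange(n + 1)  # eps[0] = 0

    # per-step carry-over: effective strain of each Maxwell spring at step start
    eps_hat = np.zeros((n, 2))
    prev_end = np.zeros(2)  # eps_s_(i-1)j evaluated at t_i
    for i in range(n):
        eps_hat[i] = (eps[i + 1] - eps[i]) + prev_end
        t_start, t_end = i * hold, (i + 1) * hold
        prev_end = np.array([
            spring_strain(t_end, t_start, eps_hat[i, j], params.c_m,
                          params.etas[j])
            for j in range(2)])

    sigma = np.empty_like(t)
    for i in range(n):
        sel = idx == i
        if not np.any(sel):
            continue
        s = equilibrium_stress(eps[i + 1], params.c_a, params.c_b)
        for j in range(2):
            s = s + params.c_m * spring_strain(
                t[sel], i * hold, eps_hat[i, j], params.c_m, params.etas[j])
        sigma[sel] = s
    return sigma


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class ViscoFit:
    params: ViscoParams
    rms_residual: float
    converged: bool
    equilibrium_rms: float
    slow_element_flag: bool = False  #: eta2/c_m exceeds 10x the hold duration
    n_starts: int = N_MULTISTART
    start_costs: list = field(default_factory=list)


def _hold_samples(protocol: StepProtocol, times: np.ndarray) -> np.ndarray:
    """Boolean mask of samples inside hold phases (ramps excluded)."""
    mask = np.zeros(len(times), dtype=bool)
    for lo, hi in protocol.hold_windows():
        mask |= (times >= lo) & (times <= hi)
    return mask


def extract_equilibrium(times: np.ndarray, stress: np.ndarray,
                        protocol: StepProtocol,
                        window_fraction: float = EQUILIBRIUM_WINDOW
                        ) -> tuple[np.ndarray, np.ndarray]:
    """(strain magnitudes, end-of-hold mean stresses), one per protocol step."""
    eps = np.empty(protocol.n_steps)
    sig = np.empty(protocol.n_steps)
    for i, (lo, hi) in enumerate(protocol.hold_windows()):
        # half-open: boundary samples belong to the next step
        last = hi >= protocol.span - 1e-12
        win = (times >= hi - window_fraction * protocol.hold_duration) \
            & ((times <= hi) if last else (times < hi))
        if not np.any(win):
            raise FormatError(f"no samples in the tail of hold {i + 1}")
        eps[i] = protocol.cumulative_strain(i + 1)
        sig[i] = float(np.mean(stress[win]))
    return eps, sig


def _fit_equilibrium(eps_eq: np.ndarray, sig_eq: np.ndarray
                     ) -> tuple[float, float]:
    lo = (BOUNDS["c_a"][0], BOUNDS["c_b"][0])
    hi = (BOUNDS["c_a"][1], BOUNDS["c_b"][1])
    p0 = (float(np.clip(sig_eq[-1] / eps_eq[-1], lo[0], hi[0])), 1.0)
    (c_a, c_b), _ = curve_fit(equilibrium_stress, eps_eq, sig_eq, p0=p0,
                              bounds=(lo, hi), maxfev=20000)
    return float(c_a), float(c_b)


def _maxwell_tail(params: ViscoParams, protocol: StepProtocol,
                  times: np.ndarray, window_fraction: float) -> np.ndarray:
    """Mean unrelaxed Maxwell stress over each hold's tail window."""
    eq_stress = equilibrium_stress(
        protocol.step_magnitude * np.arange(1, protocol.n_steps + 1),
        params.c_a, params.c_b)
    total = simulate_protocol(params, protocol, times)
    tails = np.empty(protocol.n_steps)
    for i, (lo, hi) in enumerate(protocol.hold_windows()):
        last = hi >= protocol.span - 1e-12
        win = (times >= hi - window_fraction * protocol.hold_duration) \
            & ((times <= hi) if last else (times < hi))
        tails[i] = float(np.mean(total[win])) - eq_stress[i]
    return tails


def fit_viscoelastic(series: MechanicalTimeSeries, protocol: StepProtocol,
                     nu: float | None = None, stress: np.ndarray | None = None
                     ) -> ViscoFit:
    """Two-step fit of the five Maxwell-Wiechert parameters.

    Stress magnitudes are taken from ``stress`` if given, else computed as
    F / (pi r_c^2) from the series' force and radius frames.  Step 1 fits
    (c_a, c_b) to the end-of-hold equilibrium stresses; step 2 fits
    (c_m, eta1, eta2) to the full hold-phase trace with (c_a, c_b) frozen,
    multi-starting over a log-spaced grid of viscosity initialisations.
    Because the hyperbolic (1/t) relaxation leaves a non-negligible Maxwell
    stress at the end of finite holds, the staged estimate is biased; a
    joint refinement of all five parameters on the full hold trace from the
    staged starting point removes the bias (noiseless traces are recovered
    to optimizer tolerance).
    ``nu`` is accepted for interface symmetry with the compression fit; the
    relaxation model itself is uniaxial.
    """
    if stress is None:
        if series.force is None or series.radius is None:
            raise FormatError("stress requires force and radius frames")
        stress = np.abs(series.force) / (np.pi * series.radius ** 2)
    stress = np.asarray(stress, dtype=float)
    times = series.time

    if len(protocol.hold_windows()) < 2:
        raise FormatError("at least 2 holds are required")

    # -- step 1: nonlinear spring from end-of-hold equilibrium data
    eps_eq, sig_eq = extract_equilibrium(times, stress, protocol)
    c_a, c_b = _fit_equilibrium(eps_eq, sig_eq)

    # -- step 2: Maxwell elements from the transient response
    mask = _hold_samples(protocol, times)
    t_fit, s_fit = times[mask], stress[mask]
    # relative residual weights: the trace spans an order of magnitude in
    # stress across the steps, and instrument noise is closer to a constant
    # relative error, so each sample is weighted by 1/|stress| (floored)
    w_fit = 1.0 / np.maximum(np.abs(s_fit), 1e-3 * np.max(np.abs(s_fit)))

    # amplitude-based initial stiffness: jump above equilibrium at first hold
    first_lo, first_hi = protocol.hold_windows()[0]
    first = (times >= first_lo) & (times < first_hi)
    jump = max(float(np.max(stress[first]) - sig_eq[0]), 1e-6)
    c_m0 = float(np.clip(jump / (2.0 * protocol.step_magnitude),
                         *BOUNDS["c_m"]))

    lb = np.log([BOUNDS["c_m"][0], BOUNDS["eta"][0], BOUNDS["eta"][0]])
    ub = np.log([BOUNDS["c_m"][1], BOUNDS["eta"][1], BOUNDS["eta"][1]])

    def fit_maxwell(ca: float, cb: float, starts):
        def residual(x: np.ndarray) -> np.ndarray:
            c_m, e1, e2 = np.exp(x)
            p = ViscoParams(ca, cb, c_m, min(e1, e2), max(e1, e2))
            return w_fit * (simulate_protocol(p, protocol, t_fit) - s_fit)

        best, best_cost, diag = None, np.inf, []
        for x0 in starts:
            try:
                res = least_squares(residual, np.log(x0), bounds=(lb, ub),
                                    xtol=1e-12, ftol=1e-12, gtol=1e-12)
            except (DomainError, FloatingPointError) as exc:
                diag.append((tuple(x0), None, str(exc)))
                continue
            diag.append((tuple(x0), float(res.cost), None))
            if res.cost < best_cost:
                best, best_cost = res, res.cost
        return best, diag

    # characteristic viscosity scale: eta ~ eps * c_m * hold
    eta_scale = protocol.step_magnitude * c_m0 * protocol.hold_duration
    cands = np.clip(eta_scale * np.array([0.05, 0.3, 2.0, 12.0]),
                    *BOUNDS["eta"])
    starts = [(c_m0, cands[i], cands[j])
              for i in range(len(cands)) for j in range(i, len(cands))]
    starts = starts[:N_MULTISTART]
    best, costs = fit_maxwell(c_a, c_b, starts)
    if best is None:
        raise FitError(f"no start converged; diagnostics: {costs}")

    def as_params(ca, cb, x):
        c_m, e1, e2 = np.exp(x)
        return ViscoParams(float(ca), float(cb), float(c_m),
                           float(min(e1, e2)), float(max(e1, e2)))

    # -- joint polish: the hyperbolic (1/t) relaxation leaves unrelaxed
    # Maxwell stress at the end of finite holds, so the staged estimate is
    # biased; refine all five parameters together on the full hold trace
    # from the staged starting point (single objective -> exact recovery on
    # noiseless data)
    params = as_params(c_a, c_b, best.x)

    def residual5(x: np.ndarray) -> np.ndarray:
        ca, e1, e2 = np.exp(x[0]), np.exp(x[3]), np.exp(x[4])
        p = ViscoParams(ca, x[1], np.exp(x[2]), min(e1, e2), max(e1, e2))
        return w_fit * (simulate_protocol(p, protocol, t_fit) - s_fit)

    x0 = np.array([np.log(params.c_a), params.c_b, np.log(params.c_m),
                   np.log(params.eta1), np.log(params.eta2)])
    lb5 = np.array([np.log(BOUNDS["c_a"][0]), BOUNDS["c_b"][0],
                    np.log(BOUNDS["c_m"][0]), np.log(BOUNDS["eta"][0]),
                    np.log(BOUNDS["eta"][0])])
    ub5 = np.array([np.log(BOUNDS["c_a"][1]), BOUNDS["c_b"][1],
                    np.log(BOUNDS["c_m"][1]), np.log(BOUNDS["eta"][1]),
                    np.log(BOUNDS["eta"][1])])
    try:
        polish = least_squares(residual5, np.clip(x0, lb5, ub5),
                               bounds=(lb5, ub5),
                               xtol=1e-14, ftol=1e-14, gtol=1e-14)
        e1, e2 = np.exp(polish.x[3]), np.exp(polish.x[4])
        params = ViscoParams(float(np.exp(polish.x[0])), float(polish.x[1]),
                             float(np.exp(polish.x[2])),
                             float(min(e1, e2)), float(max(e1, e2)))
        best = polish
    except (DomainError, FloatingPointError):  # keep the staged estimate
        pass
    c_a, c_b = params.c_a, params.c_b

    eq_rms = float(np.sqrt(np.mean(
        (equilibrium_stress(eps_eq, params.c_a, params.c_b)
         + _maxwell_tail(params, protocol, times, EQUILIBRIUM_WINDOW)
         - sig_eq) ** 2)))
    rms = float(np.sqrt(np.mean(
        (simulate_protocol(params, protocol, t_fit) - s_fit) ** 2)))
    slow_flag = params.eta2 / params.c_m > 10.0 * protocol.hold_duration
    if slow_flag:
        log.warning("slow Maxwell element poorly constrained: eta2/c_m = %.3g s "
                    "exceeds 10x the hold duration", params.eta2 / params.c_m)
    return ViscoFit(params=params, rms_residual=rms, converged=best.success,
                    equilibrium_rms=eq_rms, slow_element_flag=slow_flag,
                    n_starts=len(starts), start_costs=costs)
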