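"""Synthetic-data generators with known ground truth for every pipeline input.

Each generator is a pure function of (parameters, seed): the same arguments
reproduce byte-identical output.  A :class:`SyntheticTruth` record travels
with every artifact and fully determines regeneration; it can be written as
a YAML sidecar next to the generated file.

What is emulated (and what is not): stepped indentation and stress-relaxation
force records with additive Gaussian noise from known constitutive
parameters; side-camera geometry consistent with a chosen Poisson ratio;
two-color trichrome and four-color picrosirius rasters composed of
contiguous irregular class regions with exact per-class pixel counts; axial
fiber angle sets with von Mises concentration on the doubled angles;
four-archetype cell feature tables with group-level shifts in area, aspect
ratio and marker intensities.  None of these claim photorealism or
instrument-specific artifacts (drift, optical distortion, segmentation
errors) - see the methods note for what passing tests do and do not show.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import ndimage
from scipy.stats import truncnorm

from .io import (ConfigurationError, DomainError, FormatError,
                 MechanicalTimeSeries, StepProtocol)
from .histology import DEFAULT_BANDS, HueBand, StainRaster, hsl_to_rgb
from .viscoelastic import ViscoParams, simulate_protocol

__all__ = [
    "SyntheticTruth", "gen_indentation", "gen_relaxation", "gen_stain_raster",
    "gen_fibers", "gen_cell_table", "gen_grouped", "ARCHETYPES",
    "DEFAULT_GROUP_EFFECTS",
]


@dataclass
class SyntheticTruth:
    """Ground-truth sidecar: generator name, parameters, seed."""

    generator: str
    parameters: dict
    seed: int
    extras: dict = field(default_factory=dict)

    def to_yaml(self, path) -> None:
        payload = {"generator": self.generator, "seed": self.seed,
                   "parameters": self.parameters}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(generator=d["generator"], parameters=d["parameters"],
                   seed=d["seed"])


def _sample_times(protocol: StepProtocol, dt: float) -> np.ndarray:
    """Hold-phase sample grid (plus ramp endpoints when ramps are finite)."""
    times = []
    for i, (lo, hi) in enumerate(protocol.hold_windows()):
        if protocol.ramp_duration:
            times.append(np.array([lo - protocol.ramp_duration]))
        n = max(int(round((hi - lo) / dt)), 2)
        times.append(np.linspace(lo, hi, n + 1))
    t = np.concatenate(times)
    # strictly increasing with no duplicated boundary samples
    keep = np.concatenate([[True], np.diff(t) > 1e-12])
    return t[keep]


# --------------------------------------------------------------------------
# mechanics
# --------------------------------------------------------------------------

def gen_indentation(E_true: float, R: float = 38.1e-6, nu: float = 0.5,
                    H0: float = 3e-3,
                    protocol: StepProtocol | None = None,
                    noise_sd: float = 0.0, seed: int = 0, sample_dt: float = 1.0
                    ) -> tuple[MechanicalTimeSeries, SyntheticTruth]:
    """Stepped flat-punch indentation record.

    Hold-phase steady forces lie on the Sneddon line
    F = E * 2R * delta / (1 - nu^2) plus zero-mean Gaussian noise of sd
    ``noise_sd`` (N); ramps (if the protocol has a finite ramp rate) are
    linear segments between steady levels.
    """
    if E_true < 0:
        raise FormatError("E_true must be non-negative")
    if not 0 < nu <= 0.5:
        if nu >= 1:
            raise DomainError("nu = 1 makes the Sneddon prefactor singular")
        raise FormatError("nu must be in (0, 0.5]")
    protocol = protocol or StepProtocol(5, 0.01, 60.0)
    rng = np.random.default_rng(seed)
    t = _sample_times(protocol, sample_dt)

    deltas = np.array([protocol.cumulative_strain(i) * H0
                       for i in range(protocol.n_steps + 1)])
    steady = E_true * 2.0 * R * deltas / (1.0 - nu ** 2)
    if protocol.ramp_duration:
        # linear ramps between steady levels; no duplicate breakpoints
        breakpoints, levels = [], []
        for i, (lo, hi) in enumerate(protocol.hold_windows(), start=1):
            breakpoints += [lo - protocol.ramp_duration, lo, hi]
            levels += [steady[i - 1], steady[i], steady[i]]
        force = np.interp(t, breakpoints, levels)
    else:
        # instantaneous steps; a sample at a boundary carries the next load
        period = protocol.hold_duration
        step_of = np.minimum((t / period).astype(int) + 1, protocol.n_steps)
        force = steady[step_of]
    force = force + rng.normal(0.0, noise_sd, size=len(t)) if noise_sd > 0 else force

    series = MechanicalTimeSeries(time=t, force=force, H0=H0,
                                  specimen_id=f"synth-indent-{seed}")
    truth = SyntheticTruth(
        generator="gen_indentation", seed=seed,
        parameters={"E_true": E_true, "R": R, "nu": nu, "H0": H0,
                    "noise_sd": noise_sd, "n_steps": protocol.n_steps,
                    "step_magnitude": protocol.step_magnitude,
                    "hold_duration": protocol.hold_duration})
    return series, truth


def gen_relaxation(params: ViscoParams, nu_true: float = 0.45,
                   H0: float = 3e-3, R0: float = 1.5e-3,
                   protocol: StepProtocol | None = None,
                   noise_sd: float = 0.0, seed: int = 0, sample_dt: float = 1.0,
                   geometry_noise_sd: float = 0.0, noise_relative: float = 0.0
                   ) -> tuple[MechanicalTimeSeries, SyntheticTruth]:
    """Stepped unconfined-compression stress-relaxation record.

    The stress magnitude trace comes from the Maxwell-Wiechert forward model
    on the protocol's cumulative strain magnitudes; Gaussian noise of sd
    ``noise_sd`` (Pa, additive) plus ``noise_relative`` (sd proportional to
    the sample's stress) is added on stress and converted to force through
    the current cross-section, F = |sigma| * pi * r_c^2.  Geometry frames
    satisfy eps_rr = -nu_true * eps_zz exactly (optionally perturbed by
    ``geometry_noise_sd`` on the radius frames, in meters).
    """
    if not 0 < nu_true <= 0.5:
        raise FormatError("nu_true must be in (0, 0.5]")
    protocol = protocol or StepProtocol(8, 0.025, 120.0)
    if protocol.total_deformation >= 1.0:
        raise FormatError("protocol total deformation must be < 100%")
    rng = np.random.default_rng(seed)
    t = _sample_times(protocol, sample_dt)

    sigma = simulate_protocol(params, protocol, t)
    if noise_relative > 0:
        sigma = sigma * (1.0 + rng.normal(0.0, noise_relative, size=len(t)))
    if noise_sd > 0:
        sigma = sigma + rng.normal(0.0, noise_sd, size=len(t))

    step_of = np.minimum((t / protocol.hold_duration).astype(int) + 1,
                         protocol.n_steps)
    eps_zz = -protocol.step_magnitude * step_of  # signed compressive strain
    eps_rr = -nu_true * eps_zz
    height = H0 * (1.0 + eps_zz)
    radius = R0 * (1.0 + eps_rr)
    if geometry_noise_sd > 0:
        radius = radius + rng.normal(0.0, geometry_noise_sd, size=len(t))
    force = sigma * np.pi * radius ** 2  # positive compressive load magnitude

    series = MechanicalTimeSeries(time=t, force=force, height=height,
                                  radius=radius, H0=H0, R0=R0,
                                  specimen_id=f"synth-relax-{seed}")
    truth = SyntheticTruth(
        generator="gen_relaxation", seed=seed,
        parameters={"c_a": params.c_a, "c_b": params.c_b, "c_m": params.c_m,
                    "eta1": params.eta1, "eta2": params.eta2,
                    "nu_true": nu_true, "H0": H0, "R0": R0,
                    "noise_sd": noise_sd, "n_steps": protocol.n_steps,
                    "step_magnitude": protocol.step_magnitude,
                    "hold_duration": protocol.hold_duration})
    return series, truth


# --------------------------------------------------------------------------
# stain rasters
# --------------------------------------------------------------------------

def _band_color_jitter(band: HueBand, rng: np.random.Generator, n: int
                       ) -> np.ndarray:
    """n RGB rows sampled inside the central part of a band (8-bit safe)."""
    intervals = band.hue_intervals()
    widths = np.array([hi - lo for lo, hi in intervals])
    total = widths.sum()
    # hue in the central 60% of the (possibly wrapped) band
    u = rng.uniform(0.2, 0.8, size=n) * total
    h = np.empty(n)
    off = 0.0
    for (lo, hi), w in zip(intervals, widths):
        sel = (u >= off) & (u < off + w)
        h[sel] = lo + (u[sel] - off)
        off += w
    s_lo, s_hi = max(band.sat[0], 0.35), min(band.sat[1], 0.85)
    l_lo, l_hi = max(band.light[0], 0.35), min(band.light[1], 0.65)
    s = rng.uniform(s_lo, s_hi, size=n)
    l = rng.uniform(l_lo, l_hi, size=n)
    return hsl_to_rgb(h, s, l)


#: generator color classes per stain; MTC "red" (cytoplasm) is rendered but
#: intentionally falls outside the MTC band set (counts as unclassified tissue)
_GEN_BANDS: dict[str, dict[str, HueBand]] = {
    "MTC": {"blue": DEFAULT_BANDS["MTC"][0],
            "red": HueBand("red", 340.0, 20.0, sat=(0.3, 0.9), light=(0.3, 0.7))},
    "PSR": {b.name: b for b in DEFAULT_BANDS["PSR"]},
}


def gen_stain_raster(stain: str, class_fractions: dict[str, float],
                     size: int = 512, seed: int = 0
                     ) -> tuple[StainRaster, SyntheticTruth]:
    """Block-composed synthetic stain raster with known class fractions.

    ``class_fractions`` are fractions of the whole raster; their sum must be
    <= 1 and the remainder is rendered as background (white for MTC, black
    for PSR).  Class regions are contiguous with irregular boundaries
    (quantile bins of a smoothed random field), so pixel counts are exact up
    to rounding.  The truth records both the requested raster fractions and
    the implied over-tissue fractions that classification recovers.
    """
    if stain not in _GEN_BANDS:
        raise FormatError(f"unknown stain {stain!r}")
    fracs = dict(class_fractions)
    for name, f in fracs.items():
        if name not in _GEN_BANDS[stain]:
            raise ConfigurationError(f"unknown class {name!r} for {stain}")
        if not 0.0 <= f <= 1.0:
            raise ConfigurationError("fractions must be in [0, 1]")
    total = sum(fracs.values())
    if total > 1.0 + 1e-12:
        raise ConfigurationError("class fractions sum to more than 1")

    rng = np.random.default_rng(seed)
    field_ = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                     sigma=size / 16.0)
    order = np.argsort(field_.ravel(), kind="stable")
    n_pix = size * size

    names = sorted(fracs)  # deterministic class order
    counts = [int(round(fracs[k] * n_pix)) for k in names]
    overflow = sum(counts) - n_pix
    if overflow > 0:
        counts[-1] -= overflow
    label = np.full(n_pix, -1, dtype=int)  # -1 = background
    pos = 0
    for k, c in enumerate(counts):
        label[order[pos:pos + c]] = k
        pos += c
    label = label.reshape(size, size)

    bg = np.array([255, 255, 255] if stain == "MTC" else [0, 0, 0],
                  dtype=np.uint8)
    img = np.empty((size, size, 3), dtype=np.uint8)
    img[label == -1] = bg
    for k, name in enumerate(names):
        sel = label == k
        img[sel] = _band_color_jitter(_GEN_BANDS[stain][name], rng,
                                      int(np.count_nonzero(sel)))

    n_tissue = int(np.count_nonzero(label >= 0))
    tissue_fracs = {name: (counts[k] / n_tissue if n_tissue else 0.0)
                    for k, name in enumerate(names)}
    raster = StainRaster(pixels=img, stain=stain)
    truth = SyntheticTruth(
        generator="gen_stain_raster", seed=seed,
        parameters={"stain": stain, "class_fractions": fracs, "size": size},
        extras={"tissue_fractions": tissue_fracs, "label_map": label,
                "tissue_pixels": n_tissue})
    return raster, truth


# --------------------------------------------------------------------------
# fibers
# --------------------------------------------------------------------------

def gen_fibers(n: int, mean_angle: float = 90.0, kappa: float = 0.0,
               length_dist: tuple[float, float] = (30.0, 10.0),
               width_dist: tuple[float, float] = (3.0, 1.0),
               intensity_dist: tuple[float, float] = (100.0, 20.0),
               seed: int = 0, grid: bool = False
               ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Axial fiber-segment table with von Mises angle concentration.

    Angles are drawn von Mises on the doubled angles (the standard axial-data
    construction) and halved into [0, 180); kappa = 0 gives uniform axial
    orientations, large kappa the aligned limit.  ``grid=True`` instead
    places the n angles on an even grid over [0, 180) (the exact-uniform
    case).  Lengths and widths are normal truncated at 0; intensities are
    non-negative.
    """
    if n < 1:
        raise FormatError("n must be >= 1")
    if kappa < 0:
        raise FormatError("kappa must be >= 0")
    rng = np.random.default_rng(seed)
    if grid:
        angles = np.arange(n) * (180.0 / n)
    elif kappa == 0:
        angles = rng.uniform(0.0, 180.0, size=n)
    else:
        doubled = rng.vonmises(np.deg2rad(2.0 * mean_angle), kappa, size=n)
        angles = (np.rad2deg(doubled) / 2.0) % 180.0

    def _trunc(mean: float, sd: float, size: int) -> np.ndarray:
        if sd == 0:
            return np.full(size, mean)
        a = (0.0 - mean) / sd
        return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size,
                             random_state=rng)

    fibers = pd.DataFrame({
        "angle_deg": angles,
        "length_um": _trunc(*length_dist, n),
        "width_um": _trunc(*width_dist, n),
        "intensity": _trunc(*intensity_dist, n),
    })
    truth = SyntheticTruth(
        generator="gen_fibers", seed=seed,
        parameters={"n": n, "mean_angle": mean_angle, "kappa": kappa,
                    "length_dist": list(length_dist),
                    "width_dist": list(width_dist),
                    "intensity_dist": list(intensity_dist), "grid": grid})
    return fibers, truth


# --------------------------------------------------------------------------
# cell feature tables
# --------------------------------------------------------------------------

#: phenotype archetypes: area (um^2), aspect ratio, PanCK and Vimentin (a.u.)
ARCHETYPES: dict[str, dict[str, float]] = {
    "epithelial-large": {"area": 420.0, "aspect": 1.3, "panck": 800.0,
                         "vimentin": 110.0},
    "epithelial-small": {"area": 130.0, "aspect": 1.2, "panck": 760.0,
                         "vimentin": 100.0},
    "stroma": {"area": 360.0, "aspect": 2.6, "panck": 90.0, "vimentin": 700.0},
    "immune": {"area": 90.0, "aspect": 1.15, "panck": 80.0, "vimentin": 640.0},
}

#: the four study groups (onset x tissue)
GROUPS = ("AO-normal", "AO-cancer", "EO-normal", "EO-cancer")

#: qualitative group shifts: EO cells smaller, cancer cells larger than
#: matched normal; EO-normal more elongated, EO-cancer more rounded; PanCK
#: lower and Vimentin higher in EO; Vimentin lower in cancer.  Multiplicative
#: on (area, aspect, PanCK, Vimentin).
DEFAULT_GROUP_EFFECTS: dict[str, tuple[float, float, float, float]] = {
    "AO-normal": (1.00, 1.00, 1.00, 1.00),
    "AO-cancer": (1.20, 1.00, 1.00, 0.85),
    "EO-normal": (0.80, 1.15, 0.85, 1.15),
    "EO-cancer": (0.96, 0.90, 0.85, 0.98),
}

#: archetype mixing proportions per tissue type
_MIX = {"normal": (0.22, 0.24, 0.32, 0.22), "cancer": (0.34, 0.30, 0.20, 0.16)}


def gen_cell_table(n_per_group: int = 500,
                   group_effects: dict | None = None,
                   noise_scale: float = 1.0, seed: int = 0
                   ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Four-archetype, four-group synthetic cell feature table.

    Each group mixes the four phenotype archetypes; group effects shift area,
    aspect ratio, PanCK and Vimentin multiplicatively (all-ones effects make
    the groups exchangeable).  Areas are log-normal (positive, right-skewed);
    markers are truncated normal.  ``noise_scale`` scales all dispersion
    (smaller = better-separated archetypes).  Latent phenotype labels are
    stored in the truth, not in the table.
    """
    if n_per_group < 10:
        raise FormatError("n_per_group must be >= 10")
    effects = dict(DEFAULT_GROUP_EFFECTS if group_effects is None
                   else group_effects)
    rng = np.random.default_rng(seed)
    arche_names = list(ARCHETYPES)

    rows, latent = [], []
    for group in GROUPS:
        tissue = group.split("-")[1]
        a_shift, ar_shift, pk_shift, vm_shift = effects[group]
        counts = rng.multinomial(n_per_group, _MIX[tissue])
        for arche, count in zip(arche_names, counts):
            base = ARCHETYPES[arche]
            area = base["area"] * a_shift * np.exp(
                rng.normal(0.0, 0.25 * noise_scale, count))
            aspect = np.maximum(
                base["aspect"] * ar_shift
                + rng.normal(0.0, 0.15 * noise_scale, count), 1.0)
            panck = np.maximum(base["panck"] * pk_shift
                               + rng.normal(0.0, 60.0 * noise_scale, count), 0.0)
            vim = np.maximum(base["vimentin"] * vm_shift
                             + rng.normal(0.0, 60.0 * noise_scale, count), 0.0)
            minor = np.sqrt(4.0 * area / (np.pi * aspect))
            major = aspect * minor
            ecc = np.sqrt(1.0 - 1.0 / aspect ** 2)
            rows.append(pd.DataFrame({
                "group": group,
                "area": area,
                "major_axis": major,
                "minor_axis": minor,
                "eccentricity": ecc,
                "solidity": np.clip(
                    rng.normal(0.95, 0.02 * noise_scale, count), 0.0, 1.0),
                "extent": np.clip(
                    rng.normal(0.72, 0.05 * noise_scale, count), 0.0, 1.0),
                "orientation": rng.uniform(-90.0, 90.0, count),
                "panck": panck,
                "vimentin": vim,
            }))
            latent.append(np.full(count, arche))
    table = pd.concat(rows, ignore_index=True)
    table.insert(0, "cell_id", np.arange(len(table)))
    truth = SyntheticTruth(
        generator="gen_cell_table", seed=seed,
        parameters={"n_per_group": n_per_group, "noise_scale": noise_scale,
                    "group_effects": {k: list(v) for k, v in effects.items()}},
        extras={"phenotype": np.concatenate(latent)})
    return table, truth


def gen_grouped(n: int = 20, location_shifts: dict | None = None,
                noise: float = 1.0, seed: int = 0
                ) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Grouped measurement table for the rank statistics.

    ``location_shifts`` maps group keys to location shifts; tuple keys
    ``(a_level, b_level)`` produce a two-factor layout, string keys a
    one-factor layout.  Values are Gaussian around the shift with sd
    ``noise``; ``n`` observations per cell.
    """
    shifts = location_shifts if location_shifts is not None else {
        ("AO", "normal"): 0.0, ("AO", "cancer"): 0.0,
        ("EO", "normal"): 0.0, ("EO", "cancer"): 0.0}
    rng = np.random.default_rng(seed)
    rows = []
    for key in shifts:
        a, b = key if isinstance(key, tuple) else (key, "all")
        rows.append(pd.DataFrame({
            "value": shifts[key] + rng.normal(0.0, noise, size=n),
            "factor_a": a, "factor_b": b}))
    table = pd.concat(rows, ignore_index=True)
    truth = SyntheticTruth(
        generator="gen_grouped", seed=seed,
        parameters={"n": n, "noise": noise,
                    "location_shifts": {str(k): v for k, v in shifts.items()}})
    return table, truth
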