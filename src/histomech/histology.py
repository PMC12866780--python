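"""Colorimetric pixel classification of trichrome and picrosirius-red stains.

Classification runs in the HSL (hue-saturation-lightness, bi-cone) color
space.  Masson's trichrome (MTC) collagen is the blue band H = 150-249 deg;
picrosirius red (PSR) birefringence is split into red (324-12, wrapping
through 0), orange (13-52), yellow (53-72) and green (73-180) with
S = 0.1-1 and L = 0.1-0.93.  Hue comparisons are half-open ``[lo, hi+1)`` on
the printed integer boundaries so adjacent bands partition without
double-counting.  Area fractions are reported over tissue (non-background)
pixels; background is near-white for MTC and near-black for PSR.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ConfigurationError, FormatError, get_logger

log = get_logger(__name__)

#: default background lightness cutoffs
MTC_WHITE_CUTOFF = 0.95
PSR_BLACK_CUTOFF = 0.05


# --------------------------------------------------------------------------
# HSL conversion (bi-cone; skimage/matplotlib provide only HSV)
# --------------------------------------------------------------------------

def rgb_to_hsl(rgb: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Convert an 8-bit (or float in [0,1]) RGB array to (H deg, S, L).

    H in [0, 360); S, L in [0, 1]; achromatic pixels get H = 0, S = 0.
    Matches the stdlib ``colorsys.rgb_to_hls`` definition, vectorized.
    """
    rgb = np.asarray(rgb)
    if rgb.ndim < 1 or rgb.shape[-1] != 3:
        raise FormatError("expected an RGB array with 3 channels last")
    x = rgb.astype(float)
    if np.issubdtype(rgb.dtype, np.integer):
        x = x / 255.0
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    mx, mn = np.max(x, axis=-1), np.min(x, axis=-1)
    c = mx - mn
    l = (mx + mn) / 2.0

    with np.errstate(divide="ignore", invalid="ignore"):
        s = np.where(c == 0, 0.0, c / (1.0 - np.abs(2.0 * l - 1.0)))
        hp = np.zeros_like(l)
        hp = np.where(mx == r, ((g - b) / c) % 6.0, hp)
        hp = np.where((mx == g) & (mx != r), (b - r) / c + 2.0, hp)
        hp = np.where((mx == b) & (mx != r) & (mx != g), (r - g) / c + 4.0, hp)
    h = np.where(c == 0, 0.0, hp * 60.0) % 360.0
    s = np.clip(np.nan_to_num(s), 0.0, 1.0)
    return h, s, l


def hsl_to_rgb(h: np.ndarray, s: np.ndarray, l: np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_hsl`; returns an 8-bit RGB array."""
    h = np.asarray(h, dtype=float) % 360.0
    s = np.asarray(s, dtype=float)
    l = np.asarray(l, dtype=float)
    c = (1.0 - np.abs(2.0 * l - 1.0)) * s
    hp = h / 60.0
    x = c * (1.0 - np.abs(hp % 2.0 - 1.0))
    z = np.zeros_like(c)
    sector = np.floor(hp).astype(int) % 6
    r = np.select([sector == 0, sector == 1, sector == 2,
                   sector == 3, sector == 4, sector == 5],
                  [c, x, z, z, x, c])
    g = np.select([sector == 0, sector == 1, sector == 2,
                   sector == 3, sector == 4, sector == 5],
                  [x, c, c, x, z, z])
    b = np.select([sector == 0, sector == 1, sector == 2,
                   sector == 3, sector == 4, sector == 5],
                  [z, z, x, c, c, x])
    m = l - c / 2.0
    rgb = np.stack([r + m, g + m, b + m], axis=-1)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HueBand:
    """Named HSL band.  Hue interval is half-open ``[hue_lo, hue_hi)`` degrees
    with wraparound when ``hue_lo > hue_hi`` (the interval crosses 0).
    Saturation and lightness intervals are closed."""

    name: str
    hue_lo: float
    hue_hi: float
    sat: tuple[float, float] = (0.0, 1.0)
    light: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for lo, hi, what in ((*self.sat, "saturation"), (*self.light, "lightness")):
            if not (0.0 <= lo <= hi <= 1.0):
                raise ConfigurationError(f"invalid {what} range for {self.name}")
        if not (0.0 <= self.hue_lo < 360.0 and 0.0 < self.hue_hi <= 360.0):
            raise ConfigurationError(f"invalid hue range for {self.name}")

    def hue_intervals(self) -> list[tuple[float, float]]:
        """Unrolled non-wrapping hue intervals in [0, 360)."""
        if self.hue_lo < self.hue_hi:
            return [(self.hue_lo, self.hue_hi)]
        return [(self.hue_lo, 360.0), (0.0, self.hue_hi)]

    def contains(self, h: np.ndarray, s: np.ndarray, l: np.ndarray) -> np.ndarray:
        in_hue = np.zeros(np.shape(h), dtype=bool)
        for lo, hi in self.hue_intervals():
            in_hue |= (h >= lo) & (h < hi)
        return (in_hue & (s >= self.sat[0]) & (s <= self.sat[1])
                & (l >= self.light[0]) & (l <= self.light[1]))


# printed band definitions; exclusive hue bound = printed upper bound + 1 deg
MTC_BANDS: tuple[HueBand, ...] = (
    HueBand("blue", 150.0, 250.0, sat=(0.0, 1.0), light=(0.01, 1.0)),
)
_PSR_SL = {"sat": (0.1, 1.0), "light": (0.1, 0.93)}
PSR_BANDS: tuple[HueBand, ...] = (
    HueBand("red", 324.0, 13.0, **_PSR_SL),
    HueBand("orange", 13.0, 53.0, **_PSR_SL),
    HueBand("yellow", 53.0, 73.0, **_PSR_SL),
    HueBand("green", 73.0, 181.0, **_PSR_SL),
)

DEFAULT_BANDS = {"MTC": MTC_BANDS, "PSR": PSR_BANDS}


@dataclass
class StainRaster:
    """8-bit RGB histology raster with its stain kind (``MTC`` or ``PSR``)."""

    pixels: np.ndarray
    stain: str
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[-1] != 3:
            raise FormatError("raster must be H x W x 3")
        if self.pixels.size == 0:
            raise FormatError("raster is empty")
        if self.stain not in ("MTC", "PSR"):
            raise FormatError(f"unknown stain kind {self.stain!r}")


@dataclass
class AreaFractionReport:
    """Per-band area fractions over tissue pixels."""

    fractions: dict[str, float]
    tissue_pixels: int
    background_pixels: int

    @property
    def unclassified_fraction(self) -> float:
        return 1.0 - sum(self.fractions.values())

    def to_frame(self, image: str = "") -> pd.DataFrame:
        return pd.DataFrame(
            [{"image": image, "band": k, "fraction": v,
              "tissue_pixels": self.tissue_pixels}
             for k, v in self.fractions.items()])


# --------------------------------------------------------------------------
# operations
# --------------------------------------------------------------------------

def mask_background(raster: StainRaster,
                    white_cutoff: float = MTC_WHITE_CUTOFF,
                    black_cutoff: float = PSR_BLACK_CUTOFF) -> np.ndarray:
    """Boolean tissue mask.  Background is L >= ``white_cutoff`` for MTC
    (white background) or L <= ``black_cutoff`` for PSR (black background)."""
    _, _, l = rgb_to_hsl(raster.pixels)
    if raster.stain == "MTC":
        tissue = l < white_cutoff
    else:
        tissue = l > black_cutoff
    if not np.any(tissue):
        raise FormatError("empty tissue mask: nothing to quantify")
    return tissue


def _check_band_overlap(bands) -> None:
    intervals = []
    for band in bands:
        for lo, hi in band.hue_intervals():
            intervals.append((lo, hi, band.name))
    intervals.sort()
    for (lo1, hi1, n1), (lo2, hi2, n2) in zip(intervals, intervals[1:]):
        if lo2 < hi1:
            raise ConfigurationError(f"hue bands {n1!r} and {n2!r} overlap")


def classify_and_fraction(raster: StainRaster, bands=None,
                          tissue_mask: np.ndarray | None = None
                          ) -> AreaFractionReport:
    """Assign each tissue pixel to at most one band and report fractions.

    ``bands`` defaults to the stain's printed band set.  Fractions are band
    pixels / tissue pixels; unclassified tissue is allowed, so the fractions
    need not sum to 1.
    """
    if bands is None:
        bands = DEFAULT_BANDS[raster.stain]
    _check_band_overlap(bands)
    if tissue_mask is None:
        tissue_mask = mask_background(raster)
    h, s, l = rgb_to_hsl(raster.pixels)
    n_tissue = int(np.count_nonzero(tissue_mask))
    fractions = {}
    for band in bands:
        hit = band.contains(h, s, l) & tissue_mask
        fractions[band.name] = float(np.count_nonzero(hit)) / n_tissue
    return AreaFractionReport(fractions=fractions, tissue_pixels=n_tissue,
                              background_pixels=int(tissue_mask.size - n_tissue))


def read_raster(path, stain: str) -> StainRaster:
    """Load a TIFF or PNG image as a stain raster (alpha channel dropped)."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        arr = tifffile.imread(path)
    else:
        from PIL import Image
        arr = np.asarray(Image.open(path).convert("RGB"))
    if arr.ndim == 3 and arr.shape[-1] == 4:
        arr = arr[..., :3]
    return StainRaster(pixels=arr, stain=stain)


def write_raster(raster: StainRaster, path) -> None:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile
        tifffile.imwrite(path, raster.pixels)
    else:
        from PIL import Image
        Image.fromarray(raster.pixels).save(path)
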