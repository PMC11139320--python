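"""Display channel model: calibration and viewing geometry.

Pixel values map to luminance through a parametric gamma curve (or a
user-supplied lookup table), and pixel-domain grating periods map to
cycles per degree of visual angle through the screen geometry.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError, DomainError

__all__ = [
    "DisplayModel",
    "default_pixel_pitch_mm",
    "pixel_to_luminance",
    "luminance_to_pixel",
    "period_to_cpd",
    "cpd_to_period",
    "pixels_per_degree",
]

#: default panel: 22-inch diagonal, 16:9, 1920x1080
_DEFAULT_DIAGONAL_IN = 22.0
_DEFAULT_RESOLUTION = (1920, 1080)


def default_pixel_pitch_mm(
    diagonal_in: float = _DEFAULT_DIAGONAL_IN,
    resolution: tuple[int, int] = _DEFAULT_RESOLUTION,
) -> float:
    """Pixel pitch (mm/pixel, square pixels) from diagonal and resolution."""
    diag_px = math.hypot(*resolution)
    return diagonal_in * 25.4 / diag_px


@dataclass
class DisplayModel:
    """Photometric calibration plus viewing geometry.

    ``lut`` (optional) is an (N, 2) array of (pixel value, cd/m^2) pairs;
    when present it overrides the gamma curve via linear interpolation.
    A viewing distance outside the clear-vision zone
    [``min_distance_m``, ``max_distance_m``] raises a warning, not an
    error, so off-design geometries remain usable.
    """

    gamma: float = 2.4
    peak_luminance: float = 200.0
    black_level: float = 0.0
    pixel_pitch_mm: float = field(default_factory=default_pixel_pitch_mm)
    viewing_distance_m: float = 1.0
    min_distance_m: float = 0.872
    max_distance_m: float = 1.149
    lut: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.gamma <= 0:
            raise DomainError("gamma must be > 0")
        if not (self.peak_luminance > self.black_level >= 0):
            raise DomainError("need peak_luminance > black_level >= 0")
        if self.pixel_pitch_mm <= 0 or self.viewing_distance_m <= 0:
            raise DomainError("pitch and viewing distance must be > 0")
        if not (self.min_distance_m < self.max_distance_m):
            raise DomainError("min_distance_m must be < max_distance_m")
        if not (self.min_distance_m <= self.viewing_distance_m <= self.max_distance_m):
            warnings.warn(
                f"viewing distance {self.viewing_distance_m} m is outside the "
                f"clear-vision zone [{self.min_distance_m}, {self.max_distance_m}] m",
                stacklevel=3,
            )
        if self.lut is not None:
            lut = np.asarray(self.lut, dtype=float)
            if lut.ndim != 2 or lut.shape[1] != 2 or lut.shape[0] < 2:
                raise DataError("calibration LUT must be an (N>=2, 2) table")
            if np.any(np.diff(lut[:, 0]) <= 0):
                raise DataError("LUT pixel values must be strictly increasing")
            self.lut = lut

    @classmethod
    def from_lut_csv(cls, path, **kwargs) -> "DisplayModel":
        """Build a model whose calibration comes from a two-column CSV
        (pixel value, cd/m^2)."""
        lut = np.loadtxt(path, delimiter=",", skiprows=0, ndmin=2)
        return cls(lut=lut, **kwargs)


def pixel_to_luminance(p, dm: DisplayModel):
    """Luminance (cd/m^2) emitted for 8-bit pixel value ``p``.

    Parametric form: ``black + (peak - black) * (p/255)**gamma``; with a
    LUT, linear interpolation between calibration points.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 255)):
        raise DomainError("pixel value outside [0, 255]")
    if dm.lut is not None:
        out = np.interp(p, dm.lut[:, 0], dm.lut[:, 1])
    else:
        out = dm.black_level + (dm.peak_luminance - dm.black_level) * (
            p / 255.0
        ) ** dm.gamma
    return out if out.ndim else float(out)


def luminance_to_pixel(luminance, dm: DisplayModel):
    """Inverse of :func:`pixel_to_luminance` (continuous pixel value)."""
    L = np.asarray(luminance, dtype=float)
    if np.any(L < dm.black_level) or np.any(L > dm.peak_luminance):
        if dm.lut is None:
            raise DomainError("luminance outside the display range")
    if dm.lut is not None:
        out = np.interp(L, dm.lut[:, 1], dm.lut[:, 0])
    else:
        frac = (L - dm.black_level) / (dm.peak_luminance - dm.black_level)
        out = 255.0 * frac ** (1.0 / dm.gamma)
    return out if out.ndim else float(out)


def period_to_cpd(period_px, dm: DisplayModel):
    """Spatial frequency (cycles/degree) of a grating of the given pixel
    period, from the exact subtended-angle formula."""
    period_px = np.asarray(period_px, dtype=float)
    if np.any(period_px < 2):
        raise DomainError("period must be >= 2 px")
    half = period_px * dm.pixel_pitch_mm * 1e-3 / (2.0 * dm.viewing_distance_m)
    deg = 2.0 * np.degrees(np.arctan(half))
    out = 1.0 / deg
    return out if out.ndim else float(out)


def cpd_to_period(cpd, dm: DisplayModel):
    """Grating period in pixels for a given spatial frequency (cycles/deg)."""
    cpd = np.asarray(cpd, dtype=float)
    if np.any(cpd <= 0):
        raise DomainError("spatial frequency must be > 0")
    half_rad = np.radians(1.0 / (2.0 * cpd))
    out = np.tan(half_rad) * 2.0 * dm.viewing_distance_m / (dm.pixel_pitch_mm * 1e-3)
    return out if out.ndim else float(out)


def pixels_per_degree(dm: DisplayModel) -> float:
    """Small-angle pixels-per-degree factor used for DFT-grid frequency
    conversion in the video metric."""
    deg_per_px = 2.0 * math.degrees(
        math.atan(dm.pixel_pitch_mm * 1e-3 / (2.0 * dm.viewing_distance_m))
    )
    return 1.0 / deg_per_px
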