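"""Synthesis of the circular windowed-grating test pattern ("mira").

The pattern is a vertical sinusoidal grating multiplied by a radial Kaiser
window, blended into a uniform mid-grey background.  The module also provides
the closed-form spatial spectrum of the windowed grating and the temporal
(flicker) modulation waveform applied to the whole pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import i0

from .errors import ClippingError, DomainError

__all__ = [
    "MiraSpec",
    "FlickerSpec",
    "kaiser_window",
    "render_mira",
    "quantize_to_display",
    "mira_spectrum",
    "flicker_waveform",
]


@dataclass(frozen=True)
class MiraSpec:
    """Geometric and photometric parameters of the test pattern.

    Parameters
    ----------
    width_px, height_px
        Screen dimensions in pixels.
    diameter_px
        Diameter of the circular pattern, pixels.  Must fit on screen.
    kaiser_beta
        Kaiser window shape parameter, >= 0.  0 gives a flat (rectangular)
        radial window.
    period_px
        Grating period in pixels, >= 2 (pixel-grid Nyquist limit).
    background_level
        Nominal 8-bit background brightness.
    modulation_amplitude
        Peak deviation from the background in 8-bit units.
    """

    width_px: int
    height_px: int
    diameter_px: int
    kaiser_beta: float
    period_px: float
    background_level: int = 120
    modulation_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter_px > min(self.width_px, self.height_px):
            raise DomainError(
                f"pattern diameter {self.diameter_px} exceeds screen "
                f"{self.width_px}x{self.height_px}"
            )
        if self.diameter_px <= 0:
            raise DomainError("diameter must be positive")
        if self.kaiser_beta < 0:
            raise DomainError("kaiser_beta must be >= 0")
        if self.period_px < 2:
            raise DomainError("grating period must be >= 2 px (Nyquist)")
        if not (0 <= self.background_level <= 255):
            raise DomainError("background_level outside 8-bit range")
        if self.modulation_amplitude < 0:
            raise DomainError("modulation_amplitude must be >= 0")
        lo = self.background_level - self.modulation_amplitude
        hi = self.background_level + self.modulation_amplitude
        if lo < 0 or hi > 255:
            raise ClippingError(
                f"level {self.background_level} +/- amplitude "
                f"{self.modulation_amplitude} leaves [0, 255]"
            )


@dataclass(frozen=True)
class FlickerSpec:
    """Temporal modulation of the whole pattern.

    The physical backlight is driven by PWM at ``pwm_carrier_hz``; the
    carrier is far above any perceivable rate, so only the envelope at
    ``temporal_frequency_hz`` is generated.  ``mean_factor`` is the
    time-averaged multiplicative brightness factor, identical for both
    waveform modes.
    """

    temporal_frequency_hz: float
    modulation_depth: float
    pwm_carrier_hz: float = 3900.0
    waveform: str = "square"
    mean_factor: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.modulation_depth <= 1.0):
            raise DomainError("modulation_depth must lie in [0, 1]")
        if self.temporal_frequency_hz < 0:
            raise DomainError("temporal_frequency_hz must be >= 0")
        if self.temporal_frequency_hz > 0 and (
            self.pwm_carrier_hz < 10.0 * self.temporal_frequency_hz
        ):
            raise DomainError("PWM carrier must be >= 10x the flicker rate")
        if self.waveform not in ("square", "sine"):
            raise DomainError("waveform must be 'square' or 'sine'")
        if not (0.0 < self.mean_factor <= 1.0):
            raise DomainError("mean_factor must lie in (0, 1]")
        if self.mean_factor * (1.0 + self.modulation_depth) > 1.0 + 1e-12:
            raise DomainError("mean_factor*(1+m) exceeds 1: factor would clip")


def kaiser_window(r, beta: float):
    """Radial Kaiser window weight ``I0(beta*sqrt(1-r^2)) / I0(beta)``.

    Parameters
    ----------
    r : array_like
        Normalized radius in [0, 1].
    beta : float
        Window shape parameter, >= 0.

    Returns
    -------
    ndarray or float
        Window weight in (0, 1]; 1 at r=0, ``1/I0(beta)`` at r=1.
    """
    r = np.asarray(r, dtype=float)
    if beta < 0:
        raise DomainError("beta must be >= 0")
    if np.any((r < 0) | (r > 1)):
        raise DomainError("normalized radius must lie in [0, 1]")
    # clamp one-ulp overshoot: mathematically I0(b*sqrt(1-r^2)) <= I0(b)
    out = np.minimum(i0(beta * np.sqrt(1.0 - r * r)) / i0(beta), 1.0)
    return out if out.ndim else float(out)


def render_mira(spec: MiraSpec) -> np.ndarray:
    """Render the normalized pattern on the full screen.

    Returns an ``(height_px, width_px)`` float array in [0, 1].  Pixels at
    normalized radius >= 1 are exactly 1/2 (the blend background); inside
    the disc the value is ``(window * sin(2*pi*y0/T) + 1) / 2`` with
    centered integer-pixel coordinates ``x0 = x - w/2``, ``y0 = y - h/2``
    and normalized radius ``2*sqrt(x0^2+y0^2)/d``.
    """
    w, h, d = spec.width_px, spec.height_px, spec.diameter_px
    x0 = np.arange(w, dtype=float) - w / 2.0
    y0 = np.arange(h, dtype=float) - h / 2.0
    xx, yy = np.meshgrid(x0, y0)
    r = 2.0 * np.hypot(xx, yy) / d
    inside = r < 1.0
    img = np.full((h, w), 0.5)
    win = i0(spec.kaiser_beta * np.sqrt(1.0 - np.minimum(r[inside], 1.0) ** 2))
    win /= i0(spec.kaiser_beta)
    img[inside] = 0.5 * (win * np.sin(2.0 * np.pi * yy[inside] / spec.period_px) + 1.0)
    return img


def quantize_to_display(
    image01: np.ndarray, level: int, amplitude: float
) -> np.ndarray:
    """Map a normalized [0, 1] image onto the 8-bit display range.

    ``pixel = round(level + amplitude * (2*image01 - 1))``; the neutral
    value 1/2 maps to exactly ``level``.  Raises :class:`ClippingError`
    when the mapping could leave [0, 255].
    """
    if level - amplitude < 0 or level + amplitude > 255:
        raise ClippingError(
            f"level {level} +/- amplitude {amplitude} clips the 8-bit range"
        )
    image01 = np.asarray(image01, dtype=float)
    if np.any((image01 < 0) | (image01 > 1)):
        raise DomainError("normalized image values must lie in [0, 1]")
    return np.rint(level + amplitude * (2.0 * image01 - 1.0)).astype(np.uint8)


def _kaiser_transform(x, beta: float):
    """Fourier kernel sinh(sqrt(beta^2-x^2))/sqrt(beta^2-x^2), continued
    as sin(sqrt(x^2-beta^2))/sqrt(x^2-beta^2) outside the main lobe."""
    x = np.asarray(x, dtype=float)
    s = beta * beta - x * x
    out = np.empty_like(s)
    pos = s > 0
    neg = s < 0
    out[pos] = np.sinh(np.sqrt(s[pos])) / np.sqrt(s[pos])
    out[neg] = np.sinc(np.sqrt(-s[neg]) / np.pi)
    out[~pos & ~neg] = 1.0
    return out


def mira_spectrum(k, spec: MiraSpec):
    """Analytic amplitude spectrum of the windowed grating, peak-normalized.

    Parameters
    ----------
    k : array_like
        Spatial frequency in cycles/pixel (along the grating axis).
    spec : MiraSpec
        Pattern parameters; only diameter, beta and period enter.

    Returns
    -------
    ndarray or float
        ``W(k - 1/T) / W(0)`` where W is the Kaiser-window transform of a
        window with full width ``diameter_px``.  Symmetric about the
        grating carrier ``1/T`` and maximal there.
    """
    k = np.asarray(k, dtype=float)
    beta, d, T = spec.kaiser_beta, spec.diameter_px, spec.period_px
    x = np.pi * d * (k - 1.0 / T)
    peak = np.sinh(beta) / beta if beta > 0 else 1.0
    out = _kaiser_transform(x, beta) / peak
    return out if out.ndim else float(out)


def flicker_waveform(fspec: FlickerSpec, t):
    """Multiplicative brightness factor at time ``t`` (seconds).

    Square mode alternates between ``mean*(1+m)`` and ``mean*(1-m)`` each
    half period; sine mode returns ``mean*(1 + m*sin(2*pi*f*t))``.  Both
    time-average to ``mean_factor`` over a full period.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise DomainError("time must be >= 0")
    f, m, mean = fspec.temporal_frequency_hz, fspec.modulation_depth, fspec.mean_factor
    if m == 0.0 or f == 0.0:
        out = np.full_like(t, mean)
        return out if out.ndim else float(out)
    if fspec.waveform == "square":
        phase = np.mod(t * f, 1.0)
        out = np.where(phase < 0.5, mean * (1.0 + m), mean * (1.0 - m))
    else:
        out = mean * (1.0 + m * np.sin(2.0 * np.pi * f * t))
    return out if out.ndim else float(out)
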