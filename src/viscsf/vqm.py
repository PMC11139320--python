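"""CSF-weighted PSNR video quality metric and score/MOS correlation.

Per frame, the reference-minus-distorted error image is filtered in the
Fourier domain by a weight field derived from a CSF surface (sensitivity at
each DFT bin's radial cycles/degree, at the frame's temporal frequency and
the display operating point, peak-normalized to 1), and the weighted MSE
feeds a standard PSNR.  Metric outputs map to subjective scores through a
four-parameter logistic, and agreement is reported as the Pearson
correlation with Fisher-z confidence bounds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import pearsonr

from .csf_models import evaluate_csf
from .display import DisplayModel, luminance_to_pixel, pixels_per_degree
from .errors import DataError, DegenerateFitError, DomainError

__all__ = [
    "VideoPair",
    "LogisticMapping",
    "PSNR_CAP_DB",
    "csf_weight_field",
    "estimate_temporal_frequencies",
    "weighted_psnr",
    "convert_contrast_units",
    "fit_logistic_mapping",
    "plcc_with_bounds",
]

#: score assigned to (numerically) identical frames
PSNR_CAP_DB = 100.0


@dataclass
class VideoPair:
    """Aligned reference/distorted luma sequences plus display metadata."""

    reference: np.ndarray  # (T, H, W), 8-bit range
    distorted: np.ndarray
    fps: float
    display: DisplayModel = field(default_factory=DisplayModel)
    operating_luminance: float = 120.0

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.distorted = np.asarray(self.distorted, dtype=float)
        if self.reference.ndim == 2:
            self.reference = self.reference[None]
        if self.distorted.ndim == 2:
            self.distorted = self.distorted[None]
        if self.reference.shape != self.distorted.shape:
            raise DataError(
                f"frame mismatch: reference {self.reference.shape} vs "
                f"distorted {self.distorted.shape}"
            )
        if self.reference.ndim != 3 or self.reference.shape[0] == 0:
            raise DataError("need a (frames, height, width) stack")
        if self.fps <= 0:
            raise DomainError("fps must be > 0")


def _operating_level(model, display: DisplayModel, operating_luminance: float):
    """Third model input at the operating point: nearest 8-bit level for
    brightness-domain surfaces, the luminance itself otherwise."""
    if getattr(model, "domain", "brightness") == "luminance":
        return operating_luminance
    return float(np.clip(np.rint(luminance_to_pixel(operating_luminance, display)), 0, 255))


def csf_weight_field(
    model,
    shape: tuple[int, int],
    display: DisplayModel,
    temporal_frequency: float = 0.0,
    operating_luminance: float = 120.0,
) -> np.ndarray:
    """Perceptual weights on the 2-D DFT grid of a frame.

    Each bin's radial frequency (cycles/degree through the display
    geometry) is looked up in the CSF at the given temporal frequency and
    the display operating point; weights are normalized to peak 1 and the
    DC bin is forced to 1 (mean luminance errors are not attenuated).
    """
    h, w = shape
    ppd = pixels_per_degree(display)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radial_cpd = np.hypot(fy, fx) * ppd
    level = _operating_level(model, display, operating_luminance)
    k_cap = getattr(model, "k_max", None)
    if k_cap is not None:
        radial_cpd = np.minimum(radial_cpd, k_cap)
    f_cap = getattr(model, "f_max", None)
    f_eval = temporal_frequency if f_cap is None else min(temporal_frequency, f_cap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sens = evaluate_csf(model, radial_cpd, f_eval, level).sensitivity
    weights = np.asarray(sens, dtype=float)
    weights = weights / weights.max()
    weights[0, 0] = 1.0
    return weights


def estimate_temporal_frequencies(
    frames: np.ndarray, fps: float, gain: float = 1.0
) -> np.ndarray:
    """Per-frame temporal coefficient from inter-frame change.

    Frame t maps to ``fps * gain * mean|frame_t - frame_{t-1}| / 255``;
    frame 0 gets 0 Hz.  Deliberately simple — monotone in flicker/motion
    energy — and isolated here so a different estimator can be swapped in.
    """
    frames = np.asarray(frames, dtype=float)
    out = np.zeros(frames.shape[0])
    if frames.shape[0] > 1:
        diff = np.abs(np.diff(frames, axis=0)).mean(axis=(1, 2))
        out[1:] = fps * gain * diff / 255.0
    return out


def _frame_wpsnr(err: np.ndarray, weights: np.ndarray | None) -> float:
    if weights is None:
        filtered = err
    else:
        filtered = np.fft.ifft2(np.fft.fft2(err) * weights).real
    wmse = float(np.mean(filtered**2))
    if wmse <= 255.0**2 * 10.0 ** (-PSNR_CAP_DB / 10.0):
        return PSNR_CAP_DB
    return 10.0 * np.log10(255.0**2 / wmse)


def weighted_psnr(
    pair: VideoPair,
    model=None,
    temporal_frequency: float | None = None,
    temporal_gain: float = 1.0,
) -> tuple[np.ndarray, float]:
    """CSF-weighted PSNR per frame plus the sequence mean.

    With ``model=None`` this is plain PSNR.  The temporal coefficient is
    either fixed (``temporal_frequency``) or estimated per frame from the
    reference sequence; identical frames score :data:`PSNR_CAP_DB`.
    """
    n, h, w = pair.reference.shape
    if temporal_frequency is not None:
        freqs = np.full(n, float(temporal_frequency))
    else:
        freqs = estimate_temporal_frequencies(pair.reference, pair.fps, temporal_gain)
    scores = np.empty(n)
    cache: dict[float, np.ndarray] = {}
    for t in range(n):
        weights = None
        if model is not None:
            key = round(float(freqs[t]), 6)
            if key not in cache:
                cache[key] = csf_weight_field(
                    model, (h, w), pair.display, key, pair.operating_luminance
                )
            weights = cache[key]
        scores[t] = _frame_wpsnr(pair.reference[t] - pair.distorted[t], weights)
    return scores, float(scores.mean())


def convert_contrast_units(sensitivity_weber):
    """Weber-scale sensitivity to log (base-10) scale."""
    s = np.asarray(sensitivity_weber, dtype=float)
    if np.any(s <= 0):
        raise DomainError("sensitivity must be > 0")
    out = np.log10(s)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class LogisticMapping:
    """Four-parameter logistic from metric scores to subjective scores."""

    lower: float
    upper: float
    slope: float
    midpoint: float

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        out = self.lower + (self.upper - self.lower) / (
            1.0 + np.exp(-self.slope * (x - self.midpoint))
        )
        return out if out.ndim else float(out)


def _logistic(x, lower, upper, slope, midpoint):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (x - midpoint)))


def fit_logistic_mapping(scores, mos) -> LogisticMapping:
    """Least-squares fit of the 4-parameter logistic, VQEG style.

    The initializer is data driven (asymptotes from the MOS range, midpoint
    at the median score) so the fit is deterministic.
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(mos, dtype=float)
    if x.size != y.size or x.size < 5:
        raise DataError("need >= 5 paired points")
    if np.ptp(y) == 0:
        raise DegenerateFitError("subjective scores are constant; mapping undefined")
    span = np.ptp(x) if np.ptp(x) > 0 else 1.0
    sign = 1.0 if np.corrcoef(x, y)[0, 1] >= 0 else -1.0
    p0 = [y.min(), y.max(), sign * 4.0 / span, float(np.median(x))]
    params, _ = curve_fit(_logistic, x, y, p0=p0, maxfev=20000)
    lower, upper, slope, midpoint = (float(v) for v in params)
    if upper < lower:
        # (lo, up, s) and (up, lo, -s) describe the same curve; pick the
        # representation with upper > lower
        lower, upper, slope = upper, lower, -slope
    if upper == lower:
        raise DegenerateFitError("degenerate logistic: asymptotes coincide")
    return LogisticMapping(lower, upper, slope, midpoint)


def plcc_with_bounds(x, y, confidence: float = 0.95) -> tuple[float, float, float]:
    """Pearson correlation with Fisher-z confidence bounds.

    Returns (plcc, lower, upper); bounds use the normal approximation with
    standard error ``1/sqrt(n-3)`` on the z scale.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise DataError("need >= 4 paired points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DataError("inputs must be non-constant")
    r = float(pearsonr(x, y).statistic)
    from scipy.stats import norm

    zcrit = float(norm.ppf(0.5 + confidence / 2.0))
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    half = zcrit / np.sqrt(x.size - 3)
    return r, float(np.tanh(z - half)), float(np.tanh(z + half))
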