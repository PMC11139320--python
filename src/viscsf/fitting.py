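"""From threshold tables to fitted CSF surfaces.

Covers the housekeeping around the regression: exclusion filtering of
equipment-artefact conditions, per-condition aggregation, the BT.500-style
confidence-interval statistics used as a sequential stopping rule, the
ridge-regression polynomial fit with an unpenalized intercept, and the
log-linear slope analysis of uniform-field flicker data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .csf_models import PolynomialCSF, n_terms, normalize_inputs, polynomial_terms
from .errors import DataError, DomainError, RankDeficiencyError

__all__ = [
    "THRESHOLD_COLUMNS",
    "DEFAULT_EXCLUSIONS",
    "ThresholdRecord",
    "RidgeConfig",
    "read_thresholds",
    "write_thresholds",
    "records_to_frame",
    "apply_exclusions",
    "bt500_ci",
    "should_stop",
    "aggregate_conditions",
    "ridge_fit",
    "fit_log_linear_slope",
]

#: CSV schema for threshold tables (header required, '.' decimal, UTF-8)
THRESHOLD_COLUMNS = [
    "participant_id",
    "stage",
    "spatial_freq_cpd",
    "temporal_freq_hz",
    "background_level",
    "threshold_contrast",
    "replicate_index",
]

#: (temporal frequency Hz, background level) pairs excluded as equipment
#: artefacts; user-overridable.
DEFAULT_EXCLUSIONS: list[tuple[float, int]] = [
    (15.0, 200),
    (40.0, 200),
    (36.0, 160),
    (13.0, 80),
    (20.0, 80),
    (48.0, 80),
    (40.0, 40),
    (46.0, 40),
]


@dataclass(frozen=True)
class ThresholdRecord:
    """One measured (or simulated) contrast threshold.

    ``threshold_contrast`` is Weber-style on pixel values: modulation
    amplitude divided by background level, on the linear 8-bit scale.
    Sensitivity is its reciprocal.
    """

    participant_id: str
    spatial_frequency: float
    temporal_frequency: float
    background_level: int
    threshold_contrast: float
    stage: str = "pattern"
    replicate_index: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_contrast <= 1.0):
            raise DomainError("threshold_contrast must lie in (0, 1]")
        if self.spatial_frequency < 0 or self.temporal_frequency < 0:
            raise DomainError("frequencies must be >= 0")
        if self.stage not in ("flicker", "pattern"):
            raise DomainError("stage must be 'flicker' or 'pattern'")


@dataclass(frozen=True)
class RidgeConfig:
    """Ridge-regression settings; the intercept is never penalized."""

    lam: float = 0.001
    order: int = 4

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise DomainError("lambda must be >= 0")


def records_to_frame(records) -> pd.DataFrame:
    """Convert an iterable of :class:`ThresholdRecord` to the CSV-schema frame."""
    return pd.DataFrame(
        [
            {
                "participant_id": r.participant_id,
                "stage": r.stage,
                "spatial_freq_cpd": r.spatial_frequency,
                "temporal_freq_hz": r.temporal_frequency,
                "background_level": r.background_level,
                "threshold_contrast": r.threshold_contrast,
                "replicate_index": r.replicate_index,
            }
            for r in records
        ],
        columns=THRESHOLD_COLUMNS,
    )


def read_thresholds(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in THRESHOLD_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"threshold CSV missing columns: {missing}")
    if len(df) and not ((df["threshold_contrast"] > 0) & (df["threshold_contrast"] <= 1)).all():
        raise DataError("threshold_contrast values must lie in (0, 1]")
    return df[THRESHOLD_COLUMNS]


def write_thresholds(df: pd.DataFrame, path) -> None:
    df[THRESHOLD_COLUMNS].to_csv(path, index=False)


def apply_exclusions(
    df: pd.DataFrame, exclusions=DEFAULT_EXCLUSIONS, atol: float = 1e-9
) -> tuple[pd.DataFrame, int]:
    """Drop every record whose (temporal frequency, background level) matches
    an exclusion pair; returns (filtered frame, number removed)."""
    if not exclusions:
        return df, 0
    mask = np.zeros(len(df), dtype=bool)
    f = df["temporal_freq_hz"].to_numpy(dtype=float)
    l = df["background_level"].to_numpy(dtype=float)
    for ef, el in exclusions:
        mask |= np.isclose(f, ef, rtol=0.0, atol=atol) & (l == el)
    return df.loc[~mask].reset_index(drop=True), int(mask.sum())


def bt500_ci(samples) -> tuple[float, float, float]:
    """Mean, sample standard deviation and 95% confidence half-width
    ``1.96 * sd / sqrt(n)`` of a set of threshold measurements."""
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise DataError("confidence interval undefined for fewer than 2 samples")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    return mean, sd, 1.96 * sd / np.sqrt(x.size)


def should_stop(samples, fraction: float = 0.05) -> bool:
    """Sequential stopping rule: stop once the 95% confidence half-width
    falls below ``fraction`` of the current mean.  Each stimulus condition
    is checked independently of every other."""
    mean, _, halfwidth = bt500_ci(samples)
    return halfwidth < fraction * mean


def aggregate_conditions(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse records to one row per (k, f, l) condition.

    Thresholds are averaged across participants/replicates first, then the
    log10 of the averaged sensitivity is taken (average-then-log)."""
    if df.empty:
        raise DataError("no records to aggregate")
    grouped = (
        df.groupby(
            ["spatial_freq_cpd", "temporal_freq_hz", "background_level"],
            as_index=False,
        )
        .agg(mean_threshold=("threshold_contrast", "mean"), n=("threshold_contrast", "size"))
        .sort_values(["spatial_freq_cpd", "temporal_freq_hz", "background_level"])
        .reset_index(drop=True)
    )
    grouped["log10_mean_sensitivity"] = np.log10(1.0 / grouped["mean_threshold"])
    return grouped


def _design_matrix(conditions: pd.DataFrame, template: PolynomialCSF) -> np.ndarray:
    kp, fp, lp = normalize_inputs(
        conditions["spatial_freq_cpd"].to_numpy(),
        conditions["temporal_freq_hz"].to_numpy(),
        conditions["background_level"].to_numpy(),
        template,
    )
    return polynomial_terms(kp, fp, lp, template.order)


def ridge_fit(
    conditions: pd.DataFrame,
    cfg: RidgeConfig = RidgeConfig(),
    template: PolynomialCSF | None = None,
) -> PolynomialCSF:
    """Fit the polynomial surface by ridge regression.

    Solves ``(X'X + lam*I') c = X'y`` where I' is the identity with its
    constant-term entry zeroed, so the intercept is unpenalized.  With
    ``lam=0`` a rank-deficient system raises :class:`RankDeficiencyError`
    rather than returning one of infinitely many solutions.
    """
    if template is None:
        template = PolynomialCSF(order=cfg.order)
    if template.order != cfg.order:
        raise DataError("template order disagrees with ridge config")
    X = _design_matrix(conditions, template)
    y = conditions["log10_mean_sensitivity"].to_numpy(dtype=float)
    m = n_terms(cfg.order)
    if cfg.lam == 0.0:
        rank = np.linalg.matrix_rank(X)
        if rank < m:
            raise RankDeficiencyError(
                f"unregularized fit needs rank {m}, data give rank {rank} "
                f"({len(conditions)} conditions); add conditions or set lambda > 0"
            )
    penalty = np.eye(m)
    penalty[0, 0] = 0.0
    coeffs = np.linalg.solve(X.T @ X + cfg.lam * penalty, X.T @ y)
    return PolynomialCSF(
        order=cfg.order,
        coefficients=coeffs,
        k_max=template.k_max,
        f_max=template.f_max,
        l_max=template.l_max,
    )


def fit_log_linear_slope(
    df: pd.DataFrame,
    background_level: int,
    frequency_range: tuple[float, float],
) -> tuple[float, float]:
    """OLS of log10 sensitivity on temporal frequency for uniform-field
    (k = 0) records at one background level, restricted to the given
    frequency range.  Returns (slope per Hz, intercept).

    The range is an explicit argument because the log-linear description
    only holds over a limited band that shifts with background level.
    """
    lo, hi = frequency_range
    sub = df[
        (df["spatial_freq_cpd"] == 0)
        & (df["background_level"] == background_level)
        & (df["temporal_freq_hz"] >= lo)
        & (df["temporal_freq_hz"] <= hi)
    ]
    if sub["temporal_freq_hz"].nunique() < 2:
        raise DataError("need >= 2 distinct frequencies inside the range")
    f = sub["temporal_freq_hz"].to_numpy(dtype=float)
    log_s = np.log10(1.0 / sub["threshold_contrast"].to_numpy(dtype=float))
    slope, intercept = np.polyfit(f, log_s, 1)
    return float(slope), float(intercept)
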