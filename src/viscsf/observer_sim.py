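"""Synthetic-observer engine for the two threshold experiments.

Reproduces the factorial experiment designs (uniform-field flicker and
spatio-temporal pattern detection) and generates threshold tables from a
ground-truth CSF with lognormal within-observer scatter plus a fixed
per-observer offset, so the full fit pipeline is testable without any
measured data.

Randomness: one master seed is expanded through ``numpy.random.SeedSequence``
spawning, one child stream per participant, so any participant subset is
reproducible independently of the others.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .csf_models import evaluate_csf
from .display import DisplayModel, pixel_to_luminance
from .errors import DataError, DomainError
from .fitting import THRESHOLD_COLUMNS, should_stop

__all__ = [
    "ExperimentDesign",
    "ObserverModel",
    "build_design",
    "simulate_threshold",
    "simulate_session",
]

DEFAULT_LEVELS = (40, 80, 120, 160, 200)


def _log_spaced(lo: float, hi: float, n: int) -> tuple[float, ...]:
    return tuple(np.geomspace(lo, hi, n))


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial design of one threshold experiment.

    Experiment 1: uniform-field flicker only — no spatial frequencies, one
    adjustment stage.  Experiment 2: windowed gratings — spatial x temporal
    x level factorial with two adjustment stages (flicker first, then
    pattern) per condition.
    """

    temporal_frequencies: tuple[float, ...]
    spatial_frequencies: tuple[float, ...]
    background_levels: tuple[int, ...]
    n_participants: int
    stages: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise DomainError("need at least one participant")
        if not self.temporal_frequencies or not self.background_levels:
            raise DomainError("design lists must be populated")
        if any(not (0 <= l <= 255) for l in self.background_levels):
            raise DomainError("background levels must lie in [0, 255]")
        if not self.stages:
            raise DomainError("need at least one adjustment stage")

    @classmethod
    def experiment(cls, number: int) -> "ExperimentDesign":
        """Default design for experiment 1 or 2.

        Frequency grids are log-spaced within the design extremes
        (temporal 1-66.6 Hz, spatial 0.5-15 cpd); cardinalities, levels,
        cohort sizes and stage counts follow the protocols.
        """
        if number == 1:
            return cls(
                temporal_frequencies=_log_spaced(1.0, 66.6, 12),
                spatial_frequencies=(),
                background_levels=DEFAULT_LEVELS,
                n_participants=13,
                stages=("flicker",),
            )
        if number == 2:
            return cls(
                temporal_frequencies=_log_spaced(1.0, 66.6, 12),
                spatial_frequencies=_log_spaced(0.5, 15.0, 8),
                background_levels=DEFAULT_LEVELS,
                n_participants=29,
                stages=("flicker", "pattern"),
            )
        raise DomainError("experiment must be 1 or 2")

    @property
    def conditions_per_participant(self) -> int:
        n_spatial = max(len(self.spatial_frequencies), 1)
        return n_spatial * len(self.temporal_frequencies) * len(self.background_levels)

    @property
    def rows_per_participant(self) -> int:
        return self.conditions_per_participant * len(self.stages)


@dataclass(frozen=True)
class ObserverModel:
    """Ground-truth CSF plus the observer noise model.

    A simulated threshold is ``(1/s_true) * 10**(eps + b)`` with per-trial
    ``eps ~ Normal(0, log10_noise_sd)`` and a per-observer offset ``b``
    drawn once per participant with sd ``observer_bias_sd``; results are
    clipped into (0, 1].  ``display`` converts background brightness to
    luminance when the truth surface is luminance-indexed.
    """

    true_csf: object
    log10_noise_sd: float = 0.05
    observer_bias_sd: float = 0.0
    display: DisplayModel = field(default_factory=DisplayModel)

    def __post_init__(self) -> None:
        if self.log10_noise_sd < 0 or self.observer_bias_sd < 0:
            raise DomainError("noise standard deviations must be >= 0")

    def true_threshold(self, k, f, l):
        lum = (
            pixel_to_luminance(l, self.display)
            if getattr(self.true_csf, "domain", "brightness") == "luminance"
            else l
        )
        return evaluate_csf(self.true_csf, k, f, lum).contrast_threshold


def build_design(design: ExperimentDesign | int) -> pd.DataFrame:
    """Expand a design into its full per-participant condition table.

    One row per (participant, stage, spatial frequency, temporal frequency,
    background level); uniform-field designs carry spatial frequency 0.
    """
    if isinstance(design, int):
        design = ExperimentDesign.experiment(design)
    spatial = design.spatial_frequencies or (0.0,)
    rows = []
    for p in range(design.n_participants):
        pid = f"P{p + 1:02d}"
        for k in spatial:
            for f in design.temporal_frequencies:
                for l in design.background_levels:
                    for stage in design.stages:
                        rows.append((pid, stage, k, f, l))
    return pd.DataFrame(
        rows,
        columns=[
            "participant_id",
            "stage",
            "spatial_freq_cpd",
            "temporal_freq_hz",
            "background_level",
        ],
    )


def _clip_threshold(t: np.ndarray) -> np.ndarray:
    return np.clip(t, np.finfo(float).tiny, 1.0)


def simulate_threshold(obs: ObserverModel, k, f, l, rng, bias: float = 0.0):
    """Draw one threshold for condition (k, f, l); deterministic given rng."""
    base = obs.true_threshold(k, f, l)
    eps = rng.normal(0.0, obs.log10_noise_sd) if obs.log10_noise_sd > 0 else 0.0
    return float(_clip_threshold(np.asarray(base * 10.0 ** (eps + bias))))


def simulate_session(
    obs: ObserverModel,
    design: ExperimentDesign | int,
    seed: int,
    stopping: bool = False,
    max_replicates: int = 8,
) -> pd.DataFrame:
    """Simulate the full experiment and return a threshold table.

    With ``stopping`` off, exactly one record per design row.  With it on,
    replicates accrue per (participant, stage, condition) until the
    confidence-interval rule passes or ``max_replicates`` is reached.
    """
    if isinstance(design, int):
        design = ExperimentDesign.experiment(design)
    if stopping and max_replicates < 2:
        raise DataError("stopping rule needs max_replicates >= 2")
    streams = np.random.SeedSequence(seed).spawn(design.n_participants)
    spatial = design.spatial_frequencies or (0.0,)
    conditions = [
        (k, f, l)
        for k in spatial
        for f in design.temporal_frequencies
        for l in design.background_levels
    ]
    true_thr = {c: obs.true_threshold(*c) for c in conditions}
    records: list[tuple] = []
    for p, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pid = f"P{p + 1:02d}"
        bias = rng.normal(0.0, obs.observer_bias_sd) if obs.observer_bias_sd > 0 else 0.0
        for k, f, l in conditions:
            base = true_thr[(k, f, l)]
            for stage in design.stages:
                n_draw = max_replicates if stopping else 1
                eps = rng.normal(0.0, obs.log10_noise_sd, size=n_draw)
                draws = _clip_threshold(base * 10.0 ** (eps + bias))
                if stopping:
                    kept = 2
                    while kept < n_draw and not should_stop(draws[:kept]):
                        kept += 1
                    draws = draws[:kept]
                for i, thr in enumerate(draws):
                    records.append((pid, stage, k, f, l, float(thr), i))
    return pd.DataFrame(records, columns=THRESHOLD_COLUMNS)
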