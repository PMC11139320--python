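"""Contrast-sensitivity surfaces behind a single pluggable interface.

Two concrete surfaces are provided:

* :class:`PolynomialCSF` — complete polynomial of configurable order in
  normalized (spatial frequency, temporal frequency, background brightness),
  returning log10 sensitivity.  Indexed by 8-bit background brightness.
* :class:`PyramidCSF` — the linear "pyramid of visibility" baseline:
  log10 sensitivity affine in spatial frequency, temporal frequency and
  log10 luminance.  Indexed by luminance in cd/m^2.

All log-sensitivity values are base 10.  Models serialize to/from a small
self-describing JSON schema so externally fitted surfaces can be plugged in.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

from .errors import DataError, DomainError

__all__ = [
    "CSFResponse",
    "PolynomialCSF",
    "PyramidCSF",
    "exponent_triples",
    "n_terms",
    "normalize_inputs",
    "polynomial_terms",
    "evaluate_csf",
    "load_model",
    "save_model",
    "model_from_dict",
]


class CSFResponse(NamedTuple):
    log10_sensitivity: float
    sensitivity: float
    contrast_threshold: float


def exponent_triples(order: int) -> list[tuple[int, int, int]]:
    """All (alpha, gamma, delta) with alpha+gamma+delta <= order, in graded
    lexicographic order (total degree first, then lexicographic).  The first
    triple is always (0, 0, 0), the constant term."""
    if order < 0:
        raise DomainError("order must be >= 0")
    triples = []
    for total in range(order + 1):
        grade = [
            (a, g, total - a - g)
            for a in range(total + 1)
            for g in range(total - a + 1)
        ]
        triples.extend(sorted(grade))
    return triples


def n_terms(order: int) -> int:
    """Size of the complete 3-variable basis: C(order+3, 3)."""
    return math.comb(order + 3, 3)


@dataclass
class PolynomialCSF:
    """Complete polynomial surface on normalized inputs.

    ``coefficients`` is aligned with :func:`exponent_triples`\\ (order); the
    normalizers map physical inputs onto [0, 1].
    """

    order: int = 4
    coefficients: np.ndarray | None = None
    k_max: float = 15.0
    f_max: float = 66.6
    l_max: float = 200.0

    domain = "brightness"

    def __post_init__(self) -> None:
        if self.order < 0:
            raise DomainError("order must be >= 0")
        if min(self.k_max, self.f_max, self.l_max) <= 0:
            raise DomainError("normalizers must be strictly positive")
        m = n_terms(self.order)
        if self.coefficients is None:
            self.coefficients = np.zeros(m)
        else:
            self.coefficients = np.asarray(self.coefficients, dtype=float)
            if self.coefficients.shape != (m,):
                raise DataError(
                    f"order {self.order} needs {m} coefficients, "
                    f"got {self.coefficients.shape}"
                )

    @property
    def triples(self) -> list[tuple[int, int, int]]:
        return exponent_triples(self.order)

    def log10_sensitivity(self, k, f, l):
        kp, fp, lp = normalize_inputs(k, f, l, self)
        basis = polynomial_terms(kp, fp, lp, self.order)
        return basis @ self.coefficients

    def to_dict(self) -> dict:
        return {
            "type": "polynomial",
            "order": self.order,
            "normalizers": {
                "k_max": self.k_max,
                "f_max": self.f_max,
                "l_max": self.l_max,
            },
            "coefficients": [
                {"alpha": a, "gamma": g, "delta": d, "c": float(c)}
                for (a, g, d), c in zip(self.triples, self.coefficients)
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PolynomialCSF":
        order = int(data["order"])
        norm = data.get("normalizers", {})
        model = cls(
            order=order,
            k_max=float(norm.get("k_max", 15.0)),
            f_max=float(norm.get("f_max", 66.6)),
            l_max=float(norm.get("l_max", 200.0)),
        )
        index = {t: i for i, t in enumerate(model.triples)}
        seen = set()
        for entry in data.get("coefficients", []):
            key = (int(entry["alpha"]), int(entry["gamma"]), int(entry["delta"]))
            if key not in index:
                raise DataError(f"exponent triple {key} exceeds order {order}")
            if key in seen:
                raise DataError(f"duplicate exponent triple {key}")
            seen.add(key)
            model.coefficients[index[key]] = float(entry["c"])
        return model


@dataclass
class PyramidCSF:
    """Affine log10-sensitivity baseline in (k, f, log10 L)."""

    c0: float
    c_f: float
    c_k: float
    c_L: float

    domain = "luminance"

    def __post_init__(self) -> None:
        if self.c_f > 0 or self.c_k > 0:
            warnings.warn(
                "pyramid slopes c_f/c_k are expected to be non-positive",
                stacklevel=3,
            )

    def log10_sensitivity(self, k, f, L):
        k = np.asarray(k, dtype=float)
        f = np.asarray(f, dtype=float)
        L = np.asarray(L, dtype=float)
        if np.any(L <= 0):
            raise DomainError("luminance must be > 0 for the pyramid surface")
        out = self.c0 + self.c_k * k + self.c_f * f + self.c_L * np.log10(L)
        return out if np.ndim(out) else float(out)

    def to_dict(self) -> dict:
        return {
            "type": "pyramid",
            "c0": self.c0,
            "c_f": self.c_f,
            "c_k": self.c_k,
            "c_L": self.c_L,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "PyramidCSF":
        return cls(
            c0=float(data["c0"]),
            c_f=float(data["c_f"]),
            c_k=float(data["c_k"]),
            c_L=float(data["c_L"]),
        )


def normalize_inputs(k, f, l, model: PolynomialCSF):
    """Map physical (cpd, Hz, 8-bit brightness) onto the unit cube.

    Negative inputs are a domain error; inputs above their normalizer are
    clamped to 1 with a warning (extrapolating the polynomial beyond its
    fitted range is not meaningful).
    """
    k = np.asarray(k, dtype=float)
    f = np.asarray(f, dtype=float)
    l = np.asarray(l, dtype=float)
    if np.any(k < 0) or np.any(f < 0) or np.any(l < 0):
        raise DomainError("frequencies and brightness must be >= 0")
    if np.any(k > model.k_max) or np.any(f > model.f_max) or np.any(l > model.l_max):
        warnings.warn("input above model normalizer; clamping to 1", stacklevel=3)
    kp = np.minimum(k / model.k_max, 1.0)
    fp = np.minimum(f / model.f_max, 1.0)
    lp = np.minimum(l / model.l_max, 1.0)
    return kp, fp, lp


def polynomial_terms(kp, fp, lp, order: int) -> np.ndarray:
    """Basis vector(s) ``kp**alpha * fp**gamma * lp**delta`` over the graded
    lexicographic triples.  Scalar inputs give shape (n_terms,), array inputs
    append the basis axis last."""
    kp = np.asarray(kp, dtype=float)
    fp = np.asarray(fp, dtype=float)
    lp = np.asarray(lp, dtype=float)
    triples = exponent_triples(order)
    cols = [kp**a * fp**g * lp**d for a, g, d in triples]
    return np.stack(cols, axis=-1)


def evaluate_csf(model, k, f, l) -> CSFResponse:
    """Evaluate any CSF surface; returns log10 sensitivity, sensitivity and
    the contrast threshold (1/sensitivity).

    For a brightness-domain model ``l`` is 8-bit background brightness; for
    a luminance-domain model it is luminance in cd/m^2.
    """
    log10_s = model.log10_sensitivity(k, f, l)
    s = 10.0**log10_s
    if np.ndim(log10_s):
        return CSFResponse(log10_s, s, 1.0 / s)
    return CSFResponse(float(log10_s), float(s), float(1.0 / s))


_MODEL_TYPES = {"polynomial": PolynomialCSF, "pyramid": PyramidCSF}


def model_from_dict(data: dict):
    kind = data.get("type")
    if kind not in _MODEL_TYPES:
        raise DataError(f"unknown model type {kind!r}")
    return _MODEL_TYPES[kind].from_dict(data)


def load_model(path):
    """Read a CSF model from its JSON serialization."""
    with open(path) as fh:
        return model_from_dict(json.load(fh))


def save_model(model, path) -> None:
    """Write a CSF model to JSON (stable key order)."""
    with open(path, "w") as fh:
        json.dump(model.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
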