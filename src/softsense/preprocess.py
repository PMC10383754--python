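"""Savitzky-Golay filtering and SNV normalisation for Raman spectra.

Two preprocessing steps are applied per spectrum before calibration:

1. Savitzky-Golay: a local least-squares polynomial fit over a moving window
   of ``2k + 1`` channels, used for smoothing or for first/second derivatives.
   ``savgol_coefficients`` derives the convolution weights by *exact rational
   arithmetic*, so the classic printed integer tables (e.g. -3, 12, 17, 12, -3
   for a 5-point quadratic smooth) are reproduced bit-exactly.
2. SNV (standard normal variate): per-spectrum centring and scaling to zero
   mean and unit *population* standard deviation (divisor N), which removes
   multiplicative gain and additive offset differences between spectra.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import factorial, gcd

import numpy as np
from scipy.signal import savgol_filter

from .io import SpectraSet

__all__ = [
    "SavGolSpec",
    "DegenerateSpectrumError",
    "savgol_coefficients",
    "savgol_apply",
    "snv",
    "preprocess_pipeline",
]

_TARGET_DERIV = {"smooth": 0, "d1": 1, "d2": 2}


class DegenerateSpectrumError(ValueError):
    """Raised for inputs on which a preprocessing step is undefined (e.g. SNV of a constant)."""


@dataclass(frozen=True)
class SavGolSpec:
    """Savitzky-Golay filter specification.

    ``half_window`` is k: the number of neighbouring channels on each side,
    i.e. window length = 2k + 1.  ``target`` selects smoothing or a
    derivative (unit channel spacing).
    """

    half_window: int = 7
    poly_order: int = 2
    target: str = "smooth"

    def __post_init__(self):
        if self.target not in _TARGET_DERIV:
            raise ValueError(f"target must be one of {sorted(_TARGET_DERIV)}")
        if self.half_window < 1:
            raise ValueError("half_window must be >= 1")
        if self.poly_order < 0 or self.poly_order > 2 * self.half_window:
            raise ValueError("need 0 <= poly_order <= 2*half_window")
        if _TARGET_DERIV[self.target] > self.poly_order:
            raise ValueError(f"target {self.target!r} requires poly_order >= "
                             f"{_TARGET_DERIV[self.target]}")

    @property
    def window_length(self) -> int:
        return 2 * self.half_window + 1

    @property
    def deriv(self) -> int:
        return _TARGET_DERIV[self.target]


def _solve_fraction(mat: list[list[Fraction]], rhs: list[Fraction]) -> list[Fraction]:
    """Exact Gaussian elimination with partial (nonzero) pivoting."""
    n = len(rhs)
    a = [row[:] + [rhs[i]] for i, row in enumerate(mat)]
    for col in range(n):
        piv = next(r for r in range(col, n) if a[r][col] != 0)
        a[col], a[piv] = a[piv], a[col]
        inv = Fraction(1) / a[col][col]
        a[col] = [v * inv for v in a[col]]
        for r in range(n):
            if r != col and a[r][col] != 0:
                f = a[r][col]
                a[r] = [v - f * w for v, w in zip(a[r], a[col])]
    return [a[r][n] for r in range(n)]


def savgol_coefficients(spec: SavGolSpec) -> tuple[tuple[int, ...], Fraction]:
    """Exact integer-proportional Savitzky-Golay convolution weights.

    Returns ``(c, N)`` with integer weights ``c = (c_-k, ..., c_k)`` in lowest
    terms and rational normalisation ``N`` such that ``(1/N) * sum c_h x_{j+h}``
    is the least-squares polynomial fit (or its ``target`` derivative, unit
    sample spacing) evaluated at the window centre.
    """
    k, p, d = spec.half_window, spec.poly_order, spec.deriv
    offsets = range(-k, k + 1)
    # normal-equations matrix M_ij = sum_h h^(i+j); rhs picks polynomial coef d
    m = [[Fraction(sum(h ** (i + j) for h in offsets)) for j in range(p + 1)]
         for i in range(p + 1)]
    weights = []
    for h in offsets:
        # weight on x_{j+h} of coefficient a_d: solve M z = A^T e_h, take z_d
        rhs = [Fraction(h ** i) for i in range(p + 1)]
        z = _solve_fraction(m, rhs)
        weights.append(z[d] * factorial(d))  # f^(d) at centre = d! * a_d

    denom_lcm = 1
    for w in weights:
        denom_lcm = denom_lcm * w.denominator // gcd(denom_lcm, w.denominator)
    ints = [int(w * denom_lcm) for w in weights]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    g = g or 1
    c = tuple(v // g for v in ints)
    n_norm = Fraction(denom_lcm, g)
    return c, n_norm


def savgol_apply(x, spec: SavGolSpec) -> np.ndarray:
    """Apply the Savitzky-Golay filter to one spectrum, preserving length.

    Interior points are the central-window convolution; edge points come from
    asymmetric least-squares fits over the available window (same polynomial
    order), so no channels are discarded.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("savgol_apply expects a 1-D spectrum")
    if x.size < spec.window_length:
        raise ValueError(f"spectrum length {x.size} shorter than window "
                         f"{spec.window_length}")
    return savgol_filter(x, spec.window_length, spec.poly_order,
                         deriv=spec.deriv, delta=1.0, mode="interp")


def snv(x) -> np.ndarray:
    """Standard normal variate: centre and scale one spectrum to mean 0, population std 1."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise DegenerateSpectrumError("SNV needs at least 2 channels")
    sigma = x.std()  # population std, divisor N
    if sigma == 0 or not np.isfinite(sigma):
        raise DegenerateSpectrumError("SNV undefined for a zero-variance spectrum")
    return (x - x.mean()) / sigma


def preprocess_pipeline(spectra: SpectraSet, spec: SavGolSpec | None = None,
                        do_snv: bool = True) -> SpectraSet:
    """Savitzky-Golay per spectrum, then SNV per spectrum; provenance recorded.

    The default specification matches common Raman practice: 15-sample window
    (k = 7), quadratic polynomial, smoothing target, followed by SNV.
    """
    if spec is None:
        spec = SavGolSpec()
    out = np.empty_like(spectra.intensities)
    for i, row in enumerate(spectra.intensities):
        filtered = savgol_apply(row, spec)
        out[i] = snv(filtered) if do_snv else filtered
    provenance = {
        "savgol": {"half_window": spec.half_window, "poly_order": spec.poly_order,
                   "target": spec.target},
        "snv": bool(do_snv),
    }
    return spectra.replace_intensities(out, provenance={"preprocess": provenance})
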