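"""Periodized orthogonal discrete wavelet transform.

A minimal multilevel DWT for beat-window feature extraction.  Only
orthonormal Daubechies filters are provided; the transform uses circular
(periodized) boundary handling on even-length inputs, which makes each
level an orthogonal map — so Parseval holds exactly: the sum of subband
energies equals the input energy to machine precision.  Odd-length inputs
are zero-padded (zero padding adds no energy).

This module exists because no discrete wavelet transform ships with the
scientific stack assumed here; it is deliberately small and is validated
against perfect-reconstruction and energy-conservation properties.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["daubechies_filter", "dwt_periodized", "idwt_periodized", "wavedec", "subband_energies"]

# Orthonormal Daubechies scaling (low-pass) filters, ascending index.
# db1 = Haar; dbN has 2N taps and N vanishing moments.
_DB_FILTERS: dict[str, list[float]] = {
    "db1": [0.7071067811865476, 0.7071067811865476],
    "db2": [
        0.48296291314469025, 0.836516303737469,
        0.22414386804185735, -0.12940952255092145,
    ],
    "db4": [
        0.23037781330885523, 0.7148465705525415,
        0.6308807679295904, -0.02798376941698385,
        -0.18703481171888114, 0.030841381835986965,
        0.032883011666982945, -0.010597401784997278,
    ],
}


def daubechies_filter(name: str) -> tuple[np.ndarray, np.ndarray]:
    """Return (low-pass, high-pass) decomposition filters for ``name``.

    The high-pass filter is the quadrature mirror: g[k] = (-1)^k h[L-1-k].
    """
    if name not in _DB_FILTERS:
        raise ValueError(f"unknown wavelet {name!r}; available: {sorted(_DB_FILTERS)}")
    lo = np.asarray(_DB_FILTERS[name], dtype=float)
    signs = (-1.0) ** np.arange(lo.size)
    hi = signs * lo[::-1]
    return lo, hi


def _even(x: np.ndarray) -> np.ndarray:
    if x.size % 2:
        return np.concatenate([x, [0.0]])
    return x


def dwt_periodized(x: np.ndarray, wavelet: str = "db4") -> tuple[np.ndarray, np.ndarray]:
    """One level of the periodized DWT; returns (approx, detail).

    For even-length input the map is orthogonal:
    ``a[i] = sum_k lo[k] x[(2i+k) mod N]`` and likewise for the detail.
    """
    lo, hi = daubechies_filter(wavelet)
    x = _even(np.asarray(x, dtype=float))
    n = x.size
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(lo.size)[None, :]) % n
    window = x[idx]
    return window @ lo, window @ hi


def idwt_periodized(approx: np.ndarray, detail: np.ndarray, wavelet: str = "db4") -> np.ndarray:
    """Invert one level of :func:`dwt_periodized` (transpose of the
    orthogonal analysis map)."""
    lo, hi = daubechies_filter(wavelet)
    approx = np.asarray(approx, dtype=float)
    detail = np.asarray(detail, dtype=float)
    n = 2 * approx.size
    x = np.zeros(n)
    for i in range(approx.size):
        pos = (2 * i + np.arange(lo.size)) % n
        np.add.at(x, pos, approx[i] * lo + detail[i] * hi)
    return x


def wavedec(x: np.ndarray, wavelet: str = "db4", levels: int = 4) -> list[np.ndarray]:
    """Multilevel decomposition: ``[a_L, d_L, d_{L-1}, ..., d_1]``.

    The input is zero-padded to a multiple of ``2**levels`` so every level
    sees an even length and the whole transform stays orthogonal.
    """
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    if levels < 1:
        raise ValueError("levels must be >= 1")
    block = 2 ** levels
    padded = int(math.ceil(x.size / block)) * block
    if padded != x.size:
        x = np.concatenate([x, np.zeros(padded - x.size)])
    details: list[np.ndarray] = []
    approx = x
    for _ in range(levels):
        approx, detail = dwt_periodized(approx, wavelet)
        details.append(detail)
    return [approx] + details[::-1]


def subband_energies(coeffs: list[np.ndarray]) -> np.ndarray:
    """Energy (sum of squares) of each subband, approximation first."""
    return np.array([float(np.sum(c * c)) for c in coeffs])
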