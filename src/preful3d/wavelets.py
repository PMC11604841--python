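"""Orthonormal periodized Symlet-4 wavelet transform in 1D/3D.

Provides the multilevel decomposition used as an L1 sparsity penalty in the
iterative reconstruction, plus the soft-threshold proximal step.  The
transform is orthonormal (perfect reconstruction, energy preserving), which
makes ``reconstruct(soft_threshold(decompose(x)))`` the exact prox of
``lam * ||detail coefficients||_1``.
"""

from __future__ import annotations

import numpy as np

# Symlet-4 decomposition low-pass filter (8 taps, orthonormal).
SYM4_LO = np.array(
    [
        -0.07576571478927333,
        -0.02963552764599851,
        0.49761866763201545,
        0.8037387518059161,
        0.29785779560527736,
        -0.09921954357684722,
        -0.012603967262037833,
        0.0322231006040427,
    ]
)
SYM4_HI = (SYM4_LO[::-1] * np.array([1, -1] * 4)).copy()  # quadrature mirror


def _analysis_axis(x: np.ndarray, axis: int):
    """One periodized analysis step along ``axis`` (length must be even)."""
    n = x.shape[axis]
    if n % 2:
        raise ValueError("axis length must be even for the periodized DWT")
    taps = len(SYM4_LO)
    idx = (2 * np.arange(n // 2)[:, None] + np.arange(taps)[None, :]) % n
    xs = np.take(x, idx.reshape(-1), axis=axis)
    new_shape = list(x.shape)
    new_shape[axis : axis + 1] = [n // 2, taps]
    xs = xs.reshape(new_shape)
    lo = np.tensordot(xs, SYM4_LO, axes=([axis + 1], [0]))
    hi = np.tensordot(xs, SYM4_HI, axes=([axis + 1], [0]))
    return lo, hi


def _synthesis_axis(lo: np.ndarray, hi: np.ndarray, axis: int) -> np.ndarray:
    """Adjoint (= inverse, by orthonormality) of :func:`_analysis_axis`."""
    n2 = lo.shape[axis]
    n = 2 * n2
    taps = len(SYM4_LO)
    out_shape = list(lo.shape)
    out_shape[axis] = n
    out = np.zeros(out_shape, dtype=np.result_type(lo, hi))
    for j in range(taps):
        idx = (2 * np.arange(n2) + j) % n
        sl = [slice(None)] * out.ndim
        sl[axis] = idx
        np.add.at(out, tuple(sl), SYM4_LO[j] * lo + SYM4_HI[j] * hi)
    return out


def dwt3(x: np.ndarray, levels: int = 2):
    """Multilevel 3D DWT.  Returns (approx, [level_bands...]) where each
    level holds a dict of the 7 detail subbands keyed by e.g. ``"lhh"``."""
    a = np.asarray(x)
    for ax in range(3):
        if a.shape[ax] % (2**levels):
            raise ValueError("shape must be divisible by 2**levels")
    detail = []
    for _ in range(levels):
        lo0, hi0 = _analysis_axis(a, 0)
        bands = {}
        parts0 = {"l": lo0, "h": hi0}
        parts1 = {
            k0 + k1: v
            for k0, p0 in parts0.items()
            for k1, v in zip("lh", _analysis_axis(p0, 1))
        }
        sub = {}
        for key, p in parts1.items():
            lo2, hi2 = _analysis_axis(p, 2)
            sub[key + "l"] = lo2
            sub[key + "h"] = hi2
        a = sub.pop("lll")
        bands.update(sub)
        detail.append(bands)
    return a, detail


def idwt3(approx: np.ndarray, detail) -> np.ndarray:
    a = approx
    for bands in reversed(detail):
        full = dict(bands)
        full["lll"] = a
        parts1 = {}
        for key in ("ll", "lh", "hl", "hh"):
            parts1[key] = _synthesis_axis(full[key + "l"], full[key + "h"], 2)
        lo0 = _synthesis_axis(parts1["ll"], parts1["lh"], 1)
        hi0 = _synthesis_axis(parts1["hl"], parts1["hh"], 1)
        a = _synthesis_axis(lo0, hi0, 0)
    return a


def detail_l1(x: np.ndarray, levels: int = 2) -> float:
    """Sum of |detail coefficients| of the multilevel 3D DWT."""
    _, detail = dwt3(x, levels)
    return float(sum(np.abs(b).sum() for bands in detail for b in bands.values()))


def soft_threshold_dwt3(x: np.ndarray, thresh: float, levels: int = 2) -> np.ndarray:
    """Prox of ``thresh * ||detail(DWT x)||_1`` (approx band untouched)."""
    if thresh <= 0:
        return np.asarray(x)
    a, detail = dwt3(x, levels)
    for bands in detail:
        for key, band in bands.items():
            mag = np.abs(band)
            scale = np.maximum(mag - thresh, 0.0) / np.maximum(mag, 1e-300)
            bands[key] = band * scale
    return idwt3(a, detail)
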