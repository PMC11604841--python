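"""Threshold-based VDP for ventilation-weighted (Xe-style) volumes, with a
polynomial bias-field surrogate correction and rigid mutual-information
alignment."""

from __future__ import annotations

import itertools
import warnings

import numpy as np
from scipy import ndimage, optimize

from .preful import DefectResult

__all__ = ["bias_correct", "threshold_vdp", "rigid_align"]


def _poly_design(shape, mask, order):
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    grids = np.meshgrid(*axes, indexing="ij")
    cols = []
    for powers in itertools.product(range(order + 1), repeat=3):
        if sum(powers) > order:
            continue
        term = np.ones(shape)
        for g, p in zip(grids, powers):
            term = term * g**p
        cols.append(term[mask])
    return np.stack(cols, axis=1)


def bias_correct(volume: np.ndarray, mask: np.ndarray, order: int = 2):
    """Divide out a smooth multiplicative bias field.

    Log-intensity inside the mask is fit with a 3D polynomial of the given
    order by least squares; the image is divided by the exponentiated fit
    and rescaled to preserve the masked mean.  Non-positive intensities
    inside the mask are offset first (reported via a warning).
    """
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    vals = volume[mask]
    offset = 0.0
    if vals.min() <= 0:
        offset = -vals.min() + 1e-6 * max(np.ptp(vals), 1.0)
        warnings.warn(f"non-positive intensities inside mask; offset {offset:.3g} applied")
    design = _poly_design(volume.shape, mask, order)
    logv = np.log(vals + offset)
    coef, *_ = np.linalg.lstsq(design, logv, rcond=None)
    fit = np.zeros(volume.shape)
    full_design = _poly_design(volume.shape, np.ones(volume.shape, dtype=bool), order)
    fit = (full_design @ coef).reshape(volume.shape)
    fit -= fit[mask].mean()  # keep the field a pure shape, mean 1 after exp
    corrected = (volume + offset) / np.exp(fit) - offset
    target = vals.mean()
    got = corrected[mask].mean()
    if got != 0:
        corrected = corrected * (target / got)
    return corrected


def threshold_vdp(volume: np.ndarray, mask: np.ndarray, frac: float = 0.60) -> DefectResult:
    """Defect = masked voxels strictly below ``frac`` times the masked mean
    intensity; VDP is the defect share of the lung volume in percent."""
    volume = np.asarray(volume, dtype=np.float64)
    mask = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    thresh = frac * volume[mask].mean()
    defect = mask & (volume < thresh)
    vdp = 100.0 * defect.sum() / mask.sum()
    return DefectResult(defect_mask=defect, vdp_percent=float(vdp),
                        cluster_means=[float(thresh)], method="threshold")


def _mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    hist, _, _ = np.histogram2d(a.ravel(), b.ravel(), bins=bins)
    p = hist / hist.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def _rigid_resample(moving: np.ndarray, params) -> np.ndarray:
    tx, ty, tz, rx, ry, rz = params
    center = (np.array(moving.shape) - 1) / 2.0
    cx, sx = np.cos(rx), np.sin(rx)
    cy, sy = np.cos(ry), np.sin(ry)
    cz, sz = np.cos(rz), np.sin(rz)
    mat_x = np.array([[1, 0, 0], [0, cx, -sx], [0, sx, cx]])
    mat_y = np.array([[cy, 0, sy], [0, 1, 0], [-sy, 0, cy]])
    mat_z = np.array([[cz, -sz, 0], [sz, cz, 0], [0, 0, 1]])
    rot = mat_z @ mat_y @ mat_x
    offset = center - rot @ (center - np.array([tx, ty, tz]))
    return ndimage.affine_transform(moving, rot, offset=offset, order=1, mode="nearest")


def rigid_align(moving: np.ndarray, fixed: np.ndarray, bins: int = 32):
    """6-dof mutual-information rigid registration (Powell optimizer).

    Returns (aligned volume, parameter vector (tx, ty, tz, rx, ry, rz) in
    voxels / radians).  If optimization fails to beat the identity, the
    identity transform is returned with a warning.
    """
    moving = np.asarray(moving, dtype=np.float64)
    fixed = np.asarray(fixed, dtype=np.float64)
    if moving.shape != fixed.shape:
        raise ValueError("volumes must share a grid")

    def cost(params):
        return -_mutual_information(_rigid_resample(moving, params), fixed, bins)

    x0 = np.zeros(6)
    res = optimize.minimize(cost, x0, method="Powell",
                            options={"xtol": 1e-3, "ftol": 1e-5, "maxiter": 2000})
    if not res.success or res.fun > cost(x0):
        warnings.warn("rigid alignment did not improve on identity; returning identity")
        return moving.copy(), x0
    return _rigid_resample(moving, res.x), res.x
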