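"""Spatial processing: registration to mid-respiration, thoracic-cavity
segmentation by seeded region growing, and 3D guided filtering."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.registration import optical_flow_ilk

__all__ = [
    "ThoracicMask",
    "register_to_mid",
    "segment_thoracic_cavity",
    "auto_seeds",
    "guided_filter3d",
]


@dataclass
class ThoracicMask:
    mask: np.ndarray
    seeds: list
    tolerance: float


def _warp(volume: np.ndarray, flow: np.ndarray) -> np.ndarray:
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in volume.shape], indexing="ij")
    sample = np.array([c + f for c, f in zip(coords, flow)])
    return ndimage.map_coordinates(volume, sample, order=1, mode="nearest")


def register_to_mid(series, radius: int = 6, num_warp: int = 8):
    """Register every state to the mid-respiration state (amplitude closest
    to 0.5) with a smooth dense displacement model (iterative Lucas-Kanade
    optical flow).  States whose registration fails to reduce the SSD to
    the reference fall back to identity with a warning.

    Returns (registered ImageSeries copy, fields of shape
    (n_states, 3, X, Y, Z) mapping state coords to mid-state coords).
    """
    if series.n_states < 2:
        raise ValueError("need at least two states to register")
    mid = int(np.argmin(np.abs(np.asarray(series.state_amplitude) - 0.5)))
    ref = series.data[mid]
    scale = np.percentile(ref, 99.5)
    ref_n = ref / max(scale, 1e-12)
    registered = np.empty_like(series.data)
    fields = np.zeros((series.n_states, 3) + ref.shape)
    for s in range(series.n_states):
        if s == mid:
            registered[s] = ref
            continue
        mov = series.data[s]
        mov_n = mov / max(scale, 1e-12)
        flow = optical_flow_ilk(ref_n, mov_n, radius=radius, num_warp=num_warp)
        warped = _warp(mov, flow)
        ssd_before = float(((mov - ref) ** 2).sum())
        ssd_after = float(((warped - ref) ** 2).sum())
        if ssd_after > ssd_before:
            warnings.warn(f"registration of state {s} failed (SSD {ssd_before:.3g} -> "
                          f"{ssd_after:.3g}); using identity")
            registered[s] = mov
        else:
            registered[s] = warped
            fields[s] = flow
    out = type(series)(
        data=registered,
        state_amplitude=series.state_amplitude,
        voxel_size_mm=series.voxel_size_mm,
        provenance={**(series.provenance or {}), "registered_to": mid},
    )
    return out, fields


def jacobian_determinant(field: np.ndarray) -> np.ndarray:
    """Finite-difference Jacobian determinant of the deformation
    ``x -> x + field(x)`` for one (3, X, Y, Z) displacement field."""
    grads = np.empty((3, 3) + field.shape[1:])
    for i in range(3):
        for j in range(3):
            grads[i, j] = np.gradient(field[i], axis=j)
        grads[i, i] += 1.0
    return np.linalg.det(np.moveaxis(grads, (0, 1), (-2, -1)))


def segment_thoracic_cavity(volume: np.ndarray, seeds, tolerance: float = 0.15) -> ThoracicMask:
    """6-connected seeded region growing.

    A voxel joins the region when its intensity differs from the running
    regional mean by at most ``tolerance`` times the robust intensity range
    (1st-99th percentile).  The grown region is closed (radius 1) and
    hole-filled.  Growth that floods the image border is rejected as a
    leak.
    """
    volume = np.asarray(volume, dtype=np.float64)
    seeds = [tuple(int(v) for v in s) for s in seeds]
    if not seeds:
        raise ValueError("need at least one seed")
    lo, hi = np.percentile(volume, [1, 99])
    robust_range = max(hi - lo, 1e-12)
    thresh = tolerance * robust_range
    struct = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

    mask = np.zeros(volume.shape, dtype=bool)
    for s in seeds:
        mask[s] = True
    region_sum = float(volume[mask].sum())
    region_n = int(mask.sum())
    while True:
        mean = region_sum / region_n
        frontier = ndimage.binary_dilation(mask, struct) & ~mask
        accept = frontier & (np.abs(volume - mean) <= thresh)
        n_new = int(accept.sum())
        if n_new == 0:
            break
        mask |= accept
        region_sum += float(volume[accept].sum())
        region_n += n_new

    border = np.zeros(volume.shape, dtype=bool)
    border[0], border[-1] = True, True
    border[:, 0], border[:, -1] = True, True
    border[:, :, 0], border[:, :, -1] = True, True
    if mask[border].sum() > 0.10 * border.sum():
        raise ValueError("region growing leaked: grown region floods the image border")

    mask = ndimage.binary_closing(mask, ndimage.generate_binary_structure(3, 1), iterations=1)
    mask = ndimage.binary_fill_holes(mask)
    return ThoracicMask(mask=mask, seeds=seeds, tolerance=tolerance)


def auto_seeds(volume: np.ndarray, n_seeds: int = 2):
    """Centroids of the two largest dark connected components inside the
    body (lung candidates)."""
    volume = np.asarray(volume, dtype=np.float64)
    body = volume > 0.25 * np.percentile(volume, 99)
    body = ndimage.binary_fill_holes(body)
    body_interior = ndimage.binary_erosion(body, iterations=2)
    dark = body_interior & (volume < 0.75 * np.median(volume[body_interior]))
    labels, n = ndimage.label(dark)
    if n == 0:
        raise ValueError("no dark components found for automatic seeding")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    order = np.argsort(sizes)[::-1][:n_seeds]
    centroids = ndimage.center_of_mass(dark, labels, index=[int(i) + 1 for i in order])
    return [tuple(int(round(v)) for v in c) for c in centroids]


def guided_filter3d(image: np.ndarray, guide: np.ndarray, radius: int = 2,
                    eps: float = 1e-3) -> np.ndarray:
    """Edge-preserving guided filter (local linear model a*guide + b),
    extended to 3D with a box window of half-width ``radius``."""
    image = np.asarray(image, dtype=np.float64)
    guide = np.asarray(guide, dtype=np.float64)
    if image.shape != guide.shape:
        raise ValueError("image and guide must share a shape")
    size = 2 * radius + 1
    mean = lambda x: ndimage.uniform_filter(x, size=size)
    mean_i, mean_g = mean(image), mean(guide)
    cov_gi = mean(guide * image) - mean_g * mean_i
    var_g = mean(guide * guide) - mean_g**2
    a = cov_gi / (var_g + eps)
    b = mean_i - a * mean_g
    return mean(a) * guide + mean(b)
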