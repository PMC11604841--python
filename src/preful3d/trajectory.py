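"""Center-out 3D golden-means radial ("koosh-ball") trajectory.

Spoke directions follow the 2D golden-means construction: successive spokes
advance by irrational fractions of the unit square mapped to the sphere via
(z, azimuth), giving quasi-uniform incremental coverage so that any
contiguous block of spokes samples the sphere near-uniformly.  Readout
radii ramp quadratically over the initial gradient ramp, then linearly, up
to the Nyquist radius 0.5 cycles/voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# 2D golden means of the modified Fibonacci construction
PHI1 = 0.4656145
PHI2 = 0.6823278


@dataclass
class Trajectory:
    """Radial sampling geometry shared by all spokes.

    Attributes
    ----------
    directions : (n_spokes, 3) unit vectors
    radii : (n_readout,) normalized radius in [0, 0.5], center-out
    ramp_fraction : fraction of the readout acquired on the gradient ramp
    dcf : (n_readout,) per-sample density compensation, sums to 1 per spoke
    """

    directions: np.ndarray
    radii: np.ndarray
    ramp_fraction: float
    dcf: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.dcf is None:
            self.dcf = density_compensation(self)

    @property
    def n_spokes(self) -> int:
        return self.directions.shape[0]

    @property
    def n_readout(self) -> int:
        return self.radii.shape[0]

    def points(self, spokes=None) -> np.ndarray:
        """k-space sample locations, shape (n_spokes*n_readout, 3), spoke-major."""
        d = self.directions if spokes is None else self.directions[spokes]
        return (d[:, None, :] * self.radii[None, :, None]).reshape(-1, 3)


def golden_means_directions(n_spokes: int) -> np.ndarray:
    if n_spokes < 1:
        raise ValueError("n_spokes must be >= 1")
    m = np.arange(n_spokes, dtype=np.float64)
    z = 1.0 - 2.0 * np.mod(m * PHI1, 1.0)
    theta = 2.0 * np.pi * np.mod(m * PHI2, 1.0)
    s = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([s * np.cos(theta), s * np.sin(theta), z], axis=1)


def ramped_radii(n_readout: int, ramp_fraction: float) -> np.ndarray:
    """Radii growing quadratically on the ramp then linearly, C1-continuous,
    starting at 0 and reaching 0.5 at the last sample."""
    if n_readout < 2:
        raise ValueError("n_readout must be >= 2")
    if not 0.0 <= ramp_fraction < 1.0:
        raise ValueError("ramp_fraction must be in [0, 1)")
    t = np.arange(n_readout, dtype=np.float64) / (n_readout - 1)
    if ramp_fraction < 1.0 / n_readout:  # sub-sample ramp: plain linear
        return 0.5 * t
    a = ramp_fraction
    # r(t) = t^2/(2a) for t<=a ; r(t) = t - a/2 after, then scaled to end at 0.5
    r = np.where(t <= a, t**2 / (2 * a), t - a / 2)
    return 0.5 * r / r[-1]


def density_compensation(traj: Trajectory) -> np.ndarray:
    """Analytic 3D radial compensation: weight ~ r^2 * dr, normalized per spoke."""
    r = traj.radii
    dr = np.gradient(r)
    w = np.maximum(r**2 * dr, 0.0)
    # the r=0 sample would get zero weight; give it its cell volume ~ (dr/2)^3
    w[0] = max(w[0], (dr[0] / 2.0) ** 3)
    return w / w.sum()


def make_trajectory(n_spokes: int, n_readout: int = 64, ramp_fraction: float = 0.3) -> Trajectory:
    return Trajectory(
        directions=golden_means_directions(n_spokes),
        radii=ramped_radii(n_readout, ramp_fraction),
        ramp_fraction=ramp_fraction,
    )
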