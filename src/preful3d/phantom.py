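"""Ventilating digital thorax phantom and its radial k-space simulator.

The phantom is an ellipsoidal body containing two ellipsoidal lungs whose
parenchymal signal density oscillates with a raised-cosine breathing cycle:
at respiratory amplitude ``b`` a lung voxel with ventilation amplitude
``v`` has intensity ``rho * (1 - alpha * v * b)`` (expiration bright,
inspiration dark), and the whole thorax is warped by a smooth
superior-inferior displacement that is maximal at the diaphragm.
Ventilation defects are spheres where ``v`` is scaled down.

``simulate_acquisition`` renders this object spoke-by-spoke through the
NUFFT with multi-coil sensitivity weighting, a slow multiplicative receiver
gain drift, and complex Gaussian noise, producing the raw input of the
reconstruction pipeline together with per-spoke ground-truth respiratory
phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.ndimage import map_coordinates

from .nufft import NufftPlan
from .trajectory import Trajectory, make_trajectory

#: global tidal density-change fraction of fully ventilated parenchyma
DEFAULT_ALPHA = 0.3

#: number of quantization levels of the respiratory amplitude used by the
#: simulator (one rendered frame per level instead of one per spoke)
N_PHASE_LEVELS = 64


@dataclass
class LungGeometry:
    body_center: tuple = None
    body_semiaxes: tuple = None
    lung_centers: tuple = None
    lung_semiaxes: tuple = None
    background_intensity: float = 0.8
    parenchyma_intensity: float = 0.55

    def resolved(self, grid_shape):
        """Fill unset geometry with defaults proportional to the grid."""
        nx, ny, nz = grid_shape
        g = LungGeometry(**asdict(self))
        if g.body_center is None:
            g.body_center = (nx / 2, ny / 2, nz / 2)
        if g.body_semiaxes is None:
            g.body_semiaxes = (0.46 * nx, 0.40 * ny, 0.48 * nz)
        if g.lung_centers is None:
            g.lung_centers = (
                (0.30 * nx, 0.48 * ny, 0.55 * nz),
                (0.70 * nx, 0.48 * ny, 0.55 * nz),
            )
        if g.lung_semiaxes is None:
            g.lung_semiaxes = (0.15 * nx, 0.26 * ny, 0.30 * nz)
        return g


@dataclass
class Breathing:
    period_s: float = 4.0
    inspiration_fraction: float = 0.4
    diaphragm_shift_vox: float = 3.0

    def amplitude(self, t_s):
        """Respiratory amplitude b(t) in [0, 1]; raised cosine, 0=expiration."""
        tau = np.mod(np.asarray(t_s, dtype=np.float64) / self.period_s, 1.0)
        fi = self.inspiration_fraction
        up = 0.5 * (1.0 - np.cos(np.pi * tau / fi))
        down = 0.5 * (1.0 + np.cos(np.pi * (tau - fi) / (1.0 - fi)))
        return np.where(tau < fi, up, down)


@dataclass
class Drift:
    amplitude: float = 0.0
    period_s: float = 480.0

    def gain(self, t_s):
        return 1.0 + self.amplitude * np.sin(2.0 * np.pi * np.asarray(t_s) / self.period_s)


@dataclass
class PhantomSpec:
    grid_shape: tuple = (64, 64, 64)
    voxel_size_mm: float = 2.0
    lung_geometry: LungGeometry = field(default_factory=LungGeometry)
    defects: list = field(default_factory=list)  # (center, radius_vox, vent_scale)
    breathing: Breathing = field(default_factory=Breathing)
    drift: Drift = field(default_factory=Drift)
    noise_sigma: float = 0.0  # complex-noise SD relative to peak |kdata|
    alpha: float = DEFAULT_ALPHA
    n_coils: int = 4
    seed: int = 0

    def __post_init__(self):
        if any(n < 16 for n in self.grid_shape):
            raise ValueError("grid_shape entries must be >= 16")
        if self.n_coils < 1:
            raise ValueError("n_coils must be >= 1")

    @classmethod
    def from_dict(cls, payload: dict) -> "PhantomSpec":
        """Build a spec from plain (e.g. YAML-loaded) nested dictionaries."""
        payload = dict(payload)
        if isinstance(payload.get("lung_geometry"), dict):
            payload["lung_geometry"] = LungGeometry(**payload["lung_geometry"])
        if isinstance(payload.get("breathing"), dict):
            payload["breathing"] = Breathing(**payload["breathing"])
        if isinstance(payload.get("drift"), dict):
            payload["drift"] = Drift(**payload["drift"])
        if "grid_shape" in payload:
            payload["grid_shape"] = tuple(payload["grid_shape"])
        if "defects" in payload:
            payload["defects"] = [(tuple(c), float(r), float(s))
                                  for c, r, s in payload["defects"]]
        return cls(**payload)


@dataclass
class PhantomTruth:
    vent_amplitude_map: np.ndarray
    lung_mask: np.ndarray
    defect_mask: np.ndarray
    true_vdp_percent: float
    phase_of_spoke: np.ndarray = None  # filled by simulate_acquisition


@dataclass
class RadialAcquisition:
    kdata: np.ndarray          # (n_spokes, n_readout, n_coils) complex
    trajectory: Trajectory
    timestamp_s: np.ndarray    # (n_spokes,)
    coil_maps: np.ndarray      # (n_coils, *grid) complex, or None
    grid_shape: tuple
    voxel_size_mm: float
    seed: int

    @property
    def n_spokes(self):
        return self.kdata.shape[0]

    @property
    def n_readout(self):
        return self.kdata.shape[1]

    @property
    def n_coils(self):
        return self.kdata.shape[2]


def _ellipsoid_mask(grid_shape, center, semiaxes):
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid_shape], indexing="ij")
    q = sum(((c - c0) / a) ** 2 for c, c0, a in zip(coords, center, semiaxes))
    return q <= 1.0


def _sphere_mask(grid_shape, center, radius):
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in grid_shape], indexing="ij")
    q = sum((c - c0) ** 2 for c, c0 in zip(coords, center))
    return q <= radius**2


def build_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Construct masks and the ventilation-amplitude map; defects must lie
    inside the lungs."""
    geo = spec.lung_geometry.resolved(spec.grid_shape)
    lung = np.zeros(spec.grid_shape, dtype=bool)
    for c in geo.lung_centers:
        lung |= _ellipsoid_mask(spec.grid_shape, c, geo.lung_semiaxes)
    vent = np.where(lung, 1.0, 0.0)
    defect = np.zeros(spec.grid_shape, dtype=bool)
    for center, radius, scale in spec.defects:
        if not 0.0 <= scale <= 1.0:
            raise ValueError("ventilation_scale must be in [0, 1]")
        sph = _sphere_mask(spec.grid_shape, center, radius)
        if np.any(sph & ~lung):
            raise ValueError(f"defect at {tuple(center)} (r={radius}) extends outside the lungs")
        vent[sph] *= scale
        defect |= sph
    n_lung = int(lung.sum())
    vdp = 100.0 * defect.sum() / n_lung if n_lung else 0.0
    return PhantomTruth(vent, lung, defect, float(vdp))


def body_mask(spec: PhantomSpec) -> np.ndarray:
    geo = spec.lung_geometry.resolved(spec.grid_shape)
    return _ellipsoid_mask(spec.grid_shape, geo.body_center, geo.body_semiaxes)


def frame_at_phase(truth: PhantomTruth, spec: PhantomSpec, b: float) -> np.ndarray:
    """Render the 3D frame at respiratory amplitude ``b`` in [0, 1]."""
    if not 0.0 <= b <= 1.0:
        raise ValueError("b must be in [0, 1]")
    geo = spec.lung_geometry.resolved(spec.grid_shape)
    body = _ellipsoid_mask(spec.grid_shape, geo.body_center, geo.body_semiaxes)
    img = np.where(body, geo.background_intensity, 0.0)
    lung_signal = geo.parenchyma_intensity * (1.0 - spec.alpha * truth.vent_amplitude_map * b)
    img = np.where(truth.lung_mask, lung_signal, img)
    if b == 0.0:
        return img
    shift = b * spec.breathing.diaphragm_shift_vox
    if shift == 0.0:
        return img
    nz = spec.grid_shape[2]
    # SI displacement: maximal inferiorly (z=0), vanishing at the top slice.
    # The warp is mass-conserving (Jacobian-weighted advection) so the total
    # signal — and hence the k-space centre — tracks the parenchymal density
    # change alone.
    dz = shift * (1.0 - np.arange(nz) / (nz - 1.0))
    jac = 1.0 - shift / (nz - 1.0)
    coords = list(np.meshgrid(*[np.arange(n, dtype=np.float64) for n in spec.grid_shape], indexing="ij"))
    coords[2] = coords[2] + dz[None, None, :]
    return map_coordinates(img, coords, order=1, mode="nearest") * jac


def make_coil_maps(spec: PhantomSpec) -> np.ndarray:
    """Smooth complex Gaussian sensitivities centred on points around the torso."""
    nx, ny, nz = spec.grid_shape
    coords = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in spec.grid_shape], indexing="ij")
    maps = np.empty((spec.n_coils, nx, ny, nz), dtype=np.complex128)
    sigma = 0.6 * max(nx, ny)
    for c in range(spec.n_coils):
        ang = 2.0 * np.pi * c / spec.n_coils
        px = nx / 2 + 0.55 * nx * np.cos(ang)
        py = ny / 2 + 0.55 * ny * np.sin(ang)
        r2 = (coords[0] - px) ** 2 + (coords[1] - py) ** 2 + (coords[2] - nz / 2) ** 2 * 0.25
        mag = np.exp(-r2 / (2.0 * sigma**2))
        phase = 0.5 * np.pi * (coords[0] * np.cos(ang) + coords[1] * np.sin(ang)) / max(nx, ny)
        maps[c] = mag * np.exp(1j * (phase + ang / 3.0))
    return maps


def simulate_acquisition(
    truth: PhantomTruth,
    spec: PhantomSpec,
    traj: Trajectory = None,
    n_spokes: int = 20000,
    tr_s: float = 0.00192,
) -> RadialAcquisition:
    """Simulate the spoke-by-spoke radial acquisition of the breathing phantom.

    The respiratory amplitude is quantized to ``N_PHASE_LEVELS`` so that one
    3D frame is rendered per level rather than per spoke (a documented
    approximation); all spokes falling in a level share that frame.
    """
    if n_spokes <= 0:
        raise ValueError("n_spokes must be positive")
    if traj is None:
        traj = make_trajectory(n_spokes)
    if traj.n_spokes < n_spokes:
        raise ValueError("trajectory has fewer directions than n_spokes")
    if traj.n_spokes > n_spokes:
        traj = Trajectory(directions=traj.directions[:n_spokes], radii=traj.radii,
                          ramp_fraction=traj.ramp_fraction, dcf=traj.dcf)
    rng = np.random.default_rng(spec.seed)
    t = np.arange(n_spokes) * tr_s
    b = spec.breathing.amplitude(t)
    levels = np.round(b * (N_PHASE_LEVELS - 1)).astype(int)
    b_q = levels / (N_PHASE_LEVELS - 1)
    maps = make_coil_maps(spec)

    kdata = np.empty((n_spokes, traj.n_readout, spec.n_coils), dtype=np.complex128)
    for lev in np.unique(levels):
        sel = np.flatnonzero(levels == lev)
        frame = frame_at_phase(truth, spec, lev / (N_PHASE_LEVELS - 1))
        plan = NufftPlan(traj.points(sel), spec.grid_shape)
        for c in range(spec.n_coils):
            samples = plan.forward(frame * maps[c])
            kdata[sel, :, c] = samples.reshape(len(sel), traj.n_readout)

    gain = spec.drift.gain(t)
    kdata *= gain[:, None, None]
    if spec.noise_sigma > 0:
        sigma = spec.noise_sigma * np.abs(kdata).max()
        noise = rng.normal(scale=sigma / np.sqrt(2.0), size=kdata.shape + (2,))
        kdata += noise[..., 0] + 1j * noise[..., 1]

    truth.phase_of_spoke = b_q
    return RadialAcquisition(
        kdata=kdata,
        trajectory=traj,
        timestamp_s=t,
        coil_maps=maps,
        grid_shape=tuple(spec.grid_shape),
        voxel_size_mm=spec.voxel_size_mm,
        seed=spec.seed,
    )


def noise_sigma_for_snr(snr: float) -> float:
    """Map a nominal acquisition SNR to the relative k-space noise SD.

    Calibrated on the default 64^3 / 20k-spoke phantom so that the
    reconstructed parenchyma signal-to-noise ratio is approximately ``snr``.
    """
    return 0.0125 / snr


def simulate_xe_volume(
    truth: PhantomTruth,
    spec: PhantomSpec,
    slab_mm: float = 16.0,
    noise_sigma: float = 0.0,
    bias_amplitude: float = 0.0,
):
    """Ventilation-weighted volume emulating a slab-resolved Xe acquisition.

    Returns (image, lung_mask).  Intensity is proportional to the
    ventilation amplitude inside the lung, averaged over non-overlapping
    anterior-posterior slabs of ``slab_mm``, optionally multiplied by a
    smooth quadratic bias field and corrupted with Gaussian noise.
    """
    ratio = slab_mm / spec.voxel_size_mm
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError("slab_mm must be a multiple of voxel_size_mm")
    slab_vox = int(round(ratio))
    ny = spec.grid_shape[1]
    ys = np.where(truth.lung_mask.any(axis=(0, 2)))[0]
    if slab_vox > (ys.max() - ys.min() + 1):
        raise ValueError("slab thicker than the anterior-posterior lung extent")
    img = np.where(truth.lung_mask, truth.vent_amplitude_map, 0.0)
    out = np.zeros_like(img)
    for start in range(0, ny, slab_vox):
        sl = slice(start, min(start + slab_vox, ny))
        out[:, sl, :] = img[:, sl, :].mean(axis=1, keepdims=True)
    out = np.where(truth.lung_mask, out, 0.0)
    if bias_amplitude:
        nx, _, nz = spec.grid_shape
        cx = np.linspace(-1, 1, nx)[:, None, None]
        cy = np.linspace(-1, 1, ny)[None, :, None]
        cz = np.linspace(-1, 1, nz)[None, None, :]
        bias = 1.0 + bias_amplitude * (0.5 * cx**2 - 0.3 * cy * cz + 0.4 * cz - 0.2 * cx * cy)
        out = out * bias
    if noise_sigma > 0:
        rng = np.random.default_rng(spec.seed + 1)
        out = out + rng.normal(scale=noise_sigma * max(out.max(), 1e-12), size=out.shape)
    return out, truth.lung_mask.copy()


def find_defect_radius(spec: PhantomSpec, center, target_fraction: float, scale: float = 0.0):
    """Search the sphere radius whose voxel count is closest to
    ``target_fraction`` of the lung volume (ground-truth helper)."""
    base = build_phantom(PhantomSpec(**{**asdict(spec), "defects": [],
                                        "lung_geometry": spec.lung_geometry,
                                        "breathing": spec.breathing,
                                        "drift": spec.drift}))
    n_lung = base.lung_mask.sum()
    best, best_err = None, np.inf
    for radius in np.arange(1.0, min(spec.grid_shape) / 2.0, 0.25):
        sph = _sphere_mask(spec.grid_shape, center, radius)
        if np.any(sph & ~base.lung_mask):
            break
        frac = sph.sum() / n_lung
        if abs(frac - target_fraction) < best_err:
            best, best_err = radius, abs(frac - target_fraction)
    if best is None:
        raise ValueError("no admissible radius found at this center")
    return best
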