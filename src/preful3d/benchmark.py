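"""End-to-end benchmark scenarios on the digital phantom.

Shared by the test suite and ``scripts/acceptance.py``: desk-scale
(64^3 grid, 20 000 spokes, 10 states, SNR 20) recovery runs at three true
defect levels, self-gating fidelity, and the static reconstruction
accuracy check.
"""

from __future__ import annotations

import numpy as np

from .gating import gate
from .phantom import (
    Breathing,
    Drift,
    PhantomSpec,
    build_phantom,
    frame_at_phase,
    make_coil_maps,
    noise_sigma_for_snr,
    simulate_acquisition,
)
from .pipeline import PipelineConfig, run_pipeline
from .trajectory import make_trajectory

#: defect layouts on the default 64^3 phantom giving true VDP of ~5/10/20 %
DEFECT_LAYOUTS = {
    5: [[[19, 31, 35], 6.75, 0.0]],
    10: [[[19, 31, 35], 8.5, 0.0]],
    20: [[[19, 31, 35], 8.5, 0.0], [[45, 31, 35], 8.5, 0.0]],
}


def level_config(level: int, seed: int, out_dir: str) -> PipelineConfig:
    return PipelineConfig(out_dir=out_dir, seed=seed,
                          defects=DEFECT_LAYOUTS[level], snr=20.0)


def run_level(level: int, seed: int, out_dir: str, force: bool = False) -> dict:
    """Full pipeline at one defect level; returns the pipeline report."""
    return run_pipeline(level_config(level, seed, out_dir), force=force)


def gating_fidelity(seed: int = 1, grid: int = 64, n_spokes: int = 20000,
                    n_states: int = 10, snr: float = 20.0) -> dict:
    """Pearson r of the normalized self-gating waveform against the true
    respiratory amplitude, with drift (amplitude 0.2, block-rescaled) and
    without."""
    out = {}
    for label, drift_amp in (("clean", 0.0), ("drift", 0.2)):
        spec = PhantomSpec(grid_shape=(grid,) * 3,
                           defects=[(tuple(c), r, s) for c, r, s in DEFECT_LAYOUTS[10]],
                           drift=Drift(amplitude=drift_amp),
                           noise_sigma=noise_sigma_for_snr(snr), seed=seed)
        truth = build_phantom(spec)
        acq = simulate_acquisition(truth, spec, make_trajectory(n_spokes),
                                   n_spokes=n_spokes)
        wf, _ = gate(acq, n_states=n_states)
        out[label] = float(np.corrcoef(wf.normalized, truth.phase_of_spoke)[0, 1])
    out["degradation"] = abs(out["clean"]) - abs(out["drift"])
    return out


def static_recon_nrmse(seed: int = 2, grid: int = 64, n_spokes: int = 20000,
                       iters: int = 8) -> float:
    """NRMSE of the unregularized reconstruction of a static, noise-free
    phantom from the full spoke set, against the coil-combined reference."""
    from .nufft import NufftPlan
    from .recon import reconstruct_state

    spec = PhantomSpec(grid_shape=(grid,) * 3,
                       breathing=Breathing(diaphragm_shift_vox=0.0, period_s=1e9),
                       noise_sigma=0.0, seed=seed)
    truth = build_phantom(spec)
    traj = make_trajectory(n_spokes)
    acq = simulate_acquisition(truth, spec, traj, n_spokes=n_spokes)
    maps = make_coil_maps(spec)
    norm = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps_unit = maps / np.maximum(norm, 1e-12)
    plan = NufftPlan(acq.trajectory.points(), spec.grid_shape)
    samples = acq.kdata.transpose(2, 0, 1).reshape(acq.n_coils, -1)
    weights = np.tile(acq.trajectory.dcf, (acq.n_spokes, 1)).reshape(-1)
    x, _ = reconstruct_state(plan, maps_unit, samples, weights,
                             lam_tv=0, lam_wav=0, iters=iters)
    target = frame_at_phase(truth, spec, 0.0) * norm
    return float(np.linalg.norm(np.abs(x) - target) / np.linalg.norm(target))


def lmm_null_calibration(seed: int = 3, n_subjects: int = 12,
                         n_replicates: int = 500, alpha: float = 0.05) -> dict:
    """Empirical type-I error of the mixed-model slope test under the null."""
    from .compare import lmm_correlation

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_replicates):
        visits = rng.integers(1, 3, size=n_subjects)
        subj = np.repeat(np.arange(n_subjects), visits)
        x = rng.uniform(0, 10, size=subj.size)
        u = rng.normal(0, 1.5, size=n_subjects)
        y = 1.0 + u[subj] + rng.normal(0, 1.0, size=subj.size)
        res = lmm_correlation(x, y, subj)
        rejections += res["p_value"] < alpha
    return {"type1_error": rejections / n_replicates, "n_replicates": n_replicates}
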