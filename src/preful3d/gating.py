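"""DC self-gating: respiratory waveform extraction, smoothing, de-drifting
and respiratory-state binning with weighted spoke sharing."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "RespiratoryWaveform",
    "PhaseBinning",
    "extract_dc",
    "smooth_waveform",
    "rescale_blocks",
    "bin_phases",
    "default_block_size",
]


@dataclass
class RespiratoryWaveform:
    raw: np.ndarray
    smooth: np.ndarray = None
    normalized: np.ndarray = None
    coil_index_used: int = 0
    block_size: int = 0


@dataclass
class PhaseBinning:
    n_states: int
    membership: list        # per state: list of (spoke_index, weight)
    shared_fraction: float
    state_amplitude: np.ndarray  # per state, increasing, in [0, 1]

    def spoke_arrays(self, state: int):
        m = self.membership[state]
        idx = np.array([s for s, _ in m], dtype=np.int64)
        w = np.array([w for _, w in m], dtype=np.float64)
        return idx, w


def extract_dc(acq, n_points: int = 5, coil="auto") -> RespiratoryWaveform:
    """Per-spoke mean magnitude of the first ``n_points`` readout samples.

    With ``coil="auto"`` the coil whose candidate waveform carries the most
    spectral power in the 0.1-0.5 Hz respiratory band is selected.
    """
    if n_points > acq.n_readout:
        raise ValueError("n_points exceeds readout length")
    mags = np.abs(acq.kdata[:, :n_points, :]).mean(axis=1)  # (n_spokes, n_coils)
    if coil == "auto":
        dt = float(np.median(np.diff(acq.timestamp_s))) if acq.n_spokes > 1 else 1.0
        freqs = np.fft.rfftfreq(acq.n_spokes, d=dt)
        band = (freqs >= 0.1) & (freqs <= 0.5)
        power = []
        for c in range(acq.n_coils):
            spec = np.abs(np.fft.rfft(mags[:, c] - mags[:, c].mean())) ** 2
            power.append(spec[band].sum() if band.any() else spec[1:].sum())
        coil = int(np.argmax(power))
    elif not 0 <= coil < acq.n_coils:
        raise ValueError(f"coil index {coil} out of range")
    return RespiratoryWaveform(raw=mags[:, coil], coil_index_used=int(coil))


def smooth_waveform(raw: np.ndarray, window: int = 51, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing; endpoints by polynomial fit on the
    truncated window (scipy ``interp`` mode)."""
    raw = np.asarray(raw, dtype=np.float64)
    if window % 2 == 0 or window <= polyorder:
        raise ValueError("window must be odd and > polyorder")
    if window > raw.size:
        raise ValueError("window longer than the waveform")
    return savgol_filter(raw, window, polyorder, mode="interp")


def default_block_size(n_spokes: int) -> int:
    """Desk-scale analogue of the 5000-spoke rescaling increment."""
    return max(n_spokes // 8, 500)


def rescale_blocks(smooth: np.ndarray, block_size: int = 5000) -> np.ndarray:
    """Min-max rescale to [0, 1] within consecutive blocks (drift removal).
    A constant block maps to 0.5 everywhere."""
    if block_size < 2:
        raise ValueError("block_size must be >= 2")
    x = np.asarray(smooth, dtype=np.float64)
    out = np.empty_like(x)
    for start in range(0, x.size, block_size):
        blk = x[start : start + block_size]
        lo, hi = blk.min(), blk.max()
        out[start : start + block_size] = 0.5 if hi == lo else (blk - lo) / (hi - lo)
    return out


def bin_phases(
    normalized: np.ndarray,
    n_states: int = 30,
    shared_fraction: float = 0.30,
    decay_rate: float = 3.0,
) -> PhaseBinning:
    """Equal-count amplitude binning from expiration to inspiration with
    exponentially weighted spoke sharing between neighbouring states.

    Core spokes carry weight 1; each state additionally borrows the
    ``shared_fraction * core_size`` nearest spokes from each neighbouring
    bin with weight ``exp(-decay_rate * d)`` where ``d`` is the amplitude
    distance to the bin edge in units of the bin's amplitude width.
    """
    x = np.asarray(normalized, dtype=np.float64)
    if not 0.0 <= shared_fraction < 1.0:
        raise ValueError("shared_fraction must be in [0, 1)")
    if n_states < 2:
        raise ValueError("n_states must be >= 2")
    if x.size < n_states:
        raise ValueError("fewer spokes than states")
    order = np.argsort(x, kind="stable")
    cores = np.array_split(order, n_states)
    membership = [[(int(s), 1.0) for s in core] for core in cores]
    amp = np.array([x[core].mean() for core in cores])

    for s, core in enumerate(cores):
        width = max(x[core].max() - x[core].min(), 1.0 / n_states)
        n_share = int(round(shared_fraction * len(core)))
        for nb, edge_kind in ((s - 1, "lo"), (s + 1, "hi")):
            if not 0 <= nb < n_states or n_share == 0:
                continue
            neighbour = cores[nb]
            edge = x[core].min() if edge_kind == "lo" else x[core].max()
            # nearest-to-boundary spokes of the neighbouring core
            d = np.abs(x[neighbour] - edge)
            take = neighbour[np.argsort(d, kind="stable")[:n_share]]
            for sp in take:
                dist = abs(x[sp] - edge) / width
                membership[s].append((int(sp), float(np.exp(-decay_rate * dist))))
    return PhaseBinning(
        n_states=n_states,
        membership=membership,
        shared_fraction=shared_fraction,
        state_amplitude=amp,
    )


def gate(acq, n_states=10, shared_fraction=0.30, decay_rate=3.0,
         n_points=5, coil="auto", window=51, polyorder=3, block_size=None,
         invert=True):
    """Full gating chain: DC extraction -> smoothing -> block rescale -> binning.

    With ``invert`` (default) the normalized amplitude is flipped so that 0
    means expiration and 1 inspiration: parenchymal density — and hence the
    DC signal — is maximal at expiration.
    """
    wf = extract_dc(acq, n_points=n_points, coil=coil)
    window = min(window, wf.raw.size - (1 - wf.raw.size % 2))
    if window % 2 == 0:
        window -= 1
    wf.smooth = smooth_waveform(wf.raw, window=window, polyorder=polyorder)
    wf.block_size = block_size or default_block_size(wf.raw.size)
    wf.normalized = rescale_blocks(wf.smooth, wf.block_size)
    if invert:
        wf.normalized = 1.0 - wf.normalized
    binning = bin_phases(wf.normalized, n_states=n_states,
                         shared_fraction=shared_fraction, decay_rate=decay_rate)
    return wf, binning
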