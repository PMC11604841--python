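import numpy as np
import pytest

from conftest import brute_force_kmeans_1d
from preful3d.preful import (
    PhaseResolvedSeries,
    RVentMap,
    compute_rvent,
    interpolate_phases,
    vdp_kmeans,
)
from preful3d.recon import ImageSeries


def series_from_voxel_signal(amps, signal):
    """1-voxel-per-value helper: data shaped (n_states, len(signal), 1, 1)."""
    data = np.asarray(signal, dtype=float).T.reshape(len(amps), -1, 1, 1)
    return ImageSeries(data=data, state_amplitude=np.asarray(amps), voxel_size_mm=1.0)


class TestInterpolatePhases:
    def test_linear_signal_reproduced(self):
        amps = np.array([0.05, 0.2, 0.35, 0.55, 0.7, 0.9])
        signal = (2.0 - 0.8 * amps)[None, :]  # one voxel, linear in amplitude
        series = series_from_voxel_signal(amps, signal.T)
        out = interpolate_phases(series, n_out=15)
        expected = 2.0 - 0.8 * out.phase_grid
        np.testing.assert_allclose(out.data[:, 0, 0, 0], expected, rtol=1e-6)

    def test_constant_voxel(self):
        amps = np.linspace(0, 1, 8)
        series = series_from_voxel_signal(amps, np.full((8, 1), 3.7))
        out = interpolate_phases(series, n_out=15)
        np.testing.assert_allclose(out.data, 3.7, rtol=1e-9)

    def test_phase_grid_equidistant(self):
        amps = np.array([0.1, 0.3, 0.45, 0.6, 0.9])
        series = series_from_voxel_signal(amps, np.ones((5, 1)))
        out = interpolate_phases(series, n_out=15)
        assert out.phase_grid[0] == pytest.approx(0.1)
        assert out.phase_grid[-1] == pytest.approx(0.9)
        np.testing.assert_allclose(np.diff(out.phase_grid),
                                   np.diff(out.phase_grid)[0], rtol=1e-9)

    def test_bias_variance_tradeoff(self):
        rng = np.random.default_rng(0)
        amps = np.linspace(0, 1, 40)
        truth = np.sin(2 * np.pi * amps * 0.5)
        resid = {}
        for bw in (0.02, 0.12, 0.8):
            errs = []
            for _ in range(30):
                noisy = truth + rng.normal(0, 0.1, size=40)
                series = series_from_voxel_signal(amps, noisy[:, None])
                out = interpolate_phases(series, n_out=15, bandwidth=bw)
                ref = np.sin(2 * np.pi * out.phase_grid * 0.5)
                errs.append(((out.data[:, 0, 0, 0] - ref) ** 2).mean())
            resid[bw] = np.mean(errs)
        assert resid[0.12] < resid[0.02]   # variance dominates at tiny bw
        assert resid[0.12] < resid[0.8]    # bias dominates at huge bw

    def test_validation(self):
        amps = np.linspace(0, 1, 5)
        series = series_from_voxel_signal(amps, np.ones((5, 1)))
        with pytest.raises(ValueError):
            interpolate_phases(series, bandwidth=-1.0)
        two = series_from_voxel_signal([0.0, 1.0], np.ones((2, 1)))
        with pytest.raises(ValueError):
            interpolate_phases(two)


class TestComputeRvent:
    def _phases(self, s_ex, s_in):
        data = np.zeros((2, 1, 1, 1))
        data[0] = s_ex
        data[1] = s_in
        return PhaseResolvedSeries(data=data, phase_grid=np.array([0.0, 1.0]))

    def test_formula(self):
        rvent = compute_rvent(self._phases(1.0, 0.7), np.ones((1, 1, 1), bool))
        assert rvent.values[0, 0, 0] == pytest.approx(0.30)

    def test_equal_signals_zero(self):
        rvent = compute_rvent(self._phases(0.5, 0.5), np.ones((1, 1, 1), bool))
        assert rvent.values[0, 0, 0] == pytest.approx(0.0)

    def test_insp_denominator_convention(self):
        rvent = compute_rvent(self._phases(1.0, 0.8), np.ones((1, 1, 1), bool),
                              convention="insp-denominator")
        assert rvent.values[0, 0, 0] == pytest.approx(0.25)

    def test_invalid_voxel_flagged(self):
        phases = PhaseResolvedSeries(
            data=np.array([[[[0.0]], [[1.0]]], [[[0.0]], [[0.5]]]]),
            phase_grid=np.array([0.0, 1.0]))
        rvent = compute_rvent(phases, np.ones((2, 1, 1), bool))
        assert rvent.n_invalid == 1
        assert np.isnan(rvent.values[0, 0, 0])

    def test_end_expiration_by_signal_not_index(self):
        # phases ordered inspiration-first: max-signal detection must flip
        data = np.zeros((2, 1, 1, 1))
        data[0] = 0.7  # inspiration (low signal) first
        data[1] = 1.0
        phases = PhaseResolvedSeries(data=data, phase_grid=np.array([0.0, 1.0]))
        rvent = compute_rvent(phases, np.ones((1, 1, 1), bool))
        assert rvent.values[0, 0, 0] == pytest.approx(0.30)


class TestVdpKmeans:
    def _rvent(self, values):
        vals = np.asarray(values, dtype=float).reshape(-1, 1, 1)
        return RVentMap(values=vals, mask=np.ones(vals.shape, bool),
                        convention="exp-denominator")

    def test_two_level_toy_exact(self):
        rvent = self._rvent([0.30] * 90 + [0.00] * 10)
        res = vdp_kmeans(rvent, k=2)
        assert res.vdp_percent == pytest.approx(10.0, abs=1e-12)

    def test_matches_brute_force_on_small_toys(self):
        rng = np.random.default_rng(7)
        for k in (2, 3):
            for _ in range(10):
                vals = np.round(rng.uniform(0, 0.5, size=rng.integers(k + 2, 13)), 3)
                if np.unique(vals).size < k:
                    continue
                rvent = self._rvent(vals)
                res = vdp_kmeans(rvent, k=k, n_init=50)
                sorted_vals, labels, cost = brute_force_kmeans_1d(vals, k)
                # defect share from the brute-force optimum's lowest cluster
                lowest = sorted_vals[labels == labels[0]]
                expected = 100.0 * len(lowest) / len(vals)
                assert res.vdp_percent == pytest.approx(expected, abs=1e-9)

    def test_gaussian_mixture_recovery(self):
        rng = np.random.default_rng(1)
        means = [0.02, 0.15, 0.28, 0.40]
        weights = [0.1, 0.3, 0.3, 0.3]
        vals = np.concatenate([
            rng.normal(m, 0.01, size=int(w * 4000)) for m, w in zip(means, weights)])
        res = vdp_kmeans(self._rvent(vals), k=4)
        np.testing.assert_allclose(sorted(res.cluster_means), means, atol=0.02)
        assert res.vdp_percent == pytest.approx(10.0, abs=2.0)

    def test_outside_mask_ignored(self):
        vals = np.array([0.3] * 90 + [0.0] * 10 + [99.0] * 20)
        rvent = self._rvent(vals)
        rvent.mask[100:] = False
        res = vdp_kmeans(rvent, k=2)
        assert res.vdp_percent == pytest.approx(10.0)
        assert not res.defect_mask[100:].any()

    def test_determinism(self):
        rng = np.random.default_rng(2)
        vals = rng.uniform(size=500)
        a = vdp_kmeans(self._rvent(vals), k=4, seed=11)
        b = vdp_kmeans(self._rvent(vals), k=4, seed=11)
        np.testing.assert_array_equal(a.defect_mask, b.defect_mask)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            vdp_kmeans(self._rvent(np.full(50, 0.3)), k=2)
        with pytest.raises(ValueError):
            vdp_kmeans(self._rvent([0.1, 0.2]), k=4)

    def test_clean_defect_mask_removes_specks(self):
        from preful3d.preful import DefectResult, clean_defect_mask

        mask = np.ones((20, 20, 20), bool)
        defect = np.zeros((20, 20, 20), bool)
        defect[4:12, 4:12, 4:12] = True          # 512-voxel true defect
        defect[6:8, 6:8, 6:8] = False            # internal hole
        specks = [(15, 15, 15), (2, 17, 3), (17, 2, 17)]
        for s in specks:
            defect[s] = True                     # isolated single voxels
        res = DefectResult(defect_mask=defect,
                           vdp_percent=100 * defect.sum() / mask.sum())
        cleaned = clean_defect_mask(res, mask, min_component_vox=27)
        assert not any(cleaned.defect_mask[s] for s in specks)
        assert cleaned.defect_mask[6, 6, 6]      # hole filled
        assert cleaned.defect_mask[4:12, 4:12, 4:12].all()
        assert cleaned.vdp_percent == pytest.approx(100 * 512 / 8000)

    def test_modes_agree_on_full_volume(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0, 0.4, size=(6, 6, 6))
        rvent = RVentMap(values=vals, mask=np.ones(vals.shape, bool),
                         convention="exp-denominator")
        a = vdp_kmeans(rvent, k=3, mode="3D")
        b = vdp_kmeans(rvent, k=3, mode="2D")
        assert a.vdp_percent == pytest.approx(b.vdp_percent)
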