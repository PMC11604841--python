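import numpy as np
import pytest
from scipy import stats

from preful3d.compare import (
    REGION_NAMES,
    anova_bonferroni,
    bland_altman,
    dice,
    lmm_correlation,
    regional_vdp,
    slab_match,
    split_regions,
)


def random_mask(rng, shape=(16, 16, 16)):
    m = rng.uniform(size=shape) < 0.3
    m[0, 0, 0] = True  # never empty
    return m


class TestSplitRegions:
    def test_cuboid_octants(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[2:18, 2:18, 2:18] = True
        part = split_regions(mask, (10, 10, 10))
        counts = [(part.labels == i).sum() for i in range(1, 9)]
        np.testing.assert_allclose(counts, mask.sum() / 8, rtol=0.01)

    def test_partition_exact(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            mask = random_mask(rng)
            carina = tuple(rng.integers(2, 14, size=3))
            part = split_regions(mask, carina)
            assert ((part.labels > 0) == mask).all()
            total = sum((part.labels == i).sum() for i in range(1, 9))
            assert total == mask.sum()

    def test_carina_on_face_warns_empty(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[4:12, 4:12, 4:12] = True
        with pytest.warns(UserWarning, match="empty"):
            split_regions(mask, (4, 0, 8))

    def test_right_left_convention(self):
        mask = np.zeros((16, 16, 16), bool)
        mask[2, 8, 8] = True   # x < carina -> right lung
        mask[12, 8, 8] = True
        part = split_regions(mask, (8, 8, 8))
        assert REGION_NAMES[part.labels[2, 8, 8]].startswith("right")
        assert REGION_NAMES[part.labels[12, 8, 8]].startswith("left")

    def test_carina_outside_rejected(self):
        with pytest.raises(ValueError):
            split_regions(np.ones((8, 8, 8), bool), (99, 0, 0))

    def test_regional_recombination(self):
        rng = np.random.default_rng(1)
        for _ in range(100):
            mask = random_mask(rng, (12, 12, 12))
            defect = mask & (rng.uniform(size=mask.shape) < 0.2)
            part = split_regions(mask, tuple(rng.integers(1, 11, size=3)))
            table = regional_vdp(defect, part)
            global_vdp, n_total = table["global"]
            weighted = sum(v * n for name, (v, n) in table.items()
                           if name != "global" and n > 0)
            assert weighted / n_total == pytest.approx(global_vdp, abs=1e-10)


class TestDice:
    def test_identical(self):
        m = np.zeros((8, 8, 8), bool)
        m[2:5] = True
        assert dice(m, m) == (1.0, False)

    def test_disjoint(self):
        a = np.zeros((8, 8, 8), bool)
        b = np.zeros((8, 8, 8), bool)
        a[0], b[7] = True, True
        assert dice(a, b)[0] == 0.0

    def test_partial_overlap_arithmetic(self):
        a = np.zeros(10, bool)
        b = np.zeros(10, bool)
        a[:4] = True
        b[2:6] = True
        assert dice(a, b)[0] == 0.5

    def test_both_empty_flagged(self):
        val, flagged = dice(np.zeros(5, bool), np.zeros(5, bool))
        assert val == 1.0 and flagged

    def test_symmetry_and_padding_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            a = random_mask(rng, (8, 8, 8))
            b = random_mask(rng, (8, 8, 8))
            d1 = dice(a, b)[0]
            assert d1 == dice(b, a)[0]
            pad = [(2, 3), (0, 1), (4, 0)]
            assert dice(np.pad(a, pad), np.pad(b, pad))[0] == pytest.approx(d1)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(np.zeros(4, bool), np.zeros(5, bool))


class TestSlabMatch:
    def test_unit_slab_identity(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(size=(6, 8, 6))
        np.testing.assert_array_equal(slab_match(x, 1), x)

    def test_alternating_binary_tie_rule(self):
        col = np.zeros((1, 4, 1), bool)
        col[0, ::2, 0] = True
        pooled = slab_match(col, 2)
        assert pooled.all()  # 0.5 -> defect by the >= 0.5 rule

    def test_mean_preserved(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(size=(4, 8, 4))
        assert slab_match(x, 2).mean() == pytest.approx(x.mean())

    def test_truncated_slab_warns(self):
        with pytest.warns(UserWarning, match="truncated"):
            slab_match(np.ones((2, 5, 2)), 2)


class TestBlandAltman:
    def test_identical_series(self):
        x = np.array([1.0, 2.0, 3.0])
        bias, (lo, hi) = bland_altman(x, x)
        assert bias == 0.0 and lo == 0.0 and hi == 0.0

    def test_arithmetic_example(self):
        x = np.array([1.0, -1.0, 0.0])
        y = np.zeros(3)
        bias, (lo, hi) = bland_altman(x, y)
        assert bias == pytest.approx(0.0)
        assert lo == pytest.approx(-1.96)
        assert hi == pytest.approx(1.96)

    def test_translation_property(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        b0, (lo0, hi0) = bland_altman(x, y)
        b1, (lo1, hi1) = bland_altman(x + 3.5, y)
        assert b1 == pytest.approx(b0 + 3.5)
        assert hi1 - lo1 == pytest.approx(hi0 - lo0)

    def test_too_short(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestLmmCorrelation:
    def test_single_observation_matches_ols(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0, 20, size=12)
        y = 2.0 + 0.8 * x + rng.normal(0, 2.0, size=12)
        subjects = np.arange(12)
        res = lmm_correlation(x, y, subjects)
        ols = stats.linregress(x, y)
        assert res["r2_marginal"] == pytest.approx(ols.rvalue**2, abs=1e-3)
        assert res["df"] == pytest.approx(10, abs=0.5)
        assert res["p_value"] == pytest.approx(ols.pvalue, rel=0.05)

    def test_perfect_fit(self):
        x = np.arange(12, dtype=float)
        y = 2.0 * x
        res = lmm_correlation(x, y, np.arange(12) // 2)
        assert res["r2_marginal"] > 0.999
        assert res["p_value"] < 1e-6

    def test_slope_unbiased_and_type1_calibrated(self):
        rng = np.random.default_rng(7)
        n_subj, sigma_u, sigma_e = 12, 1.5, 1.0
        slopes, rejections = [], 0
        n_rep = 300
        for _ in range(n_rep):
            visits = rng.integers(1, 3, size=n_subj)
            subj = np.repeat(np.arange(n_subj), visits)
            x = rng.uniform(0, 10, size=subj.size)
            u = rng.normal(0, sigma_u, size=n_subj)
            y = 1.0 + 0.0 * x + u[subj] + rng.normal(0, sigma_e, size=subj.size)
            res = lmm_correlation(x, y, subj)
            slopes.append(res["slope"])
            rejections += res["p_value"] < 0.05
        assert np.mean(slopes) == pytest.approx(0.0, abs=0.03)
        assert 0.025 <= rejections / n_rep <= 0.075

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            lmm_correlation([1, 2], [1, 2], [0, 1])


class TestAnovaBonferroni:
    def test_identical_groups(self):
        g = {"a": [1.0, 2, 3], "b": [1.0, 2, 3], "c": [1.0, 2, 3]}
        f_p, pairwise = anova_bonferroni(g)
        assert f_p == pytest.approx(1.0)
        assert all(p == 1.0 for p in pairwise.values())
        assert len(pairwise) == 3

    def test_adjustment_factor(self):
        rng = np.random.default_rng(8)
        g = {k: rng.normal(size=6) for k in "abc"}
        _, pairwise = anova_bonferroni(g)
        for (k, p) in pairwise.items():
            m1, m2 = k.split(" vs ")
            _, p_raw = stats.ttest_ind(g[m1], g[m2])
            assert p == pytest.approx(min(1.0, 3 * p_raw))

    def test_f_statistic_hand_computed(self):
        groups = {"g1": [1.0, 2, 3], "g2": [1.0, 2, 3], "g3": [7.0, 8, 9]}
        f_p, _ = anova_bonferroni(groups)
        f_ref, p_ref = stats.f_oneway(*groups.values())
        # brute-force F on small integers
        data = [np.array(v) for v in groups.values()]
        grand = np.concatenate(data).mean()
        ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
        ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
        f_manual = (ss_between / 2) / (ss_within / 6)
        assert f_ref == pytest.approx(f_manual)
        assert f_p == pytest.approx(p_ref)

    def test_degenerate(self):
        with pytest.raises(ValueError):
            anova_bonferroni({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        with pytest.raises(ValueError):
            anova_bonferroni({"a": [1.0, 2.0]})
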