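"""Statistical layer: Bland-Altman, exact Wilcoxon, bootstrap correlations,
Henze-Zirkler, and the simulated visual ratings."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from wmhdrift.phantom import LesionSpec, PhantomConfig, evolve_followup, make_brain_template, plant_lesions
from wmhdrift.stats import (
    bland_altman,
    henze_zirkler,
    pearson_ci,
    simulate_fazekas,
    simulate_prins,
    spearman_bootstrap_ci,
    wilcoxon_signed_rank,
)

GRID = (64, 64, 12)


class TestBlandAltman:
    def test_identical_measurements(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.mean_difference == 0.0
        assert ba.loa_low == ba.loa_high == 0.0

    def test_hand_computed_three_pairs(self):
        # d = {1, 2, 1}: md = 1.3333, sd = 0.5774, limits [0.2017, 2.4650]
        ba = bland_altman([1.0, 3.0, 2.0], [2.0, 5.0, 3.0])
        assert ba.mean_difference == pytest.approx(1.3333, abs=1e-4)
        assert ba.sd_difference == pytest.approx(0.5774, abs=1e-4)
        assert ba.loa_low == pytest.approx(0.2017, abs=1e-4)
        assert ba.loa_high == pytest.approx(2.4650, abs=1e-4)

    def test_constant_shift_moves_mean_difference(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        y = x + rng.normal(size=20)
        ba = bland_altman(x, y)
        ba_shift = bland_altman(x, y + 3.0)
        assert ba_shift.mean_difference == pytest.approx(ba.mean_difference + 3.0)
        assert ba_shift.sd_difference == pytest.approx(ba.sd_difference)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


def brute_force_wilcoxon_p(d, alternative="greater"):
    """Exact p by enumerating all 2^n sign assignments (independent oracle)."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = len(d)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for s, r in zip(signs, ranks) if s))
    stats = np.asarray(stats)
    p_ge = (stats >= w_obs - 1e-12).mean()
    p_le = (stats <= w_obs + 1e-12).mean()
    if alternative == "greater":
        return p_ge
    if alternative == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


class TestWilcoxon:
    def test_all_positive_n5(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [0.0] * 5
        _, p_one = wilcoxon_signed_rank(a, b, alternative="greater")
        assert p_one == pytest.approx(1 / 32)
        _, p_two = wilcoxon_signed_rank(a, b)
        assert p_two == pytest.approx(2 / 32)

    def test_identical_samples(self):
        _, p = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert p == 1.0

    def test_swap_symmetry(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=12)
        b = rng.normal(size=12)
        _, p1 = wilcoxon_signed_rank(a, b)
        _, p2 = wilcoxon_signed_rank(b, a)
        assert p1 == pytest.approx(p2)

    @pytest.mark.parametrize("n", [4, 7, 10])
    @pytest.mark.parametrize("alternative", ["greater", "two-sided"])
    def test_exact_matches_brute_force(self, n, alternative):
        rng = np.random.default_rng(n)
        for _ in range(10):
            d = np.round(rng.normal(size=n), 1)
            d = d[d != 0]
            if len(d) == 0:
                continue
            _, p = wilcoxon_signed_rank(d, np.zeros(len(d)), alternative=alternative)
            assert p == pytest.approx(brute_force_wilcoxon_p(d, alternative), abs=1e-12)

    def test_matches_scipy_on_tie_free_data(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=15)
        b = rng.normal(size=15)
        _, p = wilcoxon_signed_rank(a, b)
        p_scipy = sps.wilcoxon(a, b, mode="exact").pvalue
        assert p == pytest.approx(p_scipy, abs=1e-10)

    def test_normal_approximation_bridges_exact(self):
        # at n = 25 the exact enumeration and the tie-corrected normal
        # approximation should agree closely
        rng = np.random.default_rng(9)
        a = rng.normal(0.3, 1.0, 25)
        b = np.zeros(25)
        _, p_exact = wilcoxon_signed_rank(a, b)
        import wmhdrift.stats as stats_module

        old = stats_module.EXACT_N_MAX
        try:
            stats_module.EXACT_N_MAX = 0
            _, p_norm = wilcoxon_signed_rank(a, b)
        finally:
            stats_module.EXACT_N_MAX = old
        assert abs(p_exact - p_norm) <= 0.02


class TestCorrelations:
    def test_monotone_gives_rho_one(self):
        x = np.arange(10.0)
        res = spearman_bootstrap_ci(x, x**3 + 1, B=200, seed=0)
        assert res.coefficient == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)
        res_neg = spearman_bootstrap_ci(x, -x, B=200, seed=0)
        assert res_neg.coefficient == pytest.approx(-1.0)

    def test_pearson_linear(self):
        x = np.arange(20.0)
        res = pearson_ci(x, 2 * x + 1, B=200, seed=0)
        assert res.coefficient == pytest.approx(1.0)
        res_neg = pearson_ci(x, -x, B=200, seed=0)
        assert res_neg.coefficient == pytest.approx(-1.0)

    def test_pearson_affine_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = pearson_ci(x, y, B=50, seed=1).coefficient
        r2 = pearson_ci(3 * x + 5, 0.5 * y - 2, B=50, seed=1).coefficient
        assert r1 == pytest.approx(r2)

    def test_ci_covers_zero_for_independent_data(self):
        rng = np.random.default_rng(3)
        covered = 0
        reps = 60
        for i in range(reps):
            x = rng.standard_normal(100)
            y = rng.standard_normal(100)
            res = spearman_bootstrap_ci(x, y, B=200, seed=i)
            if res.ci_low <= 0.0 <= res.ci_high:
                covered += 1
        assert covered / reps >= 0.90

    def test_ci_shrinks_with_n(self):
        rng = np.random.default_rng(4)
        widths = {}
        for n in (50, 200):
            w = []
            for i in range(20):
                x = rng.standard_normal(n)
                y = 0.4 * x + rng.standard_normal(n)
                res = spearman_bootstrap_ci(x, y, B=200, seed=i)
                w.append(res.ci_high - res.ci_low)
            widths[n] = np.mean(w)
        assert widths[200] < widths[50]

    def test_outlier_removal_flag(self):
        rng = np.random.default_rng(6)
        x = np.concatenate([rng.normal(size=30), [40.0]])
        y = np.concatenate([rng.normal(size=30), [-40.0]])
        res = spearman_bootstrap_ci(x, y, B=100, seed=0, remove_outliers=True)
        assert res.outliers_removed
        assert res.n < 31

    def test_constant_input_raises(self):
        with pytest.raises(ValueError):
            pearson_ci(np.ones(10), np.arange(10.0), B=50, seed=0)


class TestHenzeZirkler:
    def test_affine_invariance(self):
        rng = np.random.default_rng(7)
        X = rng.multivariate_normal([0, 0], [[1, 0.3], [0.3, 1]], size=60)
        A = np.array([[2.0, 0.5], [0.0, 1.5]])
        hz1, _ = henze_zirkler(X)
        hz2, _ = henze_zirkler(X @ A.T + [3.0, -1.0])
        assert hz1 == pytest.approx(hz2, abs=1e-8)

    def test_power_against_lognormal(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 40
        for _ in range(reps):
            X = np.exp(rng.standard_normal((50, 2)))
            _, p = henze_zirkler(X)
            rejections += p < 0.05
        assert rejections / reps >= 0.5

    def test_validation(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ValueError):
            henze_zirkler(rng.normal(size=(3, 5)))  # n <= d
        X = rng.normal(size=(20, 1)) @ np.ones((1, 2))  # rank deficient
        with pytest.raises(ValueError):
            henze_zirkler(X)


def _ground_truth(plan, seed=21, atrophy=0):
    cfg = PhantomConfig(
        grid_shape=GRID, seed=seed, lesion_plan=plan, stroke_prob=0.0,
        atrophy_rate=atrophy, bias_amplitude=0.0,
    )
    gt = plant_lesions(make_brain_template(cfg, seed), cfg, seed)
    return evolve_followup(gt, cfg, seed + 1), cfg


class TestRatings:
    def test_empty_wmh_scores_zero(self):
        gt, _ = _ground_truth([])
        assert simulate_fazekas(gt, "baseline") == (0, 0)

    def test_scores_nondecreasing_in_lesion_volume(self):
        scores = []
        for ml in (0.5, 2.0, 6.0):
            plan = [LesionSpec(kind="deep", tissue="intense", change="static", target_ml=ml)]
            gt, _ = _ground_truth(plan)
            scores.append(simulate_fazekas(gt, "baseline")[1])
        assert scores == sorted(scores)
        assert scores[0] >= 1

    def test_prins_identity_timepoints(self):
        plan = [LesionSpec(kind="deep", tissue="intense", change="static", target_ml=2.0)]
        gt, _ = _ground_truth(plan)
        rec = simulate_prins(gt, "s")
        assert rec.prins_total == 0
        assert all(v == 0 for v in rec.prins_region_scores.values())

    def test_prins_detects_regional_growth(self):
        plan = [
            LesionSpec(kind="deep", tissue="intense", change="grow", target_ml=1.0, grow_ml=3.0)
        ]
        gt, _ = _ground_truth(plan)
        rec = simulate_prins(gt, "s")
        assert rec.prins_total >= 1
        assert sum(v == 1 for v in rec.prins_region_scores.values()) >= 1

    def test_prins_total_bounds_and_determinism(self):
        plan = [
            LesionSpec(kind="periventricular", tissue="intense", change="disappear",
                       target_ml=2.0, ex_vacuo=False)
        ]
        gt, _ = _ground_truth(plan)
        r1 = simulate_prins(gt, "s")
        r2 = simulate_prins(gt, "s")
        assert r1 == r2
        R = len(r1.prins_region_scores)
        assert -R <= r1.prins_total <= R
        assert r1.prins_total == sum(r1.prins_region_scores.values())
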