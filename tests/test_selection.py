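import numpy as np
import pytest

from semgbench.errors import ConfigurationError, DivergenceError
from semgbench.selection import (GridSpec, RPropSettings, grid_search,
                                 rprop_minimize,
                                 sequential_complexity_selection, svm_c_grid,
                                 svm_gamma_grid, two_stage_svm_search)
from conftest import gaussian_blobs, make_split


def quadratic(center):
    center = np.asarray(center, float)

    def fg(theta):
        d = theta - center
        return float(d @ d), 2 * d
    return fg


class TestRProp:
    def test_scalar_quadratic_minimum(self):
        theta, trace = rprop_minimize(quadratic([3.0]), np.array([0.0]),
                                      RPropSettings(max_iterations=500,
                                                    cost_tolerance=0.0))
        assert abs(theta[0] - 3.0) < 1e-6
        assert trace[-1] <= trace[0]

    def test_stationary_point_is_fixed(self):
        theta, trace = rprop_minimize(quadratic([2.0, -1.0]),
                                      np.array([2.0, -1.0]))
        np.testing.assert_array_equal(theta, [2.0, -1.0])

    def test_zero_iterations_returns_start(self):
        theta, trace = rprop_minimize(quadratic([5.0]), np.array([1.0]),
                                      RPropSettings(max_iterations=0))
        assert theta[0] == 1.0 and len(trace) == 1

    def test_beats_fixed_step_gradient_descent_when_ill_conditioned(self):
        rng = np.random.default_rng(0)
        scales = np.logspace(0, 4, 10)  # condition number 1e8
        center = rng.normal(size=10)

        def fg(theta):
            d = theta - center
            return float(np.sum(scales * d * d)), 2 * scales * d

        theta0 = np.zeros(10)
        n_iter = 200
        theta, trace = rprop_minimize(
            fg, theta0, RPropSettings(max_iterations=n_iter, cost_tolerance=0.0))

        # plain GD at its best stable fixed step (just under 1/L), 10x budget
        gd = theta0.copy()
        step = 0.99 / (2 * scales.max())
        for _ in range(10 * n_iter):
            gd = gd - step * fg(gd)[1]
        assert trace[-1] <= fg(gd)[0]

    def test_path_invariant_to_positive_cost_scaling(self):
        settings = RPropSettings(max_iterations=60, cost_tolerance=0.0)
        fg = quadratic([1.0, -2.0, 0.5])

        def scaled(theta):
            c, g = fg(theta)
            return 7.3 * c, 7.3 * g

        t1, _ = rprop_minimize(fg, np.zeros(3), settings)
        t2, _ = rprop_minimize(scaled, np.zeros(3), settings)
        np.testing.assert_array_equal(t1, t2)

    def test_divergence_raises_with_iteration(self):
        def fg(theta):
            return float(np.exp(theta[0])), np.array([np.exp(theta[0])])

        with pytest.raises(DivergenceError):
            rprop_minimize(lambda t: (np.nan, np.zeros(1)), np.zeros(1))

    def test_invalid_settings(self):
        with pytest.raises(ConfigurationError):
            RPropSettings(eta_plus=0.9)
        with pytest.raises(ConfigurationError):
            RPropSettings(delta0=1e-9)


class TestGrids:
    def test_c_grid_matches_doubling_oracle(self):
        grid = svm_c_grid()
        oracle = []
        v = 0.01
        while v <= 1e4:
            oracle.append(v)
            v *= 2
        np.testing.assert_allclose(grid, oracle)
        assert grid[0] == 0.01 and grid[-1] <= 1e4 and 2 * grid[-1] > 1e4
        np.testing.assert_allclose(grid[1:] / grid[:-1], 2.0)

    def test_gamma_grid_excludes_zero(self):
        grid = svm_gamma_grid()
        assert grid[0] == pytest.approx(0.1) and grid[-1] == pytest.approx(50.0)
        assert np.all(grid > 0)
        np.testing.assert_allclose(np.diff(grid), 0.1)

    def test_gridspec_validation(self):
        with pytest.raises(ConfigurationError):
            GridSpec(svm_c=())
        with pytest.raises(ConfigurationError):
            GridSpec(svm_c=(1.0, 0.5))


class TestGridSearch:
    def separable_split(self, seed=0):
        rng = np.random.default_rng(seed)
        X, y = gaussian_blobs(rng, [[-2, -2], [2, 2]], 30, scale=0.4)
        Xc, yc = gaussian_blobs(rng, [[-2, -2], [2, 2]], 10, scale=0.4)
        return make_split(X, y, Xc, yc)

    def test_single_configuration_returned(self):
        split = self.separable_split()
        res = grid_search("svm", split,
                          GridSpec(svm_c=(1.0,), svm_gamma=(0.5,)), seed=0)
        assert res.best_config == {"C": 1.0, "gamma": 0.5}
        assert len(res.table) == 1

    def test_tie_prefers_fewer_parameters(self):
        # trivially separable: both MLP widths reach CV F1 = 100 -> smaller net
        split = self.separable_split()
        res = grid_search("mlp", split,
                          GridSpec(mlp_layers=(1,), mlp_neurons=(8, 2)),
                          seed=0, rprop=RPropSettings(max_iterations=300))
        scores = [row["cv_f1"] for row in res.table]
        assert scores[0] == scores[1] == 100.0
        assert res.best_config["n_neurons"] == 2

    def test_failing_configuration_recorded_and_skipped(self):
        split = self.separable_split()
        with pytest.warns(UserWarning, match="failed"):
            res = grid_search("nlr", split,
                              GridSpec(nlr_degrees=(9, 1)), seed=0,
                              rprop=RPropSettings(max_iterations=50))
        assert res.table[0]["cv_f1"] is None
        assert res.best_config == {"degree": 1}

    def test_two_stage_svm_search_returns_valid_config(self):
        split = self.separable_split()
        res = two_stage_svm_search(split, seed=0,
                                   coarse_c=(0.1, 1.0, 10.0),
                                   coarse_gamma=(0.5, 5.0))
        assert res.best_config["C"] > 0 and res.best_config["gamma"] > 0
        assert res.best_cv_f1 == 100.0


class TestSequentialSelection:
    def test_identical_scores_select_simplest(self):
        scores = np.full((10, 5), 80.0)
        level, log = sequential_complexity_selection(scores)
        assert level == 0
        assert all(not row["significant"] for row in log)

    def test_jump_then_plateau_selects_jump_level(self):
        # subject random effects are shared across levels (they cancel in the
        # pairing); the level effect jumps at index 3 and then plateaus
        rng = np.random.default_rng(0)
        n, levels = 30, 6
        base = rng.normal(70, 5.0, size=(n, 1))
        jump = np.array([0, 0, 0, 15.0, 15, 15])
        scores = base + jump[None, :]
        with pytest.warns(UserWarning):  # zero differences on the plateaus
            level, _ = sequential_complexity_selection(scores)
        assert level == 3
        # independent oracle: exhaustive pairwise tests confirm the plateau
        from semgbench.compare import wilcoxon_signed_rank
        for j in range(4, levels):
            with pytest.warns(UserWarning):
                _, p = wilcoxon_signed_rank(scores[:, j], scores[:, 3])
            assert p >= 0.05

    def test_monotone_large_effects_select_last_level(self):
        rng = np.random.default_rng(1)
        n, levels = 30, 5
        base = rng.normal(70, 5.0, size=(n, 1))
        scores = base + np.arange(levels)[None, :] * 10.0
        level, log = sequential_complexity_selection(scores)
        assert level == levels - 1
        assert all(row["significant"] for row in log)

    def test_plateau_stable_under_subject_noise(self):
        # per-subject noise of smaller scale than the jump never promotes
        # past the plateau (level effects are fixed, subjects vary)
        jump = np.array([0, 0, 12.0, 12.0, 12.0])
        for seed in range(20):
            rng = np.random.default_rng(seed)
            scores = 70 + jump[None, :] + rng.normal(0, 0.8, size=(30, 1))
            with pytest.warns(UserWarning):
                level, _ = sequential_complexity_selection(scores)
            assert level == 2

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ConfigurationError):
            sequential_complexity_selection(np.zeros((4, 3)))
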