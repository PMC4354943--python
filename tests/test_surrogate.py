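import numpy as np
import pytest
import scipy.stats

from chromdoe import defectsim, designs, surrogate
from chromdoe.errors import ConfigurationError, DataError
from conftest import make_constant_model


class TestLatinHypercube:
    @pytest.mark.parametrize("seed", [0, 1, 7, 123])
    def test_one_point_per_stratum_for_every_seed(self, seed):
        n = 80
        pts = surrogate.latin_hypercube(n, 3, seed=seed)
        for col in pts.T:
            strata = np.floor(col * n).astype(int)
            assert sorted(strata) == list(range(n))

    def test_two_point_one_dimensional_case(self):
        pts = surrogate.latin_hypercube(2, 1, seed=3).ravel()
        lo, hi = sorted(pts)
        assert 0.0 <= lo < 0.5 <= hi < 1.0

    def test_seed_determinism(self):
        a = surrogate.latin_hypercube(20, 2, seed=5)
        b = surrogate.latin_hypercube(20, 2, seed=5)
        c = surrogate.latin_hypercube(20, 2, seed=6)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_custom_bounds(self):
        pts = surrogate.latin_hypercube(10, 2, bounds=[(-1, 1), (5, 6)], seed=0)
        assert pts[:, 0].min() >= -1 and pts[:, 0].max() <= 1
        assert pts[:, 1].min() >= 5 and pts[:, 1].max() <= 6

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            surrogate.latin_hypercube(10, 2, bounds=[(0, 1), (2, 2)], seed=0)
        with pytest.raises(ConfigurationError):
            surrogate.latin_hypercube(1, 2, seed=0)


class TestGPSurrogate:
    def test_interpolates_training_points_noiseless(self):
        X = surrogate.latin_hypercube(25, 2, seed=1)
        y = np.sin(3 * X[:, 0]) + X[:, 1] ** 2
        gp = surrogate.fit_gp(X, y, seed=0)
        pred = gp.predict(X)
        # reproduction at training inputs is limited by the fitted nugget
        # (noise floor 1e-8, i.e. std 1e-4 on the normalized scale)
        assert np.allclose(pred, y, atol=1e-4 * max(1.0, np.abs(y).max()))
        assert gp.nugget <= 1e-7

    def test_linear_function_recovery_on_held_out_grid(self):
        X = surrogate.latin_hypercube(40, 2, seed=2)
        y = 3.0 + 2.0 * X[:, 0]
        gp = surrogate.fit_gp(X, y, seed=0)
        axis = np.linspace(0.05, 0.95, 5)
        grid = np.stack(np.meshgrid(axis, axis, indexing="ij"), -1).reshape(-1, 2)
        assert np.allclose(gp.predict(grid), 3.0 + 2.0 * grid[:, 0], atol=1e-3)

    def test_constant_surface_reduces_to_constant_mean(self):
        X = surrogate.latin_hypercube(20, 2, seed=3)
        gp = surrogate.fit_gp(X, np.full(20, 4.2), seed=0)
        probe = surrogate.latin_hypercube(10, 2, seed=9)
        assert np.allclose(gp.predict(probe), 4.2, atol=1e-6)

    def test_row_permutation_leaves_predictions_unchanged(self):
        X = surrogate.latin_hypercube(30, 2, seed=4)
        y = X[:, 0] ** 2 + 0.5 * X[:, 1]
        gp = surrogate.fit_gp(X, y, seed=0)
        perm = np.random.default_rng(0).permutation(30)
        a = gp.refit_fixed(X, y)
        b = gp.refit_fixed(X[perm], y[perm])
        probe = surrogate.latin_hypercube(15, 2, seed=11)
        assert np.allclose(a.predict(probe), b.predict(probe), atol=1e-10)

    def test_predictive_std_zero_at_training_positive_away(self):
        X = surrogate.latin_hypercube(20, 2, seed=5)
        y = X[:, 0] + np.sin(2 * X[:, 1])
        gp = surrogate.fit_gp(X, y, seed=0)
        _, std_train = gp.predict(X, return_std=True)
        assert std_train.max() < 1e-2
        far = np.array([[3.0, 3.0]])
        _, std_far = gp.predict(far, return_std=True)
        assert std_far[0] > std_train.max()

    def test_too_few_points_rejected(self):
        with pytest.raises(DataError):
            surrogate.fit_gp(np.zeros((4, 2)), np.zeros(4))

    def test_non_finite_response_rejected(self):
        X = surrogate.latin_hypercube(10, 2, seed=0)
        y = np.zeros(10)
        y[3] = np.nan
        with pytest.raises(DataError):
            surrogate.fit_gp(X, y)


class TestJackknife:
    def test_smooth_surface_slope_near_one(self):
        X = surrogate.latin_hypercube(30, 2, seed=6)
        y = scipy.stats.norm.cdf(2 * (X[:, 0] - 0.5)) + 0.3 * X[:, 1]
        preds = surrogate.jackknife_predictions(X, y, seed=0)
        slope = scipy.stats.linregress(preds, y).slope
        assert 0.8 <= slope <= 1.2

    def test_pure_noise_collapses_to_mean(self):
        rng = np.random.default_rng(8)
        X = surrogate.latin_hypercube(30, 2, seed=7)
        y = rng.normal(size=30)
        preds = surrogate.jackknife_predictions(X, y, seed=0)
        # predictions hug the mean: their spread is far below the data spread
        assert np.std(preds) < 0.5 * np.std(y)

    def test_minimum_size(self):
        X = surrogate.latin_hypercube(6, 1, seed=0)
        y = X[:, 0] ** 2
        assert surrogate.jackknife_predictions(X, y, seed=0).shape == (6,)
        with pytest.raises(DataError):
            surrogate.jackknife_predictions(X[:5], y[:5], seed=0)


class TestMinimizeDr:
    def test_recovers_known_minimum(self):
        X = surrogate.latin_hypercube(60, 2, seed=9)
        dr = (X[:, 0] - 0.3) ** 2 + (X[:, 1] - 0.7) ** 2 + 0.01
        gp = surrogate.fit_gp(X, np.log10(dr), seed=0)
        argmin, pred_dr = surrogate.minimize_dr(gp, [(0, 1), (0, 1)], seed=0)
        assert np.allclose(argmin, [0.3, 0.7], atol=0.05)
        assert pred_dr == pytest.approx(0.01, rel=0.5)

    def test_monotone_surface_minimized_at_boundary(self):
        X = surrogate.latin_hypercube(40, 2, seed=10)
        y = X[:, 0] + X[:, 1]
        gp = surrogate.fit_gp(X, y, seed=0)
        argmin, _ = surrogate.minimize_dr(gp, [(0, 1), (0, 1)], seed=0)
        assert np.allclose(argmin, [0.0, 0.0], atol=0.05)


class TestSimulationExperiment:
    def _models_and_spec(self):
        model = make_constant_model(
            0.0, 0.5, factor_names=("x1", "x2"),
            coefficients={"x1": 1.0, "x2": 0.5},
        )
        specs = [
            designs.FactorSpec("x1", "", -1.0, 0.0, 1.0, sim_sd=0.1),
            designs.FactorSpec("x2", "", -1.0, 0.0, 1.0, sim_sd=0.1),
        ]
        spec = defectsim.DefectSpec(
            factor_specs=specs,
            setpoint=np.zeros(2),
            spec_limits={"y": (None, 1.0)},
            n_runs=400,
            seed=0,
        )
        return {"y": model}, spec

    def test_experiment_shapes_and_floor(self):
        models, spec = self._models_and_spec()
        exp = surrogate.run_simulation_experiment(
            models, spec, n_points=20, runs_per_point=400, seed=1
        )
        assert exp.dr.shape == (20,)
        assert exp.jackknife.shape == (20,)
        assert np.all(np.isfinite(exp.log10_dr))
        assert exp.dr_floor == pytest.approx(0.5 / 400)
        assert np.all(exp.log10_dr >= np.log10(exp.dr_floor) - 1e-12)

    def test_optimum_improves_on_worst_sampled_point(self):
        models, spec = self._models_and_spec()
        exp = surrogate.run_simulation_experiment(
            models, spec, n_points=20, runs_per_point=400, seed=1
        )
        # the exceedance of y = x1 + 0.5 x2 above 1 shrinks toward low x1/x2,
        # so the proposed optimum must beat the median sampled DR
        final = defectsim.simulate_defect_rate(
            models, spec.with_setpoint(exp.optimum_actual)
        )
        assert final.overall_dr <= np.median(exp.dr)
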