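import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sparserules.experiments import brute_force_best_gain, full_enumeration_objective
from sparserules.optimizer import (
    DualWeights,
    FitConfig,
    RuleModel,
    UnfittableError,
    double_hinge,
    find_best_rule,
    fit,
    objective,
    solve_master,
)
from sparserules.rulespace import (
    ConjunctionRule,
    Dataset,
    InvalidConfigurationError,
    build_cutpoints,
    build_transactions,
)
from sparserules.synthdata import score_recovery


class TestDoubleHinge:
    @pytest.mark.parametrize(
        "z, d, expected",
        [
            (1.2, 0.3, 0.0),  # zero branch
            (0.0, 0.25, 1.0),  # all branches meet at z=0
            (-1.0, 0.4, 2.5),  # 1 - (0.6/0.4)*(-1)
            (0.5, 0.5, 0.5),  # 1-z branch, ordinary hinge
            (1.0, 0.4, 0.0),  # kink at z=1
        ],
    )
    def test_piecewise_values(self, z, d, expected):
        assert double_hinge(z, d) == pytest.approx(expected)

    def test_equals_hinge_at_half(self):
        z = np.linspace(-3, 3, 201)
        np.testing.assert_allclose(double_hinge(z, 0.5), np.maximum(0.0, 1.0 - z))

    @pytest.mark.parametrize("d", [0.5, 0.48, 0.4])
    def test_continuity_at_kinks(self, d):
        eps = 1e-9
        for z0 in (0.0, 1.0):
            lo, hi = double_hinge(z0 - eps, d), double_hinge(z0 + eps, d)
            assert abs(lo - hi) < 1e-6

    def test_negative_slope_steepens_as_d_decreases(self):
        z = -0.7
        losses = [double_hinge(z, d) for d in (0.5, 0.48, 0.4, 0.2)]
        assert all(a < b for a, b in zip(losses, losses[1:]))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        st.floats(-5, 5),
        st.floats(-5, 5),
        st.floats(0.01, 0.5),
    )
    def test_nonincreasing_in_z(self, z1, z2, d):
        lo, hi = sorted((z1, z2))
        assert double_hinge(hi, d) <= double_hinge(lo, d) + 1e-12

    @pytest.mark.parametrize("d", [0.0, -0.1, 0.6])
    def test_invalid_rejection_cost(self, d):
        with pytest.raises(InvalidConfigurationError):
            double_hinge(0.0, d)


def _bias_only_model(bias, cfg, p=2):
    cuts = build_cutpoints(np.random.default_rng(0).random((4, p)), cfg.bins)
    return RuleModel(
        rules=[], weights=np.zeros(0), bias=bias, cutpoints=cuts, config=cfg,
        feature_names=[f"x{j}" for j in range(p)],
    )


class TestObjective:
    def test_empty_model_loss_is_cost_weighted_count(self, random_dataset):
        cfg = FitConfig(C_pos=1.3, C_neg=0.7, d=0.5)
        model = _bias_only_model(0.0, cfg, p=random_dataset.p)
        n_pos = int(np.sum(random_dataset.y == 1))
        n_neg = random_dataset.n - n_pos
        assert objective(model, random_dataset, cfg) == pytest.approx(
            1.3 * n_pos + 0.7 * n_neg
        )

    def test_two_sample_hand_evaluation(self):
        # one rule h(x)=I(x0 >= 0.5) active on both samples, a=0.5, b=0:
        # y=+1 margin 0.5 -> phi=0.5; y=-1 margin -0.5 -> phi=1.5 (d=0.5)
        # objective = |0.5| + 1*0.5 + 1*1.5 = 2.5
        data = Dataset(np.array([[0.9], [0.8]]), np.array([1, -1]))
        cfg = FitConfig(C_pos=1.0, C_neg=1.0, d=0.5)
        rule = ConjunctionRule.from_dict({0: (0.5, np.inf)})
        model = RuleModel(
            rules=[rule], weights=np.array([0.5]), bias=0.0,
            cutpoints=build_cutpoints(data.X, 2), config=cfg, feature_names=["x0"],
        )
        assert objective(model, data, cfg) == pytest.approx(2.5)


class TestSolveMaster:
    def test_zero_columns_bias_only(self):
        y = np.array([1, 1, -1])
        cfg = FitConfig(C_pos=1.0, C_neg=1.0, d=0.5)
        a, b, duals, obj = solve_master([], y, cfg)
        assert a.size == 0
        # objective must equal the direct primal evaluation at the returned bias
        direct = 2 * double_hinge(b, 0.5) + double_hinge(-b, 0.5)
        assert obj == pytest.approx(direct, abs=1e-7)

    def test_separating_column_gets_weight_and_zero_loss(self):
        # h=[1,1,0,0] vs y=[1,1,-1,-1]: optimum a=2, b=-1, objective 2
        y = np.array([1, 1, -1, -1])
        col = np.array([1.0, 1.0, 0.0, 0.0])
        cfg = FitConfig(C_pos=100.0, C_neg=100.0, d=0.5)
        a, b, duals, obj = solve_master([col], y, cfg)
        assert a[0] == pytest.approx(2.0, abs=1e-6)
        assert b == pytest.approx(-1.0, abs=1e-6)
        assert obj == pytest.approx(2.0, abs=1e-5)

    def test_duplicated_column_same_objective(self, random_dataset):
        cfg = FitConfig(C=1.0, d=0.4)
        col = (random_dataset.X[:, 0] > 0.5).astype(float)
        _, _, _, obj1 = solve_master([col], random_dataset.y, cfg)
        _, _, _, obj2 = solve_master([col, col.copy()], random_dataset.y, cfg)
        assert obj1 == pytest.approx(obj2, abs=1e-7)

    def test_single_class_raises(self):
        with pytest.raises(UnfittableError):
            solve_master([], np.array([1, 1, 1]), FitConfig())

    @pytest.mark.parametrize("seed", range(5))
    def test_dual_weights_satisfy_derived_constraints(self, seed):
        """Numerical check of the effective dual weight u_i = alpha_i + k*beta_i.

        At the LP optimum the duals must satisfy the derived constraints:
        |sum_i y_i u_i h_j(x_i)| <= 1 per column, sum_i y_i u_i = 0 (free
        bias), and the box bound u_i <= k * C_{y_i}.
        """
        rng = np.random.default_rng(seed)
        n = 30
        y = rng.choice([-1, 1], n)
        y[:2] = [1, -1]
        cols = [(rng.random(n) > 0.5).astype(float) for _ in range(4)]
        cfg = FitConfig(C=float(rng.uniform(0.3, 2.0)), d=float(rng.uniform(0.2, 0.5)))
        a, b, duals, obj = solve_master(cols, y, cfg)
        u = duals.u
        assert np.all(u >= -1e-9)
        c_pos, c_neg = cfg.class_costs(y)
        C_i = np.where(y == 1, c_pos, c_neg)
        assert np.all(u <= cfg.k * C_i + 1e-6)
        assert abs(np.sum(y * u)) < 1e-6
        for col in cols:
            assert abs(np.sum(y * u * col)) <= 1.0 + 1e-6
        # strong duality: reported objective equals primal evaluation of (a, b)
        scores = sum(ai * ci for ai, ci in zip(a, cols)) + b
        z = y * scores
        phi = np.maximum(0.0, np.maximum(1.0 - z, 1.0 - cfg.k * z))
        primal = np.sum(np.abs(a)) + np.sum(C_i * phi)
        assert obj == pytest.approx(primal, abs=1e-6)


class TestFindBestRule:
    def test_zero_duals_returns_none(self, rng):
        X = rng.random((10, 2))
        trans = build_transactions(X, build_cutpoints(X, 3))
        y = np.ones(10, dtype=int)
        assert find_best_rule(trans, y, DualWeights(u=np.zeros(10)), 2) is None

    def test_single_heavy_sample(self, rng):
        X = rng.random((12, 2))
        trans = build_transactions(X, build_cutpoints(X, 3))
        y = np.ones(12, dtype=int)
        u = np.zeros(12)
        u[3] = 2.0
        found = find_best_rule(trans, y, DualWeights(u=u), 3)
        w = y.astype(float) * u
        assert found is not None
        assert found[1] == pytest.approx(brute_force_best_gain(trans, w, 3))

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 30, 4
        X = rng.random((n, p))
        trans = build_transactions(X, build_cutpoints(X, 3))
        w = rng.normal(0, 1.5, n)
        y = np.where(w >= 0, 1, -1)
        found = find_best_rule(trans, y, DualWeights(u=np.abs(w)), 3)
        reference = brute_force_best_gain(trans, w, 3)
        if found is None:
            assert reference <= 1.0 + 1e-6
        else:
            assert found[1] == pytest.approx(reference, abs=1e-9)


class TestFit:
    def test_recovers_planted_rule_separable(self, fitted_separable):
        model, data, truth = fitted_separable
        assert np.all(model.predict(data.X) == data.y)
        report = score_recovery(model, truth.rules)
        assert report["per_rule"][0]["jaccard"] >= 0.5

    def test_zero_iterations_gives_bias_only(self, random_dataset):
        cfg = FitConfig(max_iterations=0)
        model = fit(random_dataset, cfg)
        assert model.rules == [] and np.isfinite(model.bias)

    def test_objective_trajectory_nonincreasing(self, fitted_separable):
        model, _, _ = fitted_separable
        traj = np.array(model.objective_trajectory)
        assert np.all(np.diff(traj) <= 1e-6)

    def test_single_class_unfittable(self, rng):
        data = Dataset(rng.random((10, 2)), np.ones(10, dtype=int))
        with pytest.raises(UnfittableError):
            fit(data, FitConfig())

    def test_constant_features_unfittable(self):
        data = Dataset(np.ones((10, 2)), np.array([1, -1] * 5))
        with pytest.raises(UnfittableError):
            fit(data, FitConfig())

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_full_enumeration_lp(self, seed):
        """CG terminates at the global optimum of the fully materialized LP."""
        rng = np.random.default_rng(seed + 100)
        n, p = 20, 3
        X = rng.random((n, p))
        y = rng.choice([-1, 1], n)
        y[:2] = [1, -1]
        data = Dataset(X, y)
        cfg = FitConfig(C=1.0, d=0.35, bins=3, max_rule_order=2, max_iterations=200)
        model = fit(data, cfg)
        assert model.objective_trajectory[-1] == pytest.approx(
            full_enumeration_objective(data, cfg), abs=1e-6
        )

    def test_sparsity(self, fitted_separable):
        model, _, _ = fitted_separable
        assert len(model.rules) <= model.n_iterations
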