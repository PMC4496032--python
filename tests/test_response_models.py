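"""Polynomial surfaces, OLS fitting, gradient refinement and the BP network."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermogerm import germination_data as gd
from thermogerm import response_models as rm
from thermogerm import synthetic_data as sdata


def _grid_pairs(fn):
    return [
        (r.t_cool, r.t_warm, fn(r.t_cool, r.t_warm))
        for r in gd.half_grid_regimes()
    ]


class TestFeatures:
    @pytest.mark.parametrize(
        "t1,t2,expected",
        [
            (20, 30, [1, 20, 30, 400, 900, 600]),
            (0, 0, [1, 0, 0, 0, 0, 0]),
            (5, 40, [1, 5, 40, 25, 1600, 200]),
        ],
    )
    def test_quadratic_features(self, t1, t2, expected):
        assert rm.quadratic_features(t1, t2).tolist() == expected

    def test_quintic_feature_count_matches_enumeration(self):
        # independent count: bivariate monomials of total degree <= 5
        n = len([(i, j) for i in range(6) for j in range(6) if i + j <= 5])
        assert n == 21
        assert rm.quintic_features(3.0, 7.0).shape == (21,)

    def test_quintic_all_ones_at_unit_input(self):
        assert np.all(rm.quintic_features(1.0, 1.0) == 1.0)

    def test_quintic_ordering(self):
        feats = rm.quintic_features(2.0, 1.0)
        # index of (m, n): 1 + sum_{k<m}(k+1) + n
        assert feats[1 + 2 + 2] == 4.0  # m=2, n=2 -> T1^2 = 4
        assert feats[1 + 14 + 0] == 1.0  # m=5, n=0 -> T2^5 = 1


class TestOLS:
    def test_exact_recovery_of_known_quadratic(self):
        true = np.array([0.1, 0.02, -0.01, 1e-3, -2e-3, 5e-4])
        pairs = _grid_pairs(
            lambda a, b: float(rm.quadratic_features(a, b) @ true)
        )
        model = rm.fit_ols(pairs, degree=2)
        assert np.allclose(model.coefficients, true, atol=1e-8)

    def test_insufficient_data_rejected(self):
        pairs = _grid_pairs(lambda a, b: 0.5)[:5]
        with pytest.raises(ValueError, match="21"):
            rm.fit_ols(pairs, degree=5)

    def test_matches_normal_equations_oracle(self, rng):
        """lstsq solution equals the brute-force normal-equations solve."""
        for _ in range(10):
            t = rng.uniform(5, 40, size=(30, 2))
            y = rng.uniform(0, 1, size=30)
            pairs = np.column_stack([t, y])
            model = rm.fit_ols(pairs, degree=2)
            X, yy = rm.feature_matrix(pairs, 2)
            beta = np.linalg.solve(X.T @ X, X.T @ yy)
            assert np.allclose(model.coefficients, beta, atol=1e-6)

    def test_residuals_orthogonal_to_features(self, fixture_tables):
        pairs = gd.to_pairs(fixture_tables["Diva"])
        for degree in (2, 5):
            model = rm.fit_ols(pairs, degree)
            X, y = rm.feature_matrix(pairs, degree)
            resid = y - X @ np.asarray(model.coefficients)
            scaled = X / np.linalg.norm(X, axis=0)
            assert np.max(np.abs(scaled.T @ resid)) < 1e-6

    def test_nested_model_rmse_inequality(self, fixture_tables):
        """Quintic in-sample RMSE <= quadratic: the bases are nested."""
        for table in fixture_tables.values():
            pairs = gd.to_pairs(table)
            X2, y = rm.feature_matrix(pairs, 2)
            r = {}
            for degree in (2, 5):
                model = rm.fit_ols(pairs, degree)
                Xd, _ = rm.feature_matrix(pairs, degree)
                r[degree] = np.sqrt(
                    np.mean((Xd @ np.asarray(model.coefficients) - y) ** 2)
                )
            assert r[5] <= r[2] + 1e-12

    def test_predictions_clamped_only_at_interface(self, fixture_tables):
        pairs = gd.to_pairs(fixture_tables["Midnight II"])
        model = rm.fit_ols(pairs, degree=2)
        raw = model.evaluate(40.0, 40.0)
        assert raw < 0.0  # the quadratic dips below zero in the hot corner
        assert model.predict(40.0, 40.0) == 0.0


class TestPolynomialRefinement:
    def test_ols_start_is_a_fixed_point(self, fixture_tables):
        pairs = np.asarray(gd.to_pairs(fixture_tables["Diva"]))
        ols = rm.fit_ols(pairs, degree=2)
        refined = rm.refine_polynomial_bp(ols, pairs)
        X, y = rm.feature_matrix(pairs, 2)
        mse0 = np.mean((X @ np.asarray(ols.coefficients) - y) ** 2)
        mse1 = np.mean((X @ np.asarray(refined.coefficients) - y) ** 2)
        assert mse1 == pytest.approx(mse0, abs=1e-10)

    def test_descent_from_zero_start(self):
        true = np.array([0.2, 0.01, -0.02, 1e-3, -1e-3, 4e-4])
        pairs = _grid_pairs(
            lambda a, b: float(rm.quadratic_features(a, b) @ true)
        )
        zero = rm.PolynomialModel(degree=2, coefficients=(0.0,) * 6)
        refined = rm.refine_polynomial_bp(
            zero, pairs, rm.TrainConfig(learning_rate=0.1, epochs=500)
        )
        X, y = rm.feature_matrix(pairs, 2)
        mse0 = np.mean(y**2)
        mse1 = np.mean((X @ np.asarray(refined.coefficients) - y) ** 2)
        assert mse1 < mse0 * 0.1

    def test_zero_learning_rate_rejected(self):
        with pytest.raises(ValueError):
            rm.TrainConfig(learning_rate=0.0)


class TestNetworkForward:
    def test_zero_network_outputs_half(self):
        net = rm.NetworkModel(
            input_weights=((0.0, 0.0),) * 4,
            input_thresholds=(0.0,) * 4,
            output_weights=(0.0,) * 4,
            output_threshold=0.0,
        )
        assert rm.forward(net, 20.0, 30.0) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=200)
    @given(seed=st.integers(0, 10_000), t1=st.floats(0, 40), t2=st.floats(0, 40))
    def test_output_in_unit_interval(self, seed, t1, t2):
        net = rm.init_network(5, seed)
        assert 0.0 < rm.forward(net, t1, t2) < 1.0

    def test_input_scaling_contract(self):
        net = rm.init_network(3, 0)
        # manually scale: (40, 40) / 40 = (1, 1)
        w_in, b_in = np.asarray(net.input_weights), np.asarray(net.input_thresholds)
        hidden = 1.0 / (1.0 + np.exp(-(w_in @ np.array([1.0, 1.0]) - b_in)))
        z = hidden @ np.asarray(net.output_weights) - net.output_threshold
        assert rm.forward(net, 40.0, 40.0) == pytest.approx(1.0 / (1.0 + np.exp(-z)))


class TestTrainBP:
    def test_constant_target_converges(self):
        pairs = [(t1, t2, 0.5) for t1, t2, _ in _grid_pairs(lambda a, b: 0)][:10]
        net = rm.train_bp(
            rm.init_network(3, 1), pairs, rm.TrainConfig(epochs=500)
        )
        preds = [rm.forward(net, t1, t2) for t1, t2, _ in pairs]
        assert np.allclose(preds, 0.5, atol=0.01)

    def test_training_is_deterministic(self, fixture_tables):
        pairs = gd.to_pairs(fixture_tables["Midnight II"])
        cfg = rm.TrainConfig(epochs=200)
        a = rm.train_bp(rm.init_network(4, 42), pairs, cfg)
        b = rm.train_bp(rm.init_network(4, 42), pairs, cfg)
        assert a == b

    def test_training_mse_never_increases(self, fixture_tables):
        pairs = gd.to_pairs(fixture_tables["Leopard"])
        _, history = rm.train_bp(
            rm.init_network(6, 3), pairs, rm.TrainConfig(epochs=300),
            return_history=True,
        )
        assert np.all(np.diff(history) <= 1e-15)

    def test_capacity_on_noiseless_surface(self):
        """An H=8 network fits a smooth noiseless surface to RMSE < 0.05."""
        pairs = _grid_pairs(
            lambda a, b: float(sdata.true_surface(a, b, sdata.SurfaceParams()))
        )
        net = rm.train_bp(
            rm.init_network(8, 0), pairs, rm.TrainConfig(epochs=5000)
        )
        arr = np.asarray(pairs)
        pred = rm.forward(net, arr[:, 0], arr[:, 1])
        assert np.sqrt(np.mean((pred - arr[:, 2]) ** 2)) < 0.05


class TestSerialization:
    def test_polynomial_round_trip(self, fixture_tables):
        model = rm.fit_ols(gd.to_pairs(fixture_tables["Diva"]), degree=5)
        buf = io.StringIO()
        rm.save_model(model, buf, metadata={"cultivar": "Diva"})
        assert rm.load_model(io.StringIO(buf.getvalue())) == model

    def test_network_round_trip(self):
        net = rm.init_network(5, 17)
        buf = io.StringIO()
        rm.save_model(net, buf)
        assert rm.load_model(io.StringIO(buf.getvalue())) == net
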