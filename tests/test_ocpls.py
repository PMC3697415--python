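"""Uncentered PLS1, MCCV/PRESS, component selection, acceptance interval."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ocplsnir import (
    MCCVConfig,
    OCPLSModel,
    fit_ocpls,
    fit_uncentered_pls,
    mccv,
    predict,
    select_components,
)
from ocplsnir.exceptions import (
    ConfigError,
    ContaminationError,
    DimensionError,
    RankError,
)

from conftest import make_set


def krylov_prediction(X, n_components):
    """Independent oracle: PLS1 predictions equal least squares of the
    ones-response on the Krylov basis {X'1, (X'X)X'1, ...} mapped through X."""
    n, p = X.shape
    y = np.ones(n)
    K = np.empty((p, n_components))
    v = X.T @ y
    for j in range(n_components):
        K[:, j] = v / np.linalg.norm(v)
        v = X.T @ (X @ v)
    basis = X @ K
    beta, *_ = np.linalg.lstsq(basis, y, rcond=None)
    return basis @ beta


class TestUncenteredPls:
    def test_ones_column_gives_perfect_fit_with_one_component(self):
        rng = np.random.default_rng(0)
        # other columns orthogonal to the ones vector
        noise = rng.normal(size=(8, 4))
        noise -= noise.mean(axis=0)
        X = np.column_stack([np.ones(8), noise])
        b = fit_uncentered_pls(X, 1)
        assert np.allclose(X @ b, 1.0, atol=1e-10)

    @pytest.mark.parametrize("n_components", [1, 2, 3, 4, 5])
    def test_matches_krylov_least_squares_oracle(self, n_components):
        X = np.random.default_rng(42).normal(size=(8, 5))
        y_hat = X @ fit_uncentered_pls(X, n_components)
        expected = krylov_prediction(X, n_components)
        assert np.allclose(y_hat, expected, rtol=1e-8, atol=1e-10)

    def test_full_components_equal_ordinary_least_squares(self):
        X = np.random.default_rng(7).normal(size=(9, 5))
        y_hat = X @ fit_uncentered_pls(X, 5)
        ols = X @ np.linalg.pinv(X) @ np.ones(9)
        assert np.allclose(y_hat, ols, atol=1e-8)

    def test_rank_error_names_failing_component(self):
        rng = np.random.default_rng(1)
        X = np.outer(rng.normal(size=6), rng.normal(size=4))  # rank 1... x2
        X += np.outer(rng.normal(size=6), rng.normal(size=4))  # rank 2
        with pytest.raises(RankError, match="component 3"):
            fit_uncentered_pls(X, 3)

    def test_centering_would_destroy_the_fit(self):
        """Column-centered X makes every predictor orthogonal to the
        ones-response: the centered fit predicts ~0, never ~1 — the reason
        the model must stay uncentered."""
        X = np.random.default_rng(3).normal(size=(10, 6)) + 2.0
        Xc = X - X.mean(axis=0)
        b = fit_uncentered_pls(X, 3)
        assert np.allclose(X @ b, 1.0, atol=0.2)
        assert np.allclose(Xc.T @ np.ones(10), 0.0, atol=1e-10)
        bc = np.linalg.lstsq(Xc, np.ones(10), rcond=None)[0]
        assert np.allclose(Xc @ bc, 0.0, atol=1e-8)


class TestMccv:
    def test_error_count_arithmetic(self):
        X = np.random.default_rng(0).normal(size=(40, 30)) + 1.0
        cfg = MCCVConfig(leave_out_fraction=0.10, n_repeats=100,
                         max_components=5, rng_seed=9)
        press, errors = mccv(X, cfg)
        assert press.shape == (5,)
        assert errors.shape == (5, 400)  # 100 repeats x 4 held out
        assert np.allclose(press, (errors**2).sum(axis=1))

    def test_same_seed_reproduces_press_curve(self):
        X = np.random.default_rng(5).normal(size=(30, 20)) + 1.0
        cfg = MCCVConfig(max_components=4, rng_seed=11)
        p1, e1 = mccv(X, cfg)
        p2, e2 = mccv(X, cfg)
        assert np.array_equal(p1, p2)
        assert np.array_equal(e1, e2)

    def test_perfect_single_factor_data_has_zero_press(self):
        # X = t p', t chosen so the ones-response is exactly recoverable
        rng = np.random.default_rng(2)
        t = np.ones(20)
        p = rng.normal(size=15)
        X = np.outer(t, p)
        cfg = MCCVConfig(max_components=1, n_repeats=20, rng_seed=0)
        press, _ = mccv(X, cfg)
        assert press[0] < 1e-18

    def test_remainder_too_small_rejected(self):
        X = np.ones((12, 5))
        with pytest.raises(ConfigError):
            mccv(X, MCCVConfig(max_components=15, rng_seed=0))


class TestSelectComponents:
    @pytest.mark.parametrize(
        "curve, expected",
        [
            ([100, 50, 20, 10, 5.0, 4.99, 4.98], 5),  # flattens after 5
            ([1.0, 2.0, 3.0], 1),  # increasing -> first
            ([3.0, 3.0, 3.0], 1),  # ties -> parsimony
        ],
    )
    def test_elbow_rule(self, curve, expected):
        assert select_components(np.array(curve)) == expected

    def test_empty_curve_rejected(self):
        with pytest.raises(ConfigError):
            select_components(np.array([]))


@pytest.fixture(scope="module")
def fitted():
    rng = np.random.default_rng(8)
    X = np.outer(np.ones(24), rng.normal(size=12)) + rng.normal(
        0, 0.02, size=(24, 12)
    )
    train = make_set(X)
    model = fit_ocpls(train, MCCVConfig(max_components=5, rng_seed=4))
    return train, model


class TestFitPredict:
    def test_interval_follows_the_model_equation(self, fitted):
        _, model = fitted
        assert model.z_crit == pytest.approx(1.959964, abs=5e-7)
        lower, upper = model.interval
        assert lower == 1 - model.mu_e - model.z_crit * model.sigma_e
        assert upper == 1 - model.mu_e + model.z_crit * model.sigma_e
        assert upper - lower == pytest.approx(2 * model.z_crit * model.sigma_e)

    def test_interval_center_has_zero_z(self, fitted):
        train, model = fitted
        center = 1 - model.mu_e
        data = make_set(np.outer([1.0], np.zeros(12)), grid=train.grid)
        # synthesise a spectrum predicting exactly the center via scaling b
        x = model.b / (model.b @ model.b) * center
        data = make_set(x[None, :], grid=train.grid)
        (res,) = predict(model, data)
        assert res.accepted
        assert res.z_score == pytest.approx(0.0, abs=1e-9)

    def test_boundary_prediction_accepted_closed_interval(self, fitted):
        train, model = fitted
        upper = model.interval[1]
        x = model.b / (model.b @ model.b) * upper
        (res,) = predict(model, make_set(x[None, :], grid=train.grid))
        assert res.accepted
        x2 = model.b / (model.b @ model.b) * (upper + 10 * model.sigma_e)
        (res2,) = predict(model, make_set(x2[None, :], grid=train.grid))
        assert not res2.accepted

    def test_prediction_invariant_to_sample_order(self, fitted):
        train, model = fitted
        rng = np.random.default_rng(0)
        data = make_set(rng.normal(size=(6, 12)), grid=train.grid)
        fwd = predict(model, data)
        rev = predict(model, data.subset([5, 4, 3, 2, 1, 0]))
        assert [r.accepted for r in rev] == [r.accepted for r in fwd][::-1]
        np.testing.assert_allclose(
            [r.y_hat for r in rev], [r.y_hat for r in fwd][::-1], rtol=1e-12
        )

    def test_adulterated_training_samples_rejected(self):
        data = make_set(np.random.default_rng(0).normal(size=(12, 6)), pure=False)
        with pytest.raises(ContaminationError):
            fit_ocpls(data, MCCVConfig(max_components=3, rng_seed=0))

    def test_dimension_mismatch_rejected(self, fitted):
        _, model = fitted
        with pytest.raises(DimensionError):
            predict(model, make_set(np.ones((2, 5))))

    def test_json_round_trip(self, fitted, tmp_path):
        _, model = fitted
        path = tmp_path / "model.json"
        model.to_json(path)
        back = OCPLSModel.from_json(path)
        assert np.array_equal(back.b, model.b)
        assert back.interval == model.interval
        assert back.n_components == model.n_components
        assert back.mccv_config == model.mccv_config
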