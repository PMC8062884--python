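"""NIPALS PLSR core: oracle equivalences, VIP identities, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nrespec import SpectrumTable, fit_plsr, predict, vip_scores
from nrespec.exceptions import ComponentRangeError, GridMismatchError
from nrespec.plsr import load_model, save_model


def _ols_fit(X, y):
    """Independent normal-equations least squares with intercept."""
    Xi = np.column_stack([np.ones(len(X)), X])
    return Xi @ np.linalg.solve(Xi.T @ Xi, Xi.T @ y)


class TestFit:
    def test_single_column_equals_simple_regression(self, rng):
        x = rng.uniform(0, 1, 25)
        y = 3.0 * x + rng.normal(0, 0.1, 25)
        X = np.column_stack([x, np.zeros(25)])  # pad to p=2; zero column inert
        model = fit_plsr(X, y, A=1)
        pred = predict(model, X, a=1)
        slope = np.cov(x, y, ddof=1)[0, 1] / np.var(x, ddof=1)
        expected = y.mean() + slope * (x - x.mean())
        np.testing.assert_allclose(pred, expected, atol=1e-10)

    def test_constant_response_truncates_to_mean_model(self, rng):
        X = rng.normal(size=(10, 4))
        model = fit_plsr(X, np.full(10, 5.0), A=3)
        assert model.truncated and model.A_max == 0
        np.testing.assert_array_equal(model.coefficients(0), np.zeros(4))
        np.testing.assert_allclose(predict(model, X, a=0), 5.0)

    def test_full_rank_predictions_equal_least_squares(self, rng):
        X = rng.normal(size=(30, 8))
        y = X @ rng.normal(size=8) + rng.normal(size=30)
        model = fit_plsr(X, y, A=8)
        np.testing.assert_allclose(predict(model, X, a=8), _ols_fit(X, y), atol=1e-8)

    def test_matches_reference_pls_implementation(self, rng):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        X = rng.normal(size=(40, 15))
        y = X[:, :3] @ [1.0, -2.0, 0.5] + rng.normal(0, 0.2, 40)
        X_new = rng.normal(size=(10, 15))
        for a in (1, 3, 5):
            ref = sklearn.PLSRegression(n_components=a, scale=False).fit(X, y)
            model = fit_plsr(X, y, A=a)
            np.testing.assert_allclose(
                predict(model, X_new, a=a), ref.predict(X_new).ravel(), atol=1e-6
            )

    def test_score_columns_orthogonal(self, rng):
        X = rng.normal(size=(25, 10))
        y = rng.normal(size=25)
        model = fit_plsr(X, y, A=6)
        G = model.T.T @ model.T
        off = G - np.diag(np.diag(G))
        assert np.abs(off).max() < 1e-8 * np.abs(np.diag(G)).max()

    def test_component_range_errors(self, rng):
        X = rng.normal(size=(10, 4))
        y = rng.normal(size=10)
        with pytest.raises(ComponentRangeError):
            fit_plsr(X, y, A=0)
        with pytest.raises(ComponentRangeError):
            fit_plsr(X, y, A=5)  # > min(n-1, p) = 4
        with pytest.raises(ComponentRangeError):
            fit_plsr(X[:1], y[:1], A=1)

    def test_monotone_training_rss(self, rng):
        X = rng.normal(size=(30, 12))
        y = rng.normal(size=30)
        model = fit_plsr(X, y, A=10)
        rss = [np.sum((y - predict(model, X, a=a)) ** 2) for a in range(model.A_max + 1)]
        assert all(rss[a + 1] <= rss[a] + 1e-9 for a in range(len(rss) - 1))


class TestPredict:
    def test_a_zero_returns_training_mean(self, rng):
        X = rng.normal(size=(12, 5))
        y = rng.normal(size=12)
        model = fit_plsr(X, y, A=2)
        np.testing.assert_allclose(predict(model, rng.normal(size=(4, 5)), a=0), y.mean())

    def test_grid_mismatch_rejected(self, small_table):
        table, y = small_table
        model = fit_plsr(table, y.to_numpy(), A=2)
        shifted = SpectrumTable(table.X, table.wavelengths + 1.0, table.meta)
        with pytest.raises(GridMismatchError):
            predict(model, shifted)

    def test_a_above_fit_rejected(self, rng):
        model = fit_plsr(rng.normal(size=(10, 4)), rng.normal(size=10), A=2)
        with pytest.raises(ComponentRangeError):
            predict(model, rng.normal(size=(3, 4)), a=3)


class TestVip:
    def test_two_column_model_with_one_inert_column(self, rng):
        # p=1 is below the table minimum; with one informative and one inert
        # column, the informative one must absorb (almost) all importance.
        x = rng.uniform(0, 1, 30)
        X = np.column_stack([x, np.full(30, 0.5)])
        y = 2.0 * x
        model = fit_plsr(X, y, A=1)
        vip = vip_scores(model, a=1)
        np.testing.assert_allclose(vip, [np.sqrt(2.0), 0.0], atol=1e-10)

    def test_direct_formula_oracle(self, rng):
        X = rng.normal(size=(6, 4))
        y = rng.normal(size=6)
        model = fit_plsr(X, y, A=2)
        vip = vip_scores(model, a=2)
        # independent direct evaluation of the definition
        p = 4
        ss = np.array(
            [model.q[k] ** 2 * model.T[:, k] @ model.T[:, k] for k in range(2)]
        )
        expected = np.zeros(p)
        for j in range(p):
            acc = 0.0
            for k in range(2):
                wn = model.W[:, k] / np.linalg.norm(model.W[:, k])
                acc += ss[k] * wn[j] ** 2
            expected[j] = np.sqrt(p * acc / ss.sum())
        np.testing.assert_allclose(vip, expected, rtol=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(6, 25),
        p=st.integers(2, 12),
    )
    def test_vip_squares_average_to_one(self, seed, n, p):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, p))
        y = X @ rng.normal(size=p) + rng.normal(size=n)
        a = min(3, n - 1, p)
        model = fit_plsr(X, y, A=a)
        if model.A_max == 0:
            return
        vip = vip_scores(model)
        assert abs(np.sum(vip**2) - p) < 1e-8
        assert np.all(vip >= 0)

    def test_column_permutation_equivariance(self, rng):
        X = rng.normal(size=(20, 7))
        y = X[:, 1] * 2 + rng.normal(0, 0.1, 20)
        perm = rng.permutation(7)
        m1 = fit_plsr(X, y, A=3)
        m2 = fit_plsr(X[:, perm], y, A=3)
        np.testing.assert_allclose(vip_scores(m2, 3), vip_scores(m1, 3)[perm], atol=1e-9)
        np.testing.assert_allclose(m2.coefficients(3), m1.coefficients(3)[perm], atol=1e-9)
        X_new = rng.normal(size=(5, 7))
        np.testing.assert_allclose(
            predict(m2, X_new[:, perm], a=3), predict(m1, X_new, a=3), atol=1e-9
        )


class TestSerialization:
    def test_roundtrip_predictions_identical(self, small_table, tmp_path):
        table, y = small_table
        model = fit_plsr(table, y.to_numpy(), A=3)
        save_model(tmp_path / "model", model)
        back = load_model(tmp_path / "model")
        np.testing.assert_array_equal(predict(back, table), predict(model, table))
        assert back.A_max == model.A_max and back.scaled == model.scaled
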