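import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from plsdex import ExpressionMatrix, SampleLabels, autoscale, nipals_pls, sample_scores, vip
from plsdex.pls import Preprocessing, PLSModel

from conftest import random_instance
from reference_impls import pls1_reference


def _manual_model(weights, ssy):
    weights = np.asarray(weights, dtype=float)
    p = weights.shape[0]
    prep = Preprocessing(
        probe_ids=[f"P{j}" for j in range(p)], dropped_probes=[],
        mean=np.zeros(p), scale=None, y_mean=0.0, scaled=False,
    )
    a = weights.shape[1]
    return PLSModel(
        weights=weights, scores=np.zeros((2, a)), x_loadings=weights,
        y_loadings=np.zeros(a), ssy=np.asarray(ssy, dtype=float),
        preprocessing=prep,
    )


class TestAutoscale:
    def test_columns_centered_unit_variance(self, small_matrix, small_labels):
        X, y, prep = autoscale(small_matrix, small_labels)
        np.testing.assert_allclose(X.mean(axis=0), 0, atol=1e-12)
        np.testing.assert_allclose(X.std(axis=0, ddof=1), 1, atol=1e-12)

    def test_constant_probe_excluded_and_recorded(self, small_labels):
        data = pd.DataFrame(
            [[5.0] * 6, [1, 2, 3, 4, 5, 6]],
            index=["FLAT", "P1"], columns=[f"s{i}" for i in range(1, 7)],
        )
        X, y, prep = autoscale(ExpressionMatrix(data.astype(float)), small_labels)
        assert prep.dropped_probes == ["FLAT"]
        assert prep.probe_ids == ["P1"]
        assert X.shape == (6, 1)

    def test_y_centering(self, small_matrix, small_labels):
        _, y, _ = autoscale(small_matrix, small_labels)
        np.testing.assert_allclose(y, [0.5, 0.5, 0.5, -0.5, -0.5, -0.5])

    def test_all_constant_is_error(self, small_labels):
        data = pd.DataFrame(
            [[1.0] * 6], index=["P1"], columns=[f"s{i}" for i in range(1, 7)]
        )
        with pytest.raises(ValueError, match="zero variance"):
            autoscale(ExpressionMatrix(data), small_labels)


class TestNipals:
    def test_first_weight_is_normalized_xty(self):
        rng = np.random.default_rng(7)
        X, y = random_instance(rng, n=8, p=5)
        model = nipals_pls(X, y, 2)
        expected = X.T @ y / np.linalg.norm(X.T @ y)
        np.testing.assert_allclose(model.weights[:, 0], expected, atol=1e-12)

    def test_identical_separating_columns_symmetric_weight(self):
        X = np.array([[-1.0, -1.0], [1.0, 1.0]])
        y = np.array([-0.5, 0.5])
        model = nipals_pls(X, y, 1)
        np.testing.assert_allclose(model.weights[:, 0], [2**-0.5, 2**-0.5])
        # one component exhausts the response
        np.testing.assert_allclose(model.fitted_y(), y, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_loop_reference(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng)
        A = int(rng.integers(1, min(X.shape[0] - 1, X.shape[1]) + 1))
        model = nipals_pls(X, y, A)
        W, T, Q, SSY, yhat, vip_ref = pls1_reference(X, y, A)
        assert model.n_components == len(W)
        np.testing.assert_allclose(model.fitted_y(), yhat, atol=1e-8)
        np.testing.assert_allclose(model.weights, np.array(W).T, atol=1e-8)
        np.testing.assert_allclose(model.scores, np.array(T).T, atol=1e-8)
        np.testing.assert_allclose(vip(model).vip, vip_ref, atol=1e-8)

    def test_weight_norms_and_score_orthogonality(self):
        rng = np.random.default_rng(11)
        X, y = random_instance(rng, n=20, p=40)
        model = nipals_pls(X, y, 3)
        np.testing.assert_allclose(
            np.linalg.norm(model.weights, axis=0), 1, atol=1e-10
        )
        G = model.scores.T @ model.scores
        norms = np.sqrt(np.diag(G))
        off = G - np.diag(np.diag(G))
        assert np.all(np.abs(off) <= 1e-8 * np.outer(norms, norms))

    def test_deflation_conserves_y_sum_of_squares(self):
        rng = np.random.default_rng(13)
        X, y = random_instance(rng, n=15, p=30)
        model = nipals_pls(X, y, 3)
        # refit residual directly
        resid = y - model.fitted_y()
        total = y @ y
        np.testing.assert_allclose(
            total, model.ssy.sum() + resid @ resid, rtol=1e-8
        )
        assert np.all(model.ssy >= 0)
        assert model.ssy.sum() <= total * (1 + 1e-12)

    def test_early_stop_returns_fewer_components(self):
        X = np.array([[-1.0], [1.0], [-1.0], [1.0]])
        y = np.array([-0.5, 0.5, -0.5, 0.5])
        with pytest.warns(UserWarning, match="stopped early"):
            model = nipals_pls(np.hstack([X, X]), y, 2)
        assert model.n_components == 1

    def test_component_cap_validated(self):
        rng = np.random.default_rng(3)
        X, y = random_instance(rng, n=5, p=3)
        with pytest.raises(ValueError, match="n_components"):
            nipals_pls(X, y, 4)

    def test_cross_check_against_sklearn(self):
        sklearn = pytest.importorskip("sklearn.cross_decomposition")
        rng = np.random.default_rng(21)
        X, y = random_instance(rng, n=20, p=50)
        model = nipals_pls(X, y, 3)
        ref = sklearn.PLSRegression(n_components=3, scale=False).fit(X, y)
        np.testing.assert_allclose(
            model.fitted_y(), ref.predict(X).ravel(), atol=1e-10
        )


class TestVip:
    def test_equal_weights_give_unit_vip(self):
        model = _manual_model([[2**-0.5], [2**-0.5]], [1.0])
        np.testing.assert_allclose(vip(model).vip, [1.0, 1.0])

    def test_concentrated_weight(self):
        model = _manual_model([[1.0], [0.0]], [1.0])
        np.testing.assert_allclose(vip(model).vip, [2**0.5, 0.0])

    def test_two_component_hand_value(self):
        model = _manual_model([[1.0, 0.0], [0.0, 1.0]], [3.0, 1.0])
        np.testing.assert_allclose(vip(model).vip, [1.5**0.5, 0.5**0.5])

    def test_zero_explained_variance_is_error(self):
        model = _manual_model([[1.0], [0.0]], [0.0])
        with pytest.raises(ValueError, match="no response variance"):
            vip(model)

    @pytest.mark.parametrize("seed", range(5))
    def test_normalization_identity(self, seed):
        rng = np.random.default_rng(100 + seed)
        X, y = random_instance(rng, n=12, p=25)
        model = nipals_pls(X, y, 3)
        v = vip(model).vip
        np.testing.assert_allclose((v**2).sum(), 25, rtol=1e-6)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_identity_holds_for_random_models(self, seed):
        rng = np.random.default_rng(seed)
        X, y = random_instance(rng)
        model = nipals_pls(X, y, 1)
        v = vip(model).vip
        np.testing.assert_allclose((v**2).sum(), X.shape[1], rtol=1e-6)

    def test_one_component_ranking_matches_abs_correlation(self):
        rng = np.random.default_rng(42)
        X, y = random_instance(rng, n=10, p=8)
        model = nipals_pls(X, y, 1)
        v = vip(model).vip
        corr = np.abs(X.T @ y)  # |corr| up to a common factor on scaled X
        np.testing.assert_array_equal(np.argsort(v), np.argsort(corr))


class TestScores:
    def test_three_components_export_three_columns(self, small_matrix, small_labels):
        X, y, prep = autoscale(small_matrix, small_labels)
        model = nipals_pls(X, y, 3, preprocessing=prep,
                           sample_ids=small_matrix.sample_ids)
        table = sample_scores(model, small_labels)
        assert list(table.columns) == ["sample_id", "class", "t_1", "t_2", "t_3"]
        assert len(table) == 6

    def test_one_component_scores_equal_projection(self):
        rng = np.random.default_rng(5)
        X, y = random_instance(rng, n=8, p=4)
        model = nipals_pls(X, y, 1)
        table = sample_scores(model)
        np.testing.assert_allclose(
            table["t_1"].to_numpy(), X @ model.weights[:, 0], atol=1e-12
        )

    def test_strong_effect_separates_classes_on_first_score(self):
        from plsdex import SyntheticConfig, generate_expression, align
        cfg = SyntheticConfig(n_probes=100, n_de=30, effect_size=3.0,
                              hub_degrees=(), n_hubs=0, seed=9)
        matrix, labels, _ = generate_expression(cfg)
        X, y, prep = autoscale(matrix, labels)
        model = nipals_pls(X, y, 3, preprocessing=prep,
                           sample_ids=matrix.sample_ids)
        t1 = model.scores[:, 0]
        sign = np.sign(t1 * np.sign(y))
        assert np.all(sign == sign[0])  # perfect split on t_1 sign
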