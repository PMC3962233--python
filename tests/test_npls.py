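import numpy as np
import pytest

from jamupls.errors import ComponentError, ConvergenceError, FitError, ShapeError
from jamupls.formulary import build_tensor, matricize, to_dummy
from jamupls.npls import (
    activity_significance,
    build_corrected_weights,
    fit_npls,
    predict_npls,
)
from jamupls.pls import classify, fit_pls, predict


def _triple_sum_scores(X3, wJ, wK):
    """Explicit double-sum score: t_i = sum_j sum_k X_ijk wJ_j wK_k."""
    I, J, K = X3.shape
    t = np.zeros(I)
    for i in range(I):
        for j in range(J):
            for k in range(K):
                t[i] += X3[i, j, k] * wJ[j] * wK[k]
    return t


class TestReductionToBilinear:
    def test_k1_one_component_matches_standard_nipals(self, rng):
        X3 = rng.normal(size=(20, 6, 1))
        Y = rng.normal(size=(20, 3))
        nm = fit_npls(X3, Y, 1)
        pm = fit_pls(X3[:, :, 0], Y, 1)
        np.testing.assert_allclose(nm.scores, pm.scores, atol=1e-8)
        np.testing.assert_allclose(
            predict_npls(nm, X3), predict(pm, X3[:, :, 0]), atol=1e-8
        )

    def test_k1_multicomponent_matches_weight_deflation_nipals(self, rng):
        # with K=1 the trilinear fit is the two-way NIPALS that deflates X by
        # t w^T; scores, coefficients and fitted values coincide
        for _ in range(5):
            X3 = rng.normal(size=(25, 7, 1))
            Y = rng.normal(size=(25, 3))
            nm = fit_npls(X3, Y, 3, max_iter=50000)
            pm = fit_pls(X3[:, :, 0], Y, 3, deflation="weight", max_iter=50000)
            np.testing.assert_allclose(nm.scores, pm.scores, atol=1e-8)
            np.testing.assert_allclose(nm.coefficients, pm.coefficients, atol=1e-8)
            np.testing.assert_allclose(
                predict_npls(nm, X3), predict(pm, X3[:, :, 0]), atol=1e-8
            )


class TestRankOneRecovery:
    def test_known_factors_recovered(self, rng):
        I, J, K = 40, 6, 5
        a = rng.normal(size=J)
        a /= np.linalg.norm(a)
        b = rng.normal(size=K)
        b /= np.linalg.norm(b)
        t = rng.normal(size=I)
        X3 = t[:, None, None] * a[None, :, None] * b[None, None, :]
        model = fit_npls(X3, t, 1, keep_residuals=True)
        cos_a = abs(model.plant_weights[:, 0] @ a)
        cos_b = abs(model.activity_weights[:, 0] @ b)
        assert cos_a >= 1 - 1e-8
        assert cos_b >= 1 - 1e-8
        assert np.linalg.norm(model.y_residuals) < 1e-8


class TestAlgebraicIdentities:
    def test_double_sum_equals_kronecker(self, rng):
        for _ in range(10):
            I, J, K = rng.integers(2, 9, size=3)
            X3 = rng.normal(size=(I, J, K))
            wJ = rng.normal(size=J)
            wJ /= np.linalg.norm(wJ)
            wK = rng.normal(size=K)
            wK /= np.linalg.norm(wK)
            t_kron = matricize(X3) @ np.kron(wK, wJ)
            np.testing.assert_allclose(
                t_kron, _triple_sum_scores(X3, wJ, wK), atol=1e-10
            )

    def test_triple_path_identity_on_fit(self, rng):
        # Direct double-sum on the deflated tensor is not recoverable after the
        # fact, but the three advertised score paths on the fitted model are:
        # stored T, Kronecker weights on sequentially deflated X (implicitly the
        # stored T), and corrected weights on the original centered X.
        X3 = (rng.random(size=(30, 5, 4)) < 0.4).astype(float)
        Y = np.eye(3)[rng.integers(0, 3, 30)].astype(float)
        model = fit_npls(X3, Y, 3, max_iter=50000)
        Xc = matricize(X3) - model.x_means
        np.testing.assert_allclose(
            Xc @ model.corrected_weights, model.scores, atol=1e-8
        )
        # combined weights really are the Kronecker products of the mode weights
        for c in range(3):
            np.testing.assert_allclose(
                model.combined_weights[:, c],
                np.kron(model.activity_weights[:, c], model.plant_weights[:, c]),
                atol=1e-12,
            )

    def test_unit_norm_mode_weights(self, rng):
        X3 = rng.normal(size=(15, 4, 3))
        Y = rng.normal(size=(15, 2))
        model = fit_npls(X3, Y, 2, max_iter=50000)
        np.testing.assert_allclose(
            np.linalg.norm(model.plant_weights, axis=0), 1.0, atol=1e-10
        )
        np.testing.assert_allclose(
            np.linalg.norm(model.activity_weights, axis=0), 1.0, atol=1e-10
        )

    def test_y_residual_monotone(self, rng):
        X3 = rng.normal(size=(25, 5, 4))
        Y = rng.normal(size=(25, 3))
        norms = [
            np.linalg.norm(fit_npls(X3, Y, c, max_iter=50000, keep_residuals=True).y_residuals)
            for c in range(1, 5)
        ]
        assert all(a >= b - 1e-10 for a, b in zip(norms, norms[1:]))

    def test_score_response_covariance_nonnegative(self, rng):
        X3 = rng.normal(size=(25, 5, 4))
        Y = rng.normal(size=(25, 3))
        model = fit_npls(X3, Y, 3, max_iter=50000)
        for c in range(3):
            assert model.scores[:, c] @ model.y_scores[:, c] >= -1e-10

    def test_deterministic(self, rng):
        X3 = rng.normal(size=(15, 4, 3))
        Y = rng.normal(size=(15, 2))
        m1 = fit_npls(X3, Y, 2, max_iter=50000)
        m2 = fit_npls(X3, Y, 2, max_iter=50000)
        np.testing.assert_array_equal(m1.coefficients, m2.coefficients)

    def test_sign_convention(self, rng):
        X3 = rng.normal(size=(15, 4, 3))
        Y = rng.normal(size=(15, 2))
        model = fit_npls(X3, Y, 2, max_iter=50000)
        for c in range(2):
            k = np.argmax(np.abs(model.plant_weights[:, c]))
            assert model.plant_weights[k, c] > 0


class TestCorrectedWeights:
    def test_single_component_identity(self, rng):
        w = rng.normal(size=(6, 1))
        w /= np.linalg.norm(w)
        np.testing.assert_array_equal(build_corrected_weights(w), w)

    def test_orthogonal_weights_unchanged(self):
        W = np.eye(4)[:, :2]
        np.testing.assert_allclose(build_corrected_weights(W), W, atol=1e-15)

    def test_sequential_deflation_oracle(self, rng):
        # explicit deflation replay: scores from sequentially deflated X equal
        # corrected weights applied to the original X
        X3 = rng.normal(size=(20, 5, 3))
        Y = rng.normal(size=(20, 2))
        model = fit_npls(X3, Y, 3, max_iter=50000)
        Xc = matricize(X3) - model.x_means
        Xdef = Xc.copy()
        T_replay = np.empty_like(model.scores)
        for c in range(3):
            t = Xdef @ model.combined_weights[:, c]
            T_replay[:, c] = t
            Xdef -= np.outer(t, model.combined_weights[:, c])
        np.testing.assert_allclose(
            Xc @ model.corrected_weights, T_replay, atol=1e-8
        )


class TestPredict:
    def test_training_prediction_identity(self, rng):
        X3 = rng.normal(size=(20, 4, 3))
        Y = rng.normal(size=(20, 2))
        model = fit_npls(X3, Y, 2, max_iter=50000)
        np.testing.assert_allclose(
            predict_npls(model, X3),
            model.scores @ model.inner_coefficients + model.y_means,
            atol=1e-8,
        )

    def test_mean_row_predicts_y_mean(self, rng):
        X3 = rng.normal(size=(20, 4, 3))
        Y = rng.normal(size=(20, 2))
        model = fit_npls(X3, Y, 2, max_iter=50000)
        from jamupls.formulary import fold

        mean_row = fold(model.x_means[None, :], 4, 3)
        np.testing.assert_allclose(
            predict_npls(model, mean_row), model.y_means[None], atol=1e-12
        )

    def test_separable_training_perfect(self, separable_formulary):
        cfg, (usage, labels, activities, _) = separable_formulary
        names = cfg.resolved_class_names()
        tensor = build_tensor(usage, activities)
        dummy = to_dummy(labels, names)
        model = fit_npls(tensor, dummy, 2)
        pred = classify(predict_npls(model, tensor), names)
        assert pred == labels.labels

    def test_shape_mismatch(self, rng):
        model = fit_npls(rng.normal(size=(10, 4, 3)), rng.normal(size=(10, 2)), 1)
        with pytest.raises(ShapeError):
            predict_npls(model, rng.normal(size=(5, 4, 2)))


class TestErrors:
    def test_component_error(self, rng):
        with pytest.raises(ComponentError):
            fit_npls(rng.normal(size=(5, 3, 2)), rng.normal(size=(5, 2)), 5)

    def test_zero_variance_y(self, rng):
        with pytest.raises(FitError):
            fit_npls(rng.normal(size=(5, 3, 2)), np.ones((5, 2)), 1)

    def test_convergence_error_names_component(self, rng):
        X3 = rng.normal(size=(20, 5, 4))
        Y = rng.normal(size=(20, 3))
        with pytest.raises(ConvergenceError, match="component 1"):
            fit_npls(X3, Y, 1, max_iter=1)


class TestActivitySignificance:
    def test_inclusive_threshold(self, small_formulary, small_config):
        usage, labels, activities, _ = small_formulary
        names = small_config.resolved_class_names()
        tensor = build_tensor(usage, activities)
        dummy = to_dummy(labels, names)
        with pytest.warns(UserWarning, match="sample sizes"):
            sig = activity_significance(tensor, dummy, 2)
        # re-threshold exactly at an observed evidence value: inclusive call
        e = sig.evidence[sig.evidence > 0].min()
        with pytest.warns(UserWarning):
            sig2 = activity_significance(tensor, dummy, 2, threshold=float(e))
        k, l = np.argwhere(np.isclose(sig2.evidence, e))[0]
        assert sig2.S[k, l] == 1

    def test_unit_weight_vector_single_activity(self, rng):
        # only activity 1 carries signal: all other frontal slabs are zero
        I, J, K = 400, 6, 4
        X3 = np.zeros((I, J, K))
        X3[:, :, 0] = (rng.random((I, J)) < 0.5).astype(float)
        y = (X3[:, :3, 0].sum(axis=1) > 1).astype(float)
        sig = activity_significance(X3, y[:, None], 1, class_names=["c"])
        assert sig.S[0, 0] == 1
        assert sig.S[1:, 0].sum() == 0

    def test_small_sample_warns(self, rng):
        X3 = (rng.random((30, 4, 3)) < 0.5).astype(float)
        y = rng.integers(0, 2, 30).astype(float)
        with pytest.warns(UserWarning, match="350"):
            activity_significance(X3, y[:, None], 1)

    def test_recovers_specific_and_general_groups(self):
        from jamupls.simulate import GeneratorConfig, simulate_formulary

        cfg = GeneratorConfig(
            I=500, J=40, K=12, L=3, class_proportions=(1 / 3, 1 / 3, 1 / 3),
            n_main_per_class=6, p_main=0.8, p_support=0.03,
            n_specific_activities_per_class=2, n_general_activities=3,
            p_activity_noise=0.01, seed=5,
        )
        usage, labels, activities, truth = simulate_formulary(cfg)
        names = cfg.resolved_class_names()
        tensor = build_tensor(usage, activities)
        dummy = to_dummy(labels, names)
        sig = activity_significance(tensor, dummy, 2)
        aidx = {a: k for k, a in enumerate(sig.activity_ids)}
        cidx = {c: l for l, c in enumerate(sig.class_names)}
        for cls in names:
            for a in truth.specific_activities[cls]:
                assert sig.S[aidx[a], cidx[cls]] == 1
        for a in truth.general_activities:
            assert sig.S[aidx[a]].sum() >= 2

    def test_joint_mode_runs(self, small_formulary, small_config):
        usage, labels, activities, _ = small_formulary
        names = small_config.resolved_class_names()
        tensor = build_tensor(usage, activities)
        dummy = to_dummy(labels, names)
        with pytest.warns(UserWarning):
            sig = activity_significance(tensor, dummy, 2, mode="joint")
        assert sig.S.shape == (len(activities.activity_ids), len(names))

    def test_bad_threshold(self, rng):
        with pytest.raises(ValueError):
            activity_significance(rng.normal(size=(5, 2, 2)), np.eye(5)[:, :2], 1, threshold=0.0)
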