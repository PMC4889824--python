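"""Kernel functions and the one-against-all SVM wrapper."""

import numpy as np
import pytest
from sklearn.metrics.pairwise import polynomial_kernel, rbf_kernel
from sklearn.svm import SVC

from gesturekit import (
    KernelSpec,
    ValidationError,
    kernel_eval,
    kernel_matrix,
    load_model,
    mean_sv_per_class,
    multiclass_rate,
    per_class_binary_rate,
    per_class_recall,
    predict,
    save_model,
    total_sv_count,
    train_ova,
)
from gesturekit.svm_ova import BinaryMachine, TrainedOvaModel, decision_matrix


class TestKernelSpec:
    def test_quadratic_degree_pinned_to_two(self):
        spec = KernelSpec(family="quadratic", degree=7)
        assert spec.effective_degree == 2

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"family": "sigmoid"},
            {"family": "polynomial", "degree": 1},
            {"family": "rbf", "gamma": -1.0},
            {"family": "rbf", "c_soft_margin": 0.0},
            {"family": "polynomial", "coef0": float("inf")},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            KernelSpec(**kwargs)


class TestKernelEval:
    def test_rbf_at_identical_points_is_one(self):
        spec = KernelSpec(family="rbf", gamma=0.7)
        u = np.array([1.0, -2.0, 3.0])
        assert kernel_eval(spec, u, u) == 1.0

    def test_polynomial_degree_two_equals_quadratic(self):
        quad = KernelSpec(family="quadratic", gamma=0.5, coef0=1.5)
        poly = KernelSpec(family="polynomial", degree=2, gamma=0.5, coef0=1.5)
        u, v = np.array([1.0, 2.0]), np.array([-0.5, 3.0])
        assert kernel_eval(quad, u, v) == kernel_eval(poly, u, v)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            kernel_eval(KernelSpec(), [1.0, 2.0], [1.0])

    @pytest.mark.parametrize(
        "spec",
        [
            KernelSpec(family="quadratic", gamma=0.3, coef0=1.0),
            KernelSpec(family="polynomial", degree=4, gamma=0.2, coef0=0.5),
            KernelSpec(family="rbf", gamma=1.3),
        ],
        ids=["quadratic", "polynomial", "rbf"],
    )
    def test_gram_matrix_symmetric_psd(self, spec):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(10, 3))
        K = kernel_matrix(spec, X, X)
        np.testing.assert_allclose(K, K.T, atol=1e-12)
        assert np.linalg.eigvalsh(K).min() >= -1e-9

    def test_matches_sklearn_pairwise_kernels(self):
        rng = np.random.default_rng(2)
        U, V = rng.normal(size=(6, 4)), rng.normal(size=(5, 4))
        rbf = KernelSpec(family="rbf", gamma=0.8)
        np.testing.assert_allclose(
            kernel_matrix(rbf, U, V), rbf_kernel(U, V, gamma=0.8), rtol=1e-12
        )
        poly = KernelSpec(family="polynomial", degree=3, gamma=0.4, coef0=1.2)
        np.testing.assert_allclose(
            kernel_matrix(poly, U, V),
            polynomial_kernel(U, V, degree=3, gamma=0.4, coef0=1.2),
            rtol=1e-12,
        )


@pytest.fixture(
    params=[
        KernelSpec(family="quadratic", gamma=0.1, coef0=1.0, c_soft_margin=10.0),
        KernelSpec(family="polynomial", degree=3, gamma=0.1, coef0=1.0, c_soft_margin=10.0),
        KernelSpec(family="rbf", gamma=0.1, c_soft_margin=10.0),
    ],
    ids=["quadratic", "polynomial", "rbf"],
)
def any_kernel(request):
    return request.param


class TestTrainPredict:
    def test_six_classes_give_six_binary_machines(self, blobs6, any_kernel):
        X, y = blobs6
        model = train_ova(X, any_kernel, y=y)
        assert len(model.binary_machines) == 6
        assert model.class_labels == ("HC", "HO", "WF", "WE", "IF", "T")

    def test_separable_clusters_classified_perfectly(self, blobs6, any_kernel):
        X, y = blobs6
        model = train_ova(X, any_kernel, y=y)
        assert multiclass_rate(model, X, y) == 100.0

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            train_ova(np.zeros((5, 2)), KernelSpec(), y=["HC"] * 5)

    def test_decision_matches_sklearn_decision_function(self, blobs6):
        # the extracted plain-data machines must reproduce libsvm's decision
        X, y = blobs6
        spec = KernelSpec(family="rbf", gamma=0.3, c_soft_margin=5.0)
        model = train_ova(X, spec, y=y)
        for k, label in enumerate(model.class_labels):
            ref = SVC(C=5.0, kernel="rbf", gamma=0.3).fit(X, (y == label).astype(int))
            np.testing.assert_allclose(
                decision_matrix(model, X)[:, k], ref.decision_function(X), rtol=1e-8, atol=1e-8
            )

    def test_duplicating_training_points_keeps_decision(self, blobs6):
        X, y = blobs6
        spec = KernelSpec(family="rbf", gamma=0.2, c_soft_margin=10.0)
        m1 = train_ova(X, spec, y=y)
        m2 = train_ova(np.vstack([X, X]), spec, y=np.concatenate([y, y]))
        np.testing.assert_allclose(
            decision_matrix(m1, X), decision_matrix(m2, X), atol=1e-6
        )

    def test_prediction_order_invariant(self, blobs6, any_kernel):
        X, y = blobs6
        model = train_ova(X, any_kernel, y=y)
        perm = np.random.default_rng(0).permutation(len(X))
        np.testing.assert_array_equal(predict(model, X)[perm], predict(model, X[perm]))

    def test_training_deterministic(self, blobs6):
        X, y = blobs6
        spec = KernelSpec(family="rbf", gamma=0.2)
        m1, m2 = train_ova(X, spec, y=y), train_ova(X, spec, y=y)
        for a, b in zip(m1.binary_machines, m2.binary_machines):
            np.testing.assert_array_equal(a.support_vectors, b.support_vectors)
            np.testing.assert_array_equal(a.dual_coef, b.dual_coef)

    def test_tie_broken_by_class_order(self):
        sv = np.array([[0.0, 0.0]])
        machine = BinaryMachine(support_vectors=sv, dual_coef=np.array([1.0]), intercept=0.0)
        model = TrainedOvaModel(
            class_labels=("HC", "HO"),
            binary_machines=[machine, machine],  # identical scores everywhere
            kernel=KernelSpec(family="rbf", gamma=1.0),
        )
        assert predict(model, np.array([[1.0, 1.0]]))[0] == "HC"


class TestRatesAndSupportVectors:
    def test_perfect_binary_machines_score_100(self, blobs6, any_kernel):
        X, y = blobs6
        model = train_ova(X, any_kernel, y=y)
        rates = per_class_binary_rate(model, X, y)
        assert rates.shape == (6,)
        np.testing.assert_allclose(rates, 100.0)

    def test_always_rest_machine_scores_one_minus_prevalence(self):
        # a machine with constant negative decision classifies every sample
        # as "rest": correct exactly for the 1-p non-class fraction
        sv = np.array([[0.0]])
        neg = BinaryMachine(support_vectors=sv, dual_coef=np.array([0.0]), intercept=-1.0)
        pos = BinaryMachine(support_vectors=sv, dual_coef=np.array([0.0]), intercept=1.0)
        model = TrainedOvaModel(
            class_labels=("A", "B"), binary_machines=[neg, pos], kernel=KernelSpec()
        )
        X = np.zeros((10, 1))
        y = np.array(["A"] * 3 + ["B"] * 7)  # prevalence of A is 0.3
        rates = per_class_binary_rate(model, X, y)
        assert rates[0] == pytest.approx(100.0 * 0.7)

    def test_rates_within_bounds(self, blobs6):
        X, y = blobs6
        model = train_ova(X, KernelSpec(family="rbf", gamma=5.0, c_soft_margin=0.1), y=y)
        for fn in (per_class_binary_rate, per_class_recall):
            rates = fn(model, X, y)
            assert np.all((rates >= 0) & (rates <= 100))

    def test_sv_count_arithmetic(self, blobs6):
        X, y = blobs6
        model = train_ova(X, KernelSpec(family="rbf", gamma=0.1), y=y)
        counts = model.sv_count_per_class
        assert total_sv_count(model) == sum(counts)
        assert mean_sv_per_class(model) == pytest.approx(sum(counts) / 6)
        assert all(0 <= c <= len(X) for c in counts)

    def test_hard_margin_uses_fewer_svs_than_soft(self, blobs6):
        X, y = blobs6
        hard = train_ova(X, KernelSpec(family="rbf", gamma=0.1, c_soft_margin=1e6), y=y)
        soft = train_ova(X, KernelSpec(family="rbf", gamma=0.1, c_soft_margin=1e-3), y=y)
        assert total_sv_count(hard) < total_sv_count(soft)

    def test_empty_test_set_rejected(self, blobs6):
        X, y = blobs6
        model = train_ova(X, KernelSpec(), y=y)
        with pytest.raises(ValidationError):
            per_class_binary_rate(model, np.zeros((0, 2)), [])


def test_model_json_round_trip(tmp_path, blobs6):
    X, y = blobs6
    spec = KernelSpec(family="polynomial", degree=3, gamma=0.2, coef0=1.0, c_soft_margin=2.0)
    model = train_ova(X, spec, y=y)
    save_model(model, tmp_path / "model.json")
    back = load_model(tmp_path / "model.json")
    assert back.class_labels == model.class_labels
    assert back.kernel == model.kernel
    np.testing.assert_array_equal(predict(back, X), predict(model, X))
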