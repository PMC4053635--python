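"""Per-sample-cap SVM: solver correctness against independent oracles,
KKT conditions, severity-weighted caps, and the model ablations."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from sichml.cohort import ConsensusReading, Outcome, Side
from sichml.svm import (
    AblationVariant,
    KernelKind,
    KernelSpec,
    ablate,
    base_section_column_mask,
    decision_distance,
    hemisphere_features,
    kernel_matrix,
    manual_features,
    nihss_to_caps,
    outcome_labels,
    train_manual_svm,
    train_svm,
)
from tests.test_scores import make_record


def qp_oracle(X, y, caps, kernel=KernelSpec()):
    """Dense dual QP solved by SLSQP — independent of the SMO path."""
    K = kernel_matrix(kernel, X, X)
    Q = (y[:, None] * y[None, :]) * K
    n = len(y)

    def obj(a):
        return 0.5 * a @ Q @ a - a.sum()

    def grad(a):
        return Q @ a - 1.0

    res = minimize(obj, np.zeros(n), jac=grad, method="SLSQP",
                   bounds=[(0.0, c) for c in caps],
                   constraints=[{"type": "eq", "fun": lambda a: a @ y,
                                 "jac": lambda a: y}],
                   options={"maxiter": 500, "ftol": 1e-12})
    alpha = res.x
    f = K @ (alpha * y)
    free = (alpha > 1e-6 * max(caps)) & (alpha < np.asarray(caps) * (1 - 1e-6))
    bias = float(np.mean(y[free] - f[free])) if free.any() else 0.0
    return alpha, bias


def toy_set(seed, n=20, overlap=0.5):
    rng = np.random.default_rng(seed)
    X = rng.normal(0, 1, (n, 2))
    y = np.where(X[:, 0] + overlap * rng.normal(0, 1, n) > 0, 1.0, -1.0)
    if len(np.unique(y)) < 2:
        y[0] = -y[0]
    return X, y, rng


class TestCaps:
    def test_equal_nihss_gives_uniform_caps(self):
        assert nihss_to_caps([12, 12, 12], base_c=2.0) == pytest.approx([2.0] * 3)

    def test_mean_normalized_proportionality(self):
        assert nihss_to_caps([10, 20]) == pytest.approx([2 / 3, 4 / 3])

    def test_zero_nihss_floored(self):
        assert nihss_to_caps([0, 15]) == pytest.approx([0.01, 2.0])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            nihss_to_caps([0, 0, 0])


class TestSolver:
    def test_two_point_problem_has_symmetric_margin(self):
        model = train_svm(np.array([[-1.0], [1.0]]), [-1, 1], caps=1.0, tol=1e-8)
        assert model.bias == pytest.approx(0.0, abs=1e-8)
        assert decision_distance(model, np.array([1.0])) == pytest.approx(1.0, abs=1e-6)
        assert decision_distance(model, np.array([-1.0])) == pytest.approx(-1.0, abs=1e-6)

    def test_zero_input_returns_bias(self):
        X, y, _ = toy_set(3)
        model = train_svm(X, y, caps=1.0, tol=1e-8)
        assert decision_distance(model, np.zeros(2)) == pytest.approx(
            model.bias, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_qp_oracle(self, seed):
        X, y, rng = toy_set(seed)
        caps = rng.uniform(0.4, 1.8, len(y))
        model = train_svm(X, y, caps=caps, tol=1e-7)
        alpha, bias = qp_oracle(X, y, caps)
        f_mine = decision_distance(model, X)
        f_qp = kernel_matrix(KernelSpec(), X, X) @ (alpha * y) + bias
        assert np.max(np.abs(f_mine - f_qp)) <= 1e-4

    @pytest.mark.parametrize("seed", range(20))
    def test_uniform_caps_reduce_to_standard_c_svm(self, seed):
        # with equal caps the per-sample formulation must be an ordinary
        # C-SVM; sklearn's reference solver provides the decision values
        X, y, rng = toy_set(seed, n=40)
        w = rng.uniform(0.3, 2.0, 40)
        model = train_svm(X, y, caps=w, tol=1e-6)
        sk = SVC(C=1.0, kernel="linear", tol=1e-8).fit(X, y, sample_weight=w)
        T = rng.normal(0, 1, (10, 2))
        assert np.max(np.abs(decision_distance(model, T)
                             - sk.decision_function(T))) <= 1e-4

    def test_kkt_conditions(self):
        X, y, rng = toy_set(7, n=30)
        caps = rng.uniform(0.3, 2.0, 30)
        model = train_svm(X, y, caps=caps, tol=1e-6)
        alpha = model.diagnostics["alpha"]
        margins = y * decision_distance(model, X)
        tol = 1e-3
        assert np.all(margins[alpha < 1e-10] >= 1 - tol)
        assert np.all(margins[np.isclose(alpha, caps)] <= 1 + tol)
        assert abs(np.sum(alpha * y)) <= 1e-6 * caps.max()

    def test_free_support_vector_sits_on_unit_margin(self):
        X, y, _ = toy_set(11, n=30, overlap=0.0)
        model = train_svm(X, y, caps=10.0, tol=1e-8)
        alpha = model.diagnostics["alpha"]
        free = (alpha > 1e-8) & (alpha < 10.0 * (1 - 1e-8))
        assert free.any()
        assert np.abs(np.abs(decision_distance(model, X[free])) - 1).max() <= 1e-5

    def test_raising_a_cap_reduces_that_subjects_slack(self):
        X, y, rng = toy_set(13, n=24, overlap=1.0)
        caps = np.full(24, 0.5)
        base = train_svm(X, y, caps=caps, tol=1e-7)
        slack_base = np.maximum(0.0, 1.0 - y * decision_distance(base, X))
        worst = int(np.argmax(slack_base))
        caps2 = caps.copy()
        caps2[worst] *= 2
        bumped = train_svm(X, y, caps=caps2, tol=1e-7)
        slack_bumped = np.maximum(0.0, 1.0 - y * decision_distance(bumped, X))
        assert slack_bumped[worst] <= slack_base[worst] + 1e-6

    def test_prediction_invariant_to_subject_order(self):
        X, y, rng = toy_set(17, n=30)
        caps = rng.uniform(0.3, 2.0, 30)
        perm = rng.permutation(30)
        a = train_svm(X, y, caps=caps, tol=1e-7)
        b = train_svm(X[perm], y[perm], caps=caps[perm], tol=1e-7)
        T = rng.normal(0, 1, (8, 2))
        assert decision_distance(a, T) == pytest.approx(
            decision_distance(b, T), abs=1e-5)

    def test_sigmoid_kernel_trains_within_budget(self):
        X, y, _ = toy_set(19, n=30)
        model = train_svm(X, y, caps=1.0,
                          kernel=KernelSpec(KernelKind.SIGMOID_MLP,
                                            scale=0.5, offset=-1.0))
        acc = np.mean(np.sign(decision_distance(model, X)) == y)
        assert acc >= 0.8
        assert "iterations" in model.diagnostics

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.zeros((4, 2)), [1, 1, 1, 1], caps=1.0)

    def test_dimension_mismatch_rejected(self):
        X, y, _ = toy_set(1)
        model = train_svm(X, y, caps=1.0)
        with pytest.raises(ValueError):
            decision_distance(model, np.zeros(5))


class TestManualSvm:
    def _cohort(self, n=30, seed=0):
        rng = np.random.default_rng(seed)
        records, consensuses = [], []
        for i in range(n):
            sich = i < n // 3
            nihss = int(np.clip(rng.normal(16 if sich else 9, 4), 0, 42))
            records.append(make_record(nihss=nihss,
                                       outcome=Outcome.SICH if sich
                                       else Outcome.NO_SICH))
            acute = rng.random() < (0.7 if sich else 0.25)
            consensuses.append(ConsensusReading(
                acute_ischemia=acute,
                gt_third_mca=acute and rng.random() < 0.4,
                hyperdense_mca=rng.random() < (0.4 if sich else 0.15),
                fazekas=1.0))
        return records, consensuses

    def test_feature_coding(self):
        records, _ = self._cohort(3)
        cons = [ConsensusReading(False, False, False, 0.0),
                ConsensusReading(True, False, True, 1.0),
                ConsensusReading(True, True, False, 2.0)]
        X = manual_features(records, cons)
        assert X[:, 1].tolist() == [0.0, 1.0, 2.0]
        assert X[:, 2].tolist() == [0.0, 1.0, 0.0]

    def test_sich_subjects_score_negative_on_separable_cohort(self):
        records, consensuses = self._cohort(36, seed=4)
        model = train_manual_svm(records, consensuses)
        X = manual_features(records, consensuses)
        d = decision_distance(model, X)
        sich = outcome_labels(records) < 0
        assert d[sich].mean() < d[~sich].mean()

    def test_standardization_stored_on_model(self):
        records, consensuses = self._cohort(24, seed=5)
        model = train_manual_svm(records, consensuses)
        assert model.feature_center is not None
        assert model.feature_scale is not None


class TestAblations:
    def _setup(self, seed=0):
        rng = np.random.default_rng(seed)
        n, nx, ny, nz = 20, 6, 4, 4
        coords = np.array([(x, y, z) for z in range(nz) for y in range(ny)
                           for x in range(nx)], dtype=np.int32)
        values = rng.normal(40, 4, (n, len(coords)))
        labels = np.r_[-np.ones(5), np.ones(15)]
        nihss = rng.integers(4, 25, n).astype(float)
        sides = [Side.LEFT if i % 2 == 0 else Side.RIGHT for i in range(n)]
        return values, labels, nihss, coords, sides, nx

    def test_no_nihss_equals_full_model_on_equal_severity(self):
        values, labels, _, coords, sides, nx = self._setup(1)
        equal = np.full(len(labels), 12.0)
        full = train_svm(values, labels, caps=nihss_to_caps(equal))
        ablated, _ = ablate(AblationVariant.NO_NIHSS, values, labels, equal,
                            coords, base_c=1.0)
        # identical optimization problems, solved to the default tolerance
        assert decision_distance(full, values) == pytest.approx(
            decision_distance(ablated, values), abs=1e-3)

    def test_no_base_drops_exactly_the_base_only_columns(self):
        values, labels, nihss, coords, sides, nx = self._setup(2)
        upper_start = 2
        _, info = ablate(AblationVariant.NO_BASE, values, labels, nihss,
                         coords, upper_start=upper_start)
        expected = int((coords[:, 2] >= upper_start).sum())
        assert info["n_features"] == expected
        assert np.all(info["voxel_index"][:, 2] >= upper_start)

    def test_single_hemisphere_keeps_half_grid(self):
        values, labels, nihss, coords, sides, nx = self._setup(3)
        _, info = ablate(AblationVariant.SINGLE_HEMISPHERE, values, labels,
                         nihss, coords, nx=nx, lesion_sides=sides)
        assert info["n_features"] == len(coords) // 2
        assert np.all(info["voxel_index"][:, 0] < nx / 2)

    def test_hemisphere_features_mirror_right_sided_subjects(self):
        values, labels, nihss, coords, sides, nx = self._setup(4)
        X, kept = hemisphere_features(values, coords, nx,
                                      [Side.RIGHT] * len(labels))
        x, y, z = kept[0]
        mirror_col = np.flatnonzero((coords[:, 0] == nx - 1 - x)
                                    & (coords[:, 1] == y) & (coords[:, 2] == z))[0]
        assert X[:, 0] == pytest.approx(values[:, mirror_col])

    def test_base_mask_partitions_columns(self):
        coords = np.array([[0, 0, z] for z in range(6)], dtype=np.int32)
        mask = base_section_column_mask(coords, upper_start=2)
        assert mask.tolist() == [True, True, False, False, False, False]
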