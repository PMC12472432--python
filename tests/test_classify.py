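import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from sklearn.metrics import roc_auc_score

import oracles
from swaylab.classify import (
    COMPARE_METRICS,
    GridSpec,
    FeatureScaler,
    bootstrap_ci,
    class_imbalance_ratio,
    compare_smote_pipelines,
    confusion_and_metrics,
    importance_concordance,
    iter_grid,
    rank_auc,
    run_repeated_splits,
    scale_train_test,
    smote_oversample,
    soft_vote,
    stratified_split,
    tune_model,
)


class TestSplitAndScale:
    def test_reference_cohort_split_geometry(self):
        labels = np.array(["HOA"] * 37 + ["PD"] * 26)
        train, test = stratified_split(labels, 0.30, seed=0)
        assert len(test) == 19
        assert (labels[test] == "HOA").sum() == 11
        assert (labels[test] == "PD").sum() == 8
        assert len(train) + len(test) == 63

    def test_split_deterministic_disjoint_exhaustive(self):
        labels = np.array(["HOA"] * 10 + ["PD"] * 7)
        a = stratified_split(labels, 0.30, seed=3)
        b = stratified_split(labels, 0.30, seed=3)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])
        assert set(a[0]) | set(a[1]) == set(range(17))
        assert set(a[0]) & set(a[1]) == set()

    def test_scaler_examples(self):
        X_tr = np.array([[1.0], [3.0]])
        X_te = np.array([[2.0]])
        tr, te, scaler = scale_train_test(X_tr, X_te)
        np.testing.assert_allclose(tr.ravel(), [-1.0, 1.0])
        np.testing.assert_allclose(te.ravel(), [0.0])
        assert not scaler.degenerate_.any()

    def test_constant_column_centred_and_flagged(self):
        X = np.column_stack([np.full(5, 3.0), np.arange(5.0)])
        scaler = FeatureScaler().fit(X)
        assert scaler.degenerate_[0] and not scaler.degenerate_[1]
        out = scaler.transform(X)
        np.testing.assert_allclose(out[:, 0], 0.0)

    def test_scaler_matches_brute_force(self, rng):
        X_tr = rng.normal(size=(20, 6))
        X_te = rng.normal(size=(8, 6))
        tr, te, _ = scale_train_test(X_tr, X_te)
        mu = X_tr.mean(axis=0)
        sd = X_tr.std(axis=0)
        np.testing.assert_allclose(te, (X_te - mu) / sd, rtol=1e-12)
        np.testing.assert_allclose(tr.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(tr.std(axis=0), 1.0, rtol=1e-9)

    def test_imbalance_ratio(self):
        labels = np.array(["HOA"] * 37 + ["PD"] * 26)
        assert class_imbalance_ratio(labels) == 1.42


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.normal(size=(10, 3))
        y = np.array([0] * 5 + [1] * 5)
        X2, y2 = smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(X2, X)
        np.testing.assert_array_equal(y2, y)

    def test_output_balanced_and_on_segments(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.array([0] * 20 + [1] * 10)
        X2, y2 = smote_oversample(X, y, k=5, seed=42)
        _, counts = np.unique(y2, return_counts=True)
        assert counts[0] == counts[1] == 20
        minority = X[y == 1]
        for row in X2[len(X):]:
            dmin = min(
                oracles.point_segment_distance(row, a, b)
                for i, a in enumerate(minority)
                for b in minority[i + 1:]
            )
            assert dmin < 1e-8

    def test_small_minority_reduces_k(self, rng):
        X = rng.normal(size=(13, 2))
        y = np.array([0] * 10 + [1] * 3)
        with pytest.warns(UserWarning, match="reducing k"):
            X2, y2 = smote_oversample(X, y, k=5, seed=0)
        assert (y2 == 1).sum() == 10


class TestRankAuc:
    def test_examples(self):
        assert rank_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9]) == 1.0
        assert rank_auc([0, 1, 0, 1], [0.5, 0.5, 0.5, 0.5]) == 0.5
        assert rank_auc([1, 1, 0, 0], [0.9, 0.4, 0.5, 0.1]) == 0.75

    def test_matches_pairwise_and_sklearn(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if y.sum() in (0, n):
                continue
            s = np.round(rng.random(n), 2)  # induce ties
            auc = rank_auc(y, s)
            assert auc == pytest.approx(
                oracles.auc_pairwise_oracle(y, s), rel=1e-12)
            assert auc == pytest.approx(roc_auc_score(y, s), rel=1e-12)

    def test_single_class_flagged_nan(self):
        assert np.isnan(rank_auc([1, 1], [0.2, 0.3]))


class TestSoftVote:
    def test_mean_and_threshold(self):
        pred, prob = soft_vote(np.array([[0.9], [0.8], [0.1]]))
        assert prob[0] == pytest.approx(0.6)
        assert pred[0] == 1

    def test_unanimous_members(self):
        pred, prob = soft_vote(np.full((3, 4), 0.3))
        np.testing.assert_allclose(prob, 0.3)
        assert (pred == 0).all()

    def test_permutation_symmetric(self, rng):
        probs = rng.random((3, 10))
        _, a = soft_vote(probs)
        _, b = soft_vote(probs[[2, 0, 1]])
        np.testing.assert_allclose(a, b)

    def test_member_count_enforced(self, rng):
        with pytest.raises(ValueError, match="members"):
            soft_vote(rng.random((2, 5)))
        soft_vote(rng.random((2, 5)), n_members=None)  # override accepted


class TestConfusionMetrics:
    def test_specificity_is_hoa_recall_and_label_swap(self, rng):
        y = rng.integers(0, 2, 25)
        y[0], y[1] = 0, 1
        pred = rng.integers(0, 2, 25)
        s = rng.random(25)
        m = confusion_and_metrics(y, pred, s)
        m_sw = confusion_and_metrics(1 - y, 1 - pred, 1 - s)
        assert m.specificity == pytest.approx(
            confusion_and_metrics(1 - y, 1 - pred, 1 - s).sensitivity)
        assert m.f1_pd == pytest.approx(m_sw.f1_hoa)
        assert m.f1_hoa == pytest.approx(m_sw.f1_pd)
        assert m.tp + m.fp + m.tn + m.fn == 25

    def test_counts_and_rates_consistent(self, rng):
        y = np.array([1] * 8 + [0] * 11)
        pred = y.copy()
        pred[0] = 0
        m = confusion_and_metrics(y, pred, rng.random(19))
        assert m.sensitivity == pytest.approx(m.tp / (m.tp + m.fn))


class TestTuneModel:
    def make_separable(self, rng, n=30):
        X = np.vstack([
            rng.normal(-4, 0.3, size=(n // 2, 4)),
            rng.normal(4, 0.3, size=(n // 2, 4)),
        ])
        y = np.array([0] * (n // 2) + [1] * (n // 2))
        return X, y

    def test_single_combination_returned(self, rng):
        X, y = self.make_separable(rng)
        grid = {"C": [1], "kernel": ["linear"]}
        params, _ = tune_model("svm", grid, X, y, seed=0)
        assert params == {"C": 1, "kernel": "linear"}

    def test_separable_data_reaches_auc_one(self, rng):
        X, y = self.make_separable(rng)
        _, score = tune_model("svm", {"C": [1], "kernel": ["linear"]},
                              X, y, seed=0)
        assert score == 1.0

    def test_tie_broken_first_in_grid(self, rng):
        X, y = self.make_separable(rng)
        # degree is inert for a linear kernel: scores tie exactly
        grid = {"kernel": ["linear"], "C": [1], "degree": [2, 3]}
        params, _ = tune_model("svm", grid, X, y, seed=0)
        assert params["degree"] == 2

    def test_grid_enumeration_order(self):
        combos = list(iter_grid({"a": [1, 2], "b": ["x", "y"]}))
        assert combos[0] == {"a": 1, "b": "x"}
        assert combos[1] == {"a": 1, "b": "y"}

    def test_full_grid_sizes(self):
        grids = GridSpec.full()
        assert len(list(iter_grid(grids.rf))) == 2 * 3 * 3 * 3
        assert len(list(iter_grid(grids.gb))) == 2 * 3 * 3 * 2 * 2 * 2
        assert len(list(iter_grid(grids.svm))) == 3 * 3 * 3 * 2


class TestBootstrap:
    def test_constant_vector(self):
        s = bootstrap_ci(np.full(15, 0.9), B=200, seed=1)
        assert s.ci_low == s.ci_high == s.mean == pytest.approx(0.9)

    def test_bounds_within_resample_range(self, rng):
        v = rng.random(15)
        s = bootstrap_ci(v, B=500, seed=2)
        assert v.min() <= s.ci_low <= s.mean <= s.ci_high <= v.max()

    def test_matches_independent_oracle(self):
        v = np.array([0.0, 1.0])
        s = bootstrap_ci(v, B=1000, seed=7)
        mean_o, lo_o, hi_o = oracles.percentile_bootstrap_oracle(v, 1000, 7)
        assert s.mean == pytest.approx(mean_o)
        assert s.ci_low == pytest.approx(lo_o, rel=1e-9)
        assert s.ci_high == pytest.approx(hi_o, rel=1e-9)


def metrics_frame(rng, model, values=None, n=8):
    rows = []
    for s in range(n):
        row = {"split_id": s, "model": model}
        for metric in COMPARE_METRICS:
            row[metric] = values[s] if values is not None else rng.random()
        rows.append(row)
    return pd.DataFrame(rows)


class TestCompareSmote:
    def test_identical_arms_all_na(self, rng):
        frames = pd.concat(
            [metrics_frame(rng, m) for m in ("rf", "gb", "svm")]
        )
        out = compare_smote_pipelines(frames, frames.copy())
        assert out["p"].isna().all()
        assert len(out) == 3 * 6  # 3 models x 6 metrics

    def test_sign_pattern_enumeration(self):
        # paired differences (1, 2, 3): exact two-sided p = 2/8 = 0.25
        rng = np.random.default_rng(0)
        base = metrics_frame(rng, "rf", values=[0.5, 0.5, 0.5], n=3)
        shifted = base.copy()
        for metric in COMPARE_METRICS:
            shifted[metric] = base[metric] + np.array([0.01, 0.02, 0.03])
        frames_a = pd.concat(
            [shifted] + [metrics_frame(rng, m, values=[0.5] * 3, n=3)
                         for m in ("gb", "svm")]
        )
        frames_b = pd.concat(
            [base] + [metrics_frame(rng, m, values=[0.5] * 3, n=3)
                      for m in ("gb", "svm")]
        )
        out = compare_smote_pipelines(frames_a, frames_b)
        rf_p = out[(out["model"] == "rf")]["p"]
        np.testing.assert_allclose(rf_p, 0.25)

    def test_mismatched_splits_rejected(self, rng):
        a = pd.concat([metrics_frame(rng, m) for m in ("rf", "gb", "svm")])
        b = pd.concat(
            [metrics_frame(rng, m, n=5) for m in ("rf", "gb", "svm")]
        )
        with pytest.raises(ValueError, match="same split seeds"):
            compare_smote_pipelines(a, b)


class TestImportanceConcordance:
    def test_identical_and_reversed(self, rng):
        v = rng.random(34)
        v /= v.sum()
        rho, _ = importance_concordance(v, v)
        assert rho == pytest.approx(1.0)
        rho_r, _ = importance_concordance(v, -v)
        assert rho_r == pytest.approx(-1.0)

    def test_tie_free_matches_closed_form_and_scipy(self, rng):
        for _ in range(100):
            n = int(rng.integers(5, 40))
            a = rng.permutation(n).astype(float) + rng.random(n) * 0.01
            b = rng.permutation(n).astype(float) + rng.random(n) * 0.01
            rho, p = importance_concordance(a, b)
            assert rho == pytest.approx(
                oracles.spearman_closed_form(list(a), list(b)), rel=1e-9)
            rho_sp, p_sp = sps.spearmanr(a, b)
            assert rho == pytest.approx(rho_sp, rel=1e-9)
            if n > 8 and abs(rho) < 1:
                assert p == pytest.approx(p_sp, rel=1e-6)


class TestRepeatedSplits:
    def test_cardinality_and_determinism(self, small_table):
        grids = GridSpec.small()
        a = run_repeated_splits(small_table, grids, n_splits=2)
        b = run_repeated_splits(small_table, grids, n_splits=2)
        assert len(a.metrics) == 4 * 2  # 4 models x n_splits
        assert set(a.metrics["model"]) == {"rf", "gb", "svm", "ensemble"}
        pd.testing.assert_frame_equal(a.metrics, b.metrics)
        assert a.best_params == b.best_params
        np.testing.assert_array_equal(
            a.importances["rf"], b.importances["rf"]
        )
        assert a.importances["rf"].shape == (34,)
        assert a.importances["rf"].sum() == pytest.approx(1.0)

    def test_specificity_equals_hoa_recall_every_split(self, recovery_run):
        m = recovery_run.metrics
        np.testing.assert_allclose(
            m["specificity"], m["tn"] / (m["tn"] + m["fp"])
        )
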