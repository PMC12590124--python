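"""Feature selection, confusion/ROC metrics, SVM evaluation, bootstrap AUC
comparison, and the modality likelihood-ratio test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from epiosc.classify import (
    bootstrap_auc_compare,
    chi2_independence,
    confusion_metrics,
    lrt_modality,
    roc_auc,
    select_features_anova,
    train_eval_svm,
)


def _labels(n_per):
    return np.repeat([0, 1], n_per)


class TestSelectFeaturesAnova:
    def test_planted_feature_selected_among_noise(self, rng):
        n = 20
        y = _labels(n)
        X = pd.DataFrame(rng.standard_normal((2 * n, 10)),
                         columns=[f"f{i}" for i in range(10)])
        X["f0"] += 5.0 * y
        table = select_features_anova(X, y)
        assert table.loc["f0", "selected"]
        assert table["selected"].sum() <= 3  # few false selections expected

    def test_null_selection_rate_consistent_with_fdr(self, rng):
        any_selected = 0
        n_rep = 200
        for _ in range(n_rep):
            y = _labels(10)
            X = pd.DataFrame(rng.standard_normal((20, 8)))
            X.columns = [f"f{i}" for i in range(8)]
            any_selected += select_features_anova(X, y)["selected"].any()
        # under the global null, BH controls FWER at q: expect <= ~5% plus slack
        assert any_selected / n_rep < 0.1

    def test_importance_is_neg_log10(self, rng):
        y = _labels(15)
        X = pd.DataFrame({"f0": rng.standard_normal(30) + 2.0 * y})
        table = select_features_anova(X, y)
        assert table.loc["f0", "importance"] == pytest.approx(
            -np.log10(table.loc["f0", "p_fdr"])
        )

    def test_excluded_features_dropped(self, rng):
        y = _labels(10)
        X = pd.DataFrame(rng.standard_normal((20, 2)), columns=["keep", "asm"])
        table = select_features_anova(X, y, exclude=("asm",))
        assert "asm" not in table.index

    def test_zero_variance_skipped_with_warning(self, rng):
        y = _labels(10)
        X = pd.DataFrame({"flat": np.ones(20), "ok": rng.standard_normal(20)})
        with pytest.warns(UserWarning, match="zero variance"):
            table = select_features_anova(X, y)
        assert list(table.index) == ["ok"]


class TestConfusionMetrics:
    def test_worked_example(self):
        m = confusion_metrics(9, 8, 2, 1)
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.8)
        assert m["ppv"] == pytest.approx(9 / 11)
        assert m["npv"] == pytest.approx(8 / 9)
        assert m["accuracy"] == pytest.approx(0.85)

    def test_perfect_classifier(self):
        assert all(v == 1.0 for v in confusion_metrics(5, 5, 0, 0).values())

    def test_undefined_ratio_is_missing(self):
        m = confusion_metrics(0, 5, 0, 5)
        assert np.isnan(m["ppv"])
        assert m["accuracy"] == 0.5

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(-1, 1, 1, 1)

    @given(st.integers(1, 10), st.integers(0, 10), st.integers(0, 10),
           st.integers(0, 10), st.integers(1, 5))
    def test_invariant_to_count_scaling(self, tp, tn, fp, fn, k):
        base = confusion_metrics(tp, tn, fp, fn)
        scaled = confusion_metrics(k * tp, k * tn, k * fp, k * fn)
        for key in base:
            if np.isnan(base[key]):
                assert np.isnan(scaled[key])
            else:
                assert scaled[key] == pytest.approx(base[key])


def concordance_auc(scores, labels):
    """Mann-Whitney formulation: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(scores, float)
    y = np.asarray(labels, int)
    pos, neg = s[y == 1], s[y == 0]
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return (gt + 0.5 * eq) / (pos.size * neg.size)


class TestRocAuc:
    def test_perfect_separation(self):
        res = roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
        assert res.auc == pytest.approx(1.0)
        assert res.youden_sensitivity == 1.0 and res.youden_specificity == 1.0
        assert 0.2 < res.youden_threshold <= 0.8

    def test_constant_scores_give_half(self):
        res = roc_auc(np.ones(10), _labels(5))
        assert res.auc == pytest.approx(0.5)

    def test_matches_concordance_oracle(self, rng):
        for _ in range(50):
            s = rng.integers(0, 5, size=30).astype(float)  # many ties
            y = rng.integers(0, 2, size=30)
            if y.sum() in (0, 30):
                continue
            res = roc_auc(s, y)
            assert res.auc == pytest.approx(concordance_auc(s, y), abs=1e-12)

    def test_null_scores_centre_on_half(self, rng):
        aucs = [
            roc_auc(rng.standard_normal(100), _labels(50)).auc for _ in range(200)
        ]
        se = np.std(aucs) / np.sqrt(len(aucs))
        assert abs(np.mean(aucs) - 0.5) < 3 * se + 0.01

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestChi2:
    def test_diagonal_table(self):
        chi2, p = chi2_independence([[50, 0], [0, 50]])
        assert chi2 == pytest.approx(100.0)
        assert p < 1e-20

    def test_independence(self):
        chi2, p = chi2_independence([[25, 25], [25, 25]])
        assert chi2 == 0.0 and p == pytest.approx(1.0)

    def test_matches_pearson_formula(self, rng):
        for _ in range(100):
            obs = rng.integers(1, 50, size=(2, 2)).astype(float)
            chi2, _ = chi2_independence(obs)
            row, col = obs.sum(axis=1), obs.sum(axis=0)
            exp = np.outer(row, col) / obs.sum()
            assert chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(), rel=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError):
            chi2_independence([[0, 0], [5, 5]])


class TestTrainEvalSvm:
    def _separable(self, rng, n=20):
        y = _labels(n)
        X = pd.DataFrame({
            "a": y * 3.0 + 0.3 * rng.standard_normal(2 * n),
            "b": -y * 2.0 + 0.3 * rng.standard_normal(2 * n),
        })
        return X, y

    def test_separable_data_classified_nearly_perfectly(self, rng):
        X, y = self._separable(rng)
        rep = train_eval_svm(X, y, n_splits=100, seed=0)
        assert rep.split_metrics["accuracy"].mean() >= 0.95
        assert np.mean(rep.aucs) >= 0.98
        assert rep.chi2_p < 1e-10

    def test_shuffled_labels_at_chance(self, rng):
        X, y = self._separable(rng, n=25)
        y_perm = rng.permutation(y)
        rep = train_eval_svm(X, y_perm, n_splits=100, seed=1)
        acc = rep.split_metrics["accuracy"].mean()
        # chance band around the majority rate for a 10-sample test set
        assert 0.3 < acc < 0.7

    def test_deterministic_given_seed(self, rng):
        X, y = self._separable(rng)
        r1 = train_eval_svm(X, y, n_splits=20, seed=42)
        r2 = train_eval_svm(X, y, n_splits=20, seed=42)
        assert r1.pooled_confusion == r2.pooled_confusion
        np.testing.assert_array_equal(r1.aucs, r2.aucs)
        assert r1.gamma == r2.gamma

    def test_gamma_recorded_and_overridable(self, rng):
        X, y = self._separable(rng)
        rep = train_eval_svm(X, y, n_splits=5, seed=0, gamma=0.7)
        assert rep.gamma == 0.7

    def test_leakage_safe_normalization_stays_at_chance_on_noise(self, rng):
        y = _labels(20)
        X = pd.DataFrame(rng.standard_normal((40, 5)))
        X.columns = [f"f{i}" for i in range(5)]
        rep = train_eval_svm(X, y, n_splits=100, seed=3, scaling="train")
        assert 0.3 < rep.split_metrics["accuracy"].mean() < 0.7


class TestBootstrapAucCompare:
    def test_identical_pools_not_significant(self, rng):
        pool = rng.uniform(0.6, 0.9, size=200)
        p = bootstrap_auc_compare(pool, pool, n_boot=2000, seed=0)
        assert p >= 0.9

    def test_separated_pools_significant(self, rng):
        a = rng.normal(0.9, 0.01, size=200)
        b = a - 0.2
        p = bootstrap_auc_compare(a, b, n_boot=10000, seed=0)
        assert p <= 0.001

    def test_resolution_at_ten_draws(self, rng):
        a = rng.uniform(size=50)
        b = rng.uniform(size=50)
        p = bootstrap_auc_compare(a, b, n_boot=10, seed=1)
        assert p == pytest.approx(round(p * 10) / 10, abs=1e-12)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            bootstrap_auc_compare([], [0.5])


class TestLrtModality:
    def test_duplicate_feature_adds_nothing(self, rng):
        n = 60
        y = _labels(n // 2)
        base = pd.DataFrame({"x": y + 0.8 * rng.standard_normal(n)})
        added = pd.DataFrame({"x_copy": base["x"]})
        res = lrt_modality(base, added, y)
        assert res.delta_deviance == pytest.approx(0.0, abs=1e-4)
        assert res.p > 0.9

    def test_informative_added_feature_detected(self, rng):
        hits = 0
        n_rep = 20
        for _ in range(n_rep):
            n = 80
            y = _labels(n // 2)
            base = pd.DataFrame({"x": rng.standard_normal(n)})
            added = pd.DataFrame({"z": 1.5 * y + rng.standard_normal(n)})
            res = lrt_modality(base, added, y)
            hits += res.p < 0.05
        assert hits >= 0.9 * n_rep

    def test_null_delta_deviance_chi2_distributed(self, rng):
        # noise-added features at df=3: delta deviance ~ chi2(3); the
        # reference is asymptotic, so use a comfortably large sample
        deltas = []
        for _ in range(300):
            n = 200
            y = _labels(n // 2)
            base = pd.DataFrame({"x": y + rng.standard_normal(n)})
            added = pd.DataFrame(rng.standard_normal((n, 3)), columns=list("abc"))
            res = lrt_modality(base, added, y)
            deltas.append(res.delta_deviance)
        deltas = np.sort(deltas)
        ecdf = np.arange(1, len(deltas) + 1) / len(deltas)
        ks = np.max(np.abs(ecdf - sps.chi2.cdf(deltas, 3)))
        assert ks < 0.1

    def test_df_counts_added_columns(self, rng):
        y = _labels(30)
        base = pd.DataFrame({"x": rng.standard_normal(60)})
        added = pd.DataFrame(rng.standard_normal((60, 3)), columns=list("abc"))
        assert lrt_modality(base, added, y).df == 3
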