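"""LASSO selection, classifier CV and external-validation arithmetic."""

import numpy as np
import pandas as pd
import pytest

from lesionrad.multivariate import (
    confusion_metrics,
    external_validate,
    fit_classifiers,
    lasso_select,
)


def make_frame(X, prefix="f"):
    return pd.DataFrame(
        X, columns=[f"{prefix}{i}" for i in range(X.shape[1])],
        index=[f"P{i}" for i in range(X.shape[0])],
    )


class TestConfusionMetrics:
    @pytest.mark.parametrize(
        "tp,tn,fp,fn,acc,sen,spec",
        [
            (11, 10, 2, 1, 0.875, 11 / 12, 10 / 12),
            (10, 9, 3, 2, 19 / 24, 10 / 12, 9 / 12),
        ],
    )
    def test_exact_arithmetic(self, tp, tn, fp, fn, acc, sen, spec):
        m = confusion_metrics(tp, tn, fp, fn)
        assert m["acc"] == pytest.approx(acc, abs=1e-12)
        assert m["sen"] == pytest.approx(sen, abs=1e-12)
        assert m["spec"] == pytest.approx(spec, abs=1e-12)

    def test_all_correct(self):
        m = confusion_metrics(5, 5, 0, 0)
        assert m["acc"] == m["sen"] == m["spec"] == 1.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 0, 0, 0)


class TestLasso:
    def test_recovers_known_support(self, rng):
        """y identical to f0, all other features pure noise: only f0 can
        reduce the CV MSE, so the selection is exactly {f0}."""
        n = 200
        X = rng.normal(0, 1, (n, 6))
        y = rng.integers(0, 2, n).astype(float)
        X[:, 0] = y
        sel = lasso_select(make_frame(X), pd.Series(y, index=[f"P{i}" for i in range(n)]))
        assert sel.selected == ["f0"]

    def test_huge_alpha_empty_selection(self, rng):
        n = 100
        X = rng.normal(0, 1, (n, 5))
        y = pd.Series(rng.integers(0, 2, n).astype(float), index=[f"P{i}" for i in range(n)])
        sel = lasso_select(make_frame(X), y, alphas=np.array([1e6]))
        assert sel.selected == []

    def test_selected_set_shrinks_along_path(self, rng):
        """Weak monotonicity of the active set in the penalty weight."""
        from sklearn.linear_model import Lasso
        from sklearn.preprocessing import StandardScaler

        n = 120
        X = rng.normal(0, 1, (n, 8))
        beta = np.array([2.0, -1.5, 1.0, 0, 0, 0, 0, 0])
        y = X @ beta + rng.normal(0, 0.5, n)
        Xs = StandardScaler().fit_transform(X)
        sizes = []
        for alpha in (0.01, 0.05, 0.2, 0.8, 3.0):
            m = Lasso(alpha=alpha).fit(Xs, y)
            sizes.append(int(np.sum(m.coef_ != 0)))
        assert all(a >= b for a, b in zip(sizes, sizes[1:]))

    def test_duplicated_informative_feature(self, rng):
        n = 200
        X = rng.normal(0, 1, (n, 4))
        y = (X[:, 0] + rng.normal(0, 0.3, n) > 0).astype(float)
        X = np.column_stack([X, X[:, 0]])  # f4 duplicates f0
        sel = lasso_select(make_frame(X), pd.Series(y, index=[f"P{i}" for i in range(n)]))
        assert {"f0", "f4"} & set(sel.selected)

    def test_constant_column_dropped_with_warning(self, rng):
        n = 80
        X = rng.normal(0, 1, (n, 3))
        X[:, 2] = 5.0
        y = pd.Series((X[:, 0] > 0).astype(float), index=[f"P{i}" for i in range(n)])
        with pytest.warns(UserWarning):
            sel = lasso_select(make_frame(X), y)
        assert "f2" in sel.dropped_constant
        assert "f2" not in sel.coefficients.index


class TestClassifiers:
    def _data(self, rng, n=80, signal=True):
        X = rng.normal(0, 1, (n, 4))
        y = rng.integers(0, 2, n)
        if signal:
            X[:, 0] += 2.5 * y
        idx = [f"P{i}" for i in range(n)]
        return make_frame(X), pd.Series(y, index=idx)

    def test_null_labels_auc_near_half(self, rng):
        X, y = self._data(rng, n=100, signal=False)
        reports = fit_classifiers(X, y, model_names=("LDA", "KNN"), seed=3)
        for rep in reports.values():
            assert abs(rep.cv_median["auc"] - 0.5) < 0.25
            lo, hi = rep.cv_ci["auc"]
            assert lo <= 0.5 <= hi

    def test_signal_recovered_and_winner_flagged(self, rng):
        X, y = self._data(rng, n=100)
        reports = fit_classifiers(X, y, seed=0)
        assert sum(r.winner for r in reports.values()) == 1
        winner = next(r for r in reports.values() if r.winner)
        assert winner.cv_median["auc"] > 0.85

    def test_reproducible_given_seed(self, rng):
        X, y = self._data(rng)
        a = fit_classifiers(X, y, model_names=("KNN",), seed=7)["KNN"]
        b = fit_classifiers(X, y, model_names=("KNN",), seed=7)["KNN"]
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)

    def test_duplicated_features_leave_knn_unchanged(self, rng):
        """With per-fold standardization, replicating a feature rescales all
        distances equally, so KNN predictions are unchanged."""
        X, y = self._data(rng, n=60)
        X1 = X[["f0"]]
        X48 = pd.concat([X1] * 48, axis=1)
        X48.columns = [f"c{i}" for i in range(48)]
        a = fit_classifiers(X1, y, model_names=("KNN",), seed=5)["KNN"]
        b = fit_classifiers(X48, y, model_names=("KNN",), seed=5)["KNN"]
        pd.testing.assert_frame_equal(a.fold_metrics, b.fold_metrics)


class TestExternalValidation:
    def test_confusion_and_metrics_consistent(self, rng):
        Xt, yt = TestClassifiers()._data(rng, n=80)
        Xv, yv = TestClassifiers()._data(rng, n=24)
        rep = external_validate("LDA", Xt, yt, Xv, yv)
        c = rep.confusion
        assert sum(c.values()) == 24
        m = confusion_metrics(**c)
        assert rep.external["acc"] == pytest.approx(m["acc"], abs=1e-12)

    def test_no_leak_from_validation_labels(self, rng):
        """Shuffling validation labels must not change predictions, hence
        the confusion matrix realigns exactly with the permutation."""
        Xt, yt = TestClassifiers()._data(rng, n=80)
        Xv, yv = TestClassifiers()._data(rng, n=30)
        rep1 = external_validate("DT", Xt, yt, Xv, yv, seed=1)
        perm = pd.Series(
            np.random.default_rng(9).permutation(yv.to_numpy()), index=yv.index
        )
        rep2 = external_validate("DT", Xt, yt, Xv, perm, seed=1)
        # total positives called is a pure function of the model + features
        called1 = rep1.confusion["tp"] + rep1.confusion["fp"]
        called2 = rep2.confusion["tp"] + rep2.confusion["fp"]
        assert called1 == called2
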