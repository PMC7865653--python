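"""LASSO feature selection and cross-validated classifier comparison.

The predictor set is chosen by L1-penalized linear regression on the 0/1
class label, with the penalty weight picked as the minimizer of 10-fold
cross-validated mean squared error; features with nonzero coefficients at
that penalty survive.  Five classifier families (LDA, RBF-kernel SVM, KNN,
a single-hidden-layer neural net, and a depth-limited decision tree) are
compared by stratified 10-fold cross-validation — median and 95% percentile
interval of AUC/ACC/SEN/SPEC across folds — and the winner (highest median
AUC, ties broken by accuracy) is refit on the whole training cohort and
scored once on a held-out validation cohort via its confusion matrix.
Standardization is always fit inside the training portion only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.linear_model import LassoCV
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, KFold, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

__all__ = [
    "LassoSelection",
    "lasso_select",
    "ModelReport",
    "fit_classifiers",
    "external_validate",
    "confusion_metrics",
    "MODEL_NAMES",
    "make_model",
]

MODEL_NAMES = ("LDA", "SVM", "KNN", "NNET", "DT")


@dataclass
class LassoSelection:
    """Outcome of the cross-validated LASSO screen."""

    alphas: np.ndarray  # regularization path, descending
    cv_mse: np.ndarray  # mean CV MSE per alpha
    alpha_opt: float
    selected: list[str]
    coefficients: pd.Series
    dropped_constant: list[str] = field(default_factory=list)


def lasso_select(
    features: pd.DataFrame,
    labels: pd.Series,
    alphas: np.ndarray | None = None,
    folds: int = 10,
    seed: int = 0,
) -> LassoSelection:
    """Features with nonzero LASSO coefficients at the CV-MSE-optimal alpha.

    The 0/1 label is regressed on standardized features under squared-error
    loss; alpha minimizes the mean 10-fold CV MSE.  Constant feature
    columns are dropped with a warning before fitting.
    """
    y = labels.loc[features.index].to_numpy(dtype=float)
    X = features.copy()
    constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if constant:
        warnings.warn(f"dropping constant features: {constant}", stacklevel=2)
        X = X.drop(columns=constant)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    model = LassoCV(
        alphas=100 if alphas is None else alphas,
        cv=cv, random_state=seed, max_iter=50000,
    )
    model.fit(Xs, y)
    coefs = pd.Series(model.coef_, index=X.columns)
    selected = list(coefs.index[coefs != 0.0])
    return LassoSelection(
        alphas=np.atleast_1d(model.alphas_),
        cv_mse=np.atleast_2d(model.mse_path_).mean(axis=1),
        alpha_opt=float(model.alpha_),
        selected=selected,
        coefficients=coefs,
        dropped_constant=constant,
    )


def make_model(name: str, n_features: int, seed: int = 0, knn_k: int | None = None):
    """A standardize-then-classify pipeline for one model family.

    Hyperparameters not dictated by the analysis design: KNN's k is tuned
    over {3,5,7,9} by inner CV unless fixed; the SVM uses an RBF kernel
    with inner-CV cost selection; the neural net has one hidden layer as
    wide as the predictor set; the tree is depth-limited to 4.
    """
    if name == "LDA":
        clf = LinearDiscriminantAnalysis()
    elif name == "SVM":
        clf = GridSearchCV(
            SVC(kernel="rbf", gamma="scale"),
            {"C": [0.1, 1.0, 10.0]},
            cv=3,
            scoring="roc_auc",
        )
    elif name == "KNN":
        if knn_k is not None:
            clf = KNeighborsClassifier(n_neighbors=knn_k)
        else:
            clf = GridSearchCV(
                KNeighborsClassifier(),
                {"n_neighbors": [3, 5, 7, 9]},
                cv=3,
                scoring="roc_auc",
            )
    elif name == "NNET":
        clf = MLPClassifier(
            hidden_layer_sizes=(max(2, n_features),),
            max_iter=2000,
            random_state=seed,
        )
    elif name == "DT":
        clf = DecisionTreeClassifier(max_depth=4, random_state=seed)
    else:
        raise ValueError(f"unknown model {name!r}")
    return Pipeline([("scale", StandardScaler()), ("clf", clf)])


def _scores(model, X: np.ndarray) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        try:
            return model.predict_proba(X)[:, 1]
        except AttributeError:
            pass
    return model.decision_function(X)


def confusion_metrics(tp: int, tn: int, fp: int, fn: int) -> dict[str, float]:
    """Exact accuracy / sensitivity / specificity from confusion counts."""
    total = tp + tn + fp + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    return {
        "acc": (tp + tn) / total,
        "sen": tp / (tp + fn) if (tp + fn) else float("nan"),
        "spec": tn / (tn + fp) if (tn + fp) else float("nan"),
    }


@dataclass
class ModelReport:
    """CV summary (and, for the winner, external validation) of one model."""

    model: str
    predictors: list[str]
    cv_median: dict[str, float]
    cv_ci: dict[str, tuple[float, float]]
    fold_metrics: pd.DataFrame
    external: dict[str, float] | None = None
    confusion: dict[str, int] | None = None
    winner: bool = False

    def to_dict(self) -> dict:
        out = {
            "model": self.model,
            "predictors": self.predictors,
            "cv_median": self.cv_median,
            "cv_ci_95": {k: list(v) for k, v in self.cv_ci.items()},
            "winner": self.winner,
        }
        if self.external is not None:
            out["external"] = self.external
        if self.confusion is not None:
            out["confusion"] = self.confusion
        return out


def fit_classifiers(
    features: pd.DataFrame,
    labels: pd.Series,
    model_names: tuple[str, ...] = MODEL_NAMES,
    folds: int = 10,
    seed: int = 0,
) -> dict[str, ModelReport]:
    """Stratified k-fold CV comparison of the model families.

    Per fold and model: fit on the training portion (standardization
    included in the pipeline, so fit within the fold), score the held-out
    patients, record AUC/ACC/SEN/SPEC.  Reported are the median and the
    2.5-97.5 percentile interval across folds.  The report of the model
    with the highest median AUC (ties: highest median ACC) carries
    ``winner=True``.
    """
    y = labels.loc[features.index].to_numpy(dtype=int)
    X = features.to_numpy(dtype=float)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        folds = max(2, int(counts.min()))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    reports: dict[str, ModelReport] = {}
    for name in model_names:
        rows = []
        for tr, te in skf.split(X, y):
            if len(np.unique(y[te])) < 2:
                continue  # AUC undefined on a single-class fold
            model = make_model(name, n_features=X.shape[1], seed=seed)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X[tr], y[tr])
            score = _scores(model, X[te])
            pred = model.predict(X[te])
            tp = int(np.sum((pred == 1) & (y[te] == 1)))
            tn = int(np.sum((pred == 0) & (y[te] == 0)))
            fp = int(np.sum((pred == 1) & (y[te] == 0)))
            fn = int(np.sum((pred == 0) & (y[te] == 1)))
            m = confusion_metrics(tp, tn, fp, fn)
            m["auc"] = roc_auc_score(y[te], score)
            rows.append(m)
        fold_df = pd.DataFrame(rows)
        med = {k: float(fold_df[k].median()) for k in ("auc", "acc", "sen", "spec")}
        ci = {
            k: (
                float(np.nanpercentile(fold_df[k], 2.5)),
                float(np.nanpercentile(fold_df[k], 97.5)),
            )
            for k in ("auc", "acc", "sen", "spec")
        }
        reports[name] = ModelReport(
            model=name,
            predictors=list(features.columns),
            cv_median=med,
            cv_ci=ci,
            fold_metrics=fold_df,
        )
    best = max(reports.values(), key=lambda r: (r.cv_median["auc"], r.cv_median["acc"]))
    best.winner = True
    return reports


def external_validate(
    model_name: str,
    train_features: pd.DataFrame,
    train_labels: pd.Series,
    valid_features: pd.DataFrame,
    valid_labels: pd.Series,
    seed: int = 0,
) -> ModelReport:
    """Refit on the full training cohort; score the validation cohort once.

    Standardization parameters come from the training cohort only (they are
    inside the fitted pipeline).  Returns a report with the external
    confusion matrix and its exactly derived ACC/SEN/SPEC.
    """
    Xt = train_features.to_numpy(dtype=float)
    yt = train_labels.loc[train_features.index].to_numpy(dtype=int)
    Xv = valid_features[train_features.columns].to_numpy(dtype=float)
    yv = valid_labels.loc[valid_features.index].to_numpy(dtype=int)
    model = make_model(model_name, n_features=Xt.shape[1], seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(Xt, yt)
    pred = model.predict(Xv)
    tp = int(np.sum((pred == 1) & (yv == 1)))
    tn = int(np.sum((pred == 0) & (yv == 0)))
    fp = int(np.sum((pred == 1) & (yv == 0)))
    fn = int(np.sum((pred == 0) & (yv == 1)))
    metrics = confusion_metrics(tp, tn, fp, fn)
    if len(np.unique(yv)) == 2:
        metrics["auc"] = float(roc_auc_score(yv, _scores(model, Xv)))
    return ModelReport(
        model=model_name,
        predictors=list(train_features.columns),
        cv_median={},
        cv_ci={},
        fold_metrics=pd.DataFrame(),
        external=metrics,
        confusion={"tp": tp, "tn": tn, "fp": fp, "fn": fn},
    )
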