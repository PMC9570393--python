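"""The six-classifier ensemble and per-model variable importance.

Six algorithms — L1-penalized logistic regression (lasso), a linear support
vector machine, a decision tree, a random forest, a gradient boosting machine,
and a single-hidden-layer neural network — are each fitted on the training
samples restricted to the differentially expressed genes, tuned by stratified
k-fold cross-validation (10 folds by default), and asked for a nonnegative
importance per gene:

========================  ====================================================
model                     raw importance per gene
========================  ====================================================
lasso                     |standardized coefficient| at the CV-selected lambda
svm_linear                |hyperplane coefficient| (primal w)
decision_tree             summed Gini impurity decrease over the tree's splits
random_forest             mean decrease in Gini impurity over 500 trees
gbm                       relative influence (summed squared split
                          improvements), normalized within model
neural_net                Olden connection-weight product magnitude
========================  ====================================================

Features are z-scored with training statistics before the lasso, SVM, and
neural network (making coefficient magnitudes comparable across genes); the
tree-based models consume raw values.  Genes a model never uses receive
importance exactly 0.  Train and test error rates are misclassification
fractions at the 0.5 probability cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegressionCV
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .containers import CASE, ExpressionMatrix, SampleSplit

ALGORITHMS = ("lasso", "svm_linear", "decision_tree", "random_forest", "gbm", "neural_net")

#: short column labels used in weight tables and on-disk artifacts
ALGORITHM_LABELS = {
    "lasso": "Lasso",
    "svm_linear": "SVM",
    "random_forest": "RF",
    "neural_net": "NN",
    "gbm": "GBM",
    "decision_tree": "DT",
}


@dataclass
class ModelSpec:
    """Configuration of one ensemble member.

    Defaults follow the conventions of the corresponding R implementations:
    a 2000-point lambda path for the lasso, linear-kernel SVM cost searched
    over 1..20, tree complexity 1e-6, 500 forest trees, a 100-tree GBM with
    learn rate 0.01 and sample rate 0.8, and one hidden layer of 3 units for
    the neural network.
    """

    algorithm: str
    folds: int = 10
    seed: int = 234
    lasso_n_lambda: int = 2000
    svm_costs: tuple[float, ...] = tuple(range(1, 21))
    tree_min_impurity_decrease: float = 1e-6
    forest_trees: int = 500
    gbm_trees: int = 100
    gbm_learn_rate: float = 0.01
    gbm_sample_rate: float = 0.8
    nn_hidden: tuple[int, ...] = (3,)

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; expected one of {ALGORITHMS}")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        for name in ("lasso_n_lambda", "forest_trees", "gbm_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.gbm_sample_rate <= 1):
            raise ValueError("gbm_sample_rate must be in (0, 1]")


@dataclass
class ImportanceVector:
    """One model's absolute importances over the DEG feature set."""

    model: str
    raw: pd.Series  # gene -> nonnegative importance
    train_error: float
    test_error: float
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        vals = self.raw.to_numpy(dtype=float)
        if (vals < 0).any() or not np.isfinite(vals).all():
            raise ValueError(f"{self.model}: importances must be finite and nonnegative")


def error_rate(predictions, truth) -> float:
    """Misclassification fraction; inputs are equal-length label sequences."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape or predictions.size == 0:
        raise ValueError("predictions and truth must be non-empty and equal length")
    return float(np.mean(predictions != truth))


def _design(matrix: ExpressionMatrix, sample_ids: list[str], features: list[str]):
    sub = matrix.subset_samples(sample_ids)
    X = sub.values.loc[list(features)].to_numpy(dtype=float).T
    y = (sub.groups() == CASE).to_numpy(dtype=int)
    return X, y


def _cv(y: np.ndarray, folds: int, seed: int) -> StratifiedKFold:
    n_min = int(np.bincount(y).min())
    return StratifiedKFold(n_splits=max(2, min(folds, n_min)), shuffle=True, random_state=seed)


def _lambda_path(X: np.ndarray, y: np.ndarray, n_lambda: int) -> np.ndarray:
    """glmnet-style geometric lambda path, returned as C values (ascending)."""
    n = len(y)
    resid = y - y.mean()
    lam_max = np.abs(X.T @ resid).max() / n
    lam_max = max(lam_max, 1e-6)
    ratio = 1e-4 if n > X.shape[1] else 1e-2
    lambdas = np.geomspace(lam_max, lam_max * ratio, n_lambda)
    return np.sort(1.0 / (n * lambdas))


def _standardize(X_train: np.ndarray, X_test: np.ndarray):
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (X_train - mean) / sd, (X_test - mean) / sd


def fit_model(
    matrix: ExpressionMatrix,
    split: SampleSplit,
    features: list[str],
    spec: ModelSpec,
) -> ImportanceVector:
    """Tune and fit one ensemble member; extract importances and error rates.

    The model is tuned by stratified CV on the training samples only; the test
    samples enter only the final error-rate evaluation.
    """
    features = list(features)
    missing = set(features) - set(matrix.gene_ids)
    if missing:
        raise ValueError(f"features absent from matrix: {sorted(missing)}")
    X_train, y_train = _design(matrix, split.train_ids, features)
    X_test, y_test = _design(matrix, split.test_ids, features)
    if len(np.unique(y_train)) < 2:
        raise ValueError("training labels contain a single class")

    cv = _cv(y_train, spec.folds, spec.seed)
    p = len(features)
    hyper: dict = {}

    if spec.algorithm == "lasso":
        Xtr, Xte = _standardize(X_train, X_test)
        Cs = _lambda_path(Xtr, y_train, spec.lasso_n_lambda)
        model = LogisticRegressionCV(
            Cs=Cs,
            cv=cv,
            l1_ratios=(1.0,),  # pure lasso penalty
            solver="liblinear",
            scoring="accuracy",
            max_iter=1000,
            random_state=spec.seed,
            use_legacy_attributes=False,
        )
        model.fit(Xtr, y_train)
        raw = np.abs(model.coef_.ravel())
        chosen_c = float(np.atleast_1d(model.C_)[0])
        hyper = {"C": chosen_c, "lambda": float(1.0 / (len(y_train) * chosen_c))}
        pred_train, pred_test = model.predict(Xtr), model.predict(Xte)

    elif spec.algorithm == "svm_linear":
        Xtr, Xte = _standardize(X_train, X_test)
        search = GridSearchCV(
            SVC(kernel="linear"), {"C": list(spec.svm_costs)}, cv=cv, scoring="accuracy"
        )
        search.fit(Xtr, y_train)
        model = search.best_estimator_
        raw = np.abs(model.coef_.ravel())
        hyper = {"C": float(search.best_params_["C"]), "n_support": int(model.n_support_.sum())}
        pred_train, pred_test = model.predict(Xtr), model.predict(Xte)

    elif spec.algorithm == "decision_tree":
        model = DecisionTreeClassifier(
            criterion="gini",
            min_impurity_decrease=spec.tree_min_impurity_decrease,
            random_state=spec.seed,
        )
        model.fit(X_train, y_train)
        raw = model.tree_.compute_feature_importances(normalize=False)
        hyper = {"n_leaves": int(model.get_n_leaves()), "depth": int(model.get_depth())}
        pred_train, pred_test = model.predict(X_train), model.predict(X_test)

    elif spec.algorithm == "random_forest":
        mtry = max(1, int(np.floor(np.sqrt(p))))
        model = RandomForestClassifier(
            n_estimators=spec.forest_trees,
            max_features=mtry,
            random_state=spec.seed,
        )
        model.fit(X_train, y_train)
        # mean decrease in Gini: average unnormalized impurity decrease per tree
        raw = np.mean(
            [t.tree_.compute_feature_importances(normalize=False) for t in model.estimators_],
            axis=0,
        )
        hyper = {"mtry": mtry, "n_trees": spec.forest_trees}
        pred_train, pred_test = model.predict(X_train), model.predict(X_test)

    elif spec.algorithm == "gbm":
        model = GradientBoostingClassifier(
            n_estimators=spec.gbm_trees,
            learning_rate=spec.gbm_learn_rate,
            subsample=spec.gbm_sample_rate,
            random_state=spec.seed,
        )
        model.fit(X_train, y_train)
        raw = model.feature_importances_.copy()  # relative influence, sums to 1
        hyper = {
            "n_trees": spec.gbm_trees,
            "learn_rate": spec.gbm_learn_rate,
            "sample_rate": spec.gbm_sample_rate,
        }
        pred_train = (model.predict_proba(X_train)[:, 1] > 0.5).astype(int)
        pred_test = (model.predict_proba(X_test)[:, 1] > 0.5).astype(int)

    elif spec.algorithm == "neural_net":
        Xtr, Xte = _standardize(X_train, X_test)
        model = MLPClassifier(
            hidden_layer_sizes=spec.nn_hidden,
            solver="lbfgs",
            max_iter=5000,
            random_state=spec.seed,
        )
        model.fit(Xtr, y_train)
        # Olden importance: product of input->hidden and hidden->...->output weights
        w = model.coefs_[0]
        for layer in model.coefs_[1:]:
            w = w @ layer
        raw = np.abs(w.ravel())
        hyper = {"hidden": list(spec.nn_hidden)}
        pred_train, pred_test = model.predict(Xtr), model.predict(Xte)

    else:  # pragma: no cover - guarded by ModelSpec
        raise ValueError(spec.algorithm)

    return ImportanceVector(
        model=spec.algorithm,
        raw=pd.Series(np.asarray(raw, dtype=float), index=pd.Index(features, name="gene")),
        train_error=error_rate(pred_train, y_train),
        test_error=error_rate(pred_test, y_test),
        hyperparameters=hyper,
    )


def fit_all_models(
    matrix: ExpressionMatrix,
    split: SampleSplit,
    features: list[str],
    seed: int = 234,
    overrides: dict[str, ModelSpec] | None = None,
) -> list[ImportanceVector]:
    """Fit every ensemble member with a shared seed policy."""
    overrides = overrides or {}
    return [
        fit_model(matrix, split, features, overrides.get(alg, ModelSpec(algorithm=alg, seed=seed)))
        for alg in ALGORITHMS
    ]
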