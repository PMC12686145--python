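"""Algorithm registry for the ensemble model search.

Twelve classifiers (random forest, Lasso, Ridge, elastic net, stepwise GLM,
boosted GLM, LDA, PLS-GLM, GBM, XGBoost, SVM, naive Bayes) are combined
with nine feature-selection-capable methods, plus five standalone
embedded-sparsity models, giving the default manifest of
9 × 12 + 5 = 113 selector × classifier combinations.

Established estimators come from scikit-learn / xgboost; two that the
Python ecosystem lacks — componentwise logit boosting (a boosted linear
GLM) and forward-stepwise logistic regression by AIC — are implemented
here.  Every classifier is wrapped in a :class:`ModelAdapter` exposing a
uniform scoring surface: ``decision_scores`` (any monotone score, used for
AUC) and ``risk`` (linear predictor for linear models, predicted
non-response probability otherwise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.cross_decomposition import PLSRegression
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.feature_selection import RFE
from sklearn.linear_model import LogisticRegression
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC, LinearSVC
from xgboost import XGBClassifier

__all__ = [
    "ComboSpec",
    "SelectorSpec",
    "ClassifierSpec",
    "AlgorithmRegistry",
    "ModelAdapter",
    "default_registry",
    "reduced_manifest",
    "ComponentwiseLogitBoost",
    "ForwardStepwiseLogistic",
]


class ComponentwiseLogitBoost(BaseEstimator, ClassifierMixin):
    """Boosted linear logistic model with componentwise base learners.

    Each boosting iteration fits the negative-gradient residual of the
    logistic loss by simple least squares on every single feature and adds a
    shrunken update for the best one, yielding a sparse linear predictor.
    """

    def __init__(self, n_iter: int = 100, learning_rate: float = 0.1):
        self.n_iter = n_iter
        self.learning_rate = learning_rate

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        n, p = X.shape
        self.classes_ = np.unique(y)
        base = np.clip(y.mean(), 1e-6, 1 - 1e-6)
        self.intercept_ = float(np.log(base / (1 - base)))
        coef = np.zeros(p)
        colsq = (X ** 2).sum(axis=0)
        colsq[colsq == 0] = np.inf  # constant column: never selected
        f = np.full(n, self.intercept_)
        for _ in range(self.n_iter):
            resid = y - expit(f)
            beta = X.T @ resid / colsq
            gain = beta ** 2 * colsq
            j = int(np.argmax(gain))
            if gain[j] <= 0:
                break
            step = self.learning_rate * beta[j]
            coef[j] += step
            f += step * X[:, j]
        self.coef_ = coef.reshape(1, -1)
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_.ravel() + self.intercept_

    def predict_proba(self, X):
        p = expit(self.decision_function(X))
        return np.column_stack([1 - p, p])

    def predict(self, X):
        return (self.decision_function(X) >= 0).astype(int)


class ForwardStepwiseLogistic(BaseEstimator, ClassifierMixin):
    """Forward-stepwise logistic regression selected by AIC.

    Features are added greedily (unpenalized logistic fit at each step)
    while the AIC improves, up to ``max_features``.
    """

    def __init__(self, max_features: int = 10):
        self.max_features = max_features

    @staticmethod
    def _aic(model, X, y, k):
        p = np.clip(model.predict_proba(X)[:, 1], 1e-12, 1 - 1e-12)
        loglik = float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))
        return 2 * (k + 1) - 2 * loglik

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        self.classes_ = np.unique(y)
        n, p = X.shape
        chosen: list[int] = []
        base = np.clip(y.mean(), 1e-12, 1 - 1e-12)
        best_aic = 2 - 2 * float(
            np.sum(y * np.log(base) + (1 - y) * np.log(1 - base))
        )
        current = None
        while len(chosen) < min(self.max_features, p):
            best_j, best_cand, cand_model = None, best_aic, None
            for j in range(p):
                if j in chosen:
                    continue
                cols = chosen + [j]
                m = LogisticRegression(C=1e6, max_iter=500).fit(X[:, cols], y)
                aic = self._aic(m, X[:, cols], y, len(cols))
                if aic < best_cand - 1e-9:
                    best_j, best_cand, cand_model = j, aic, m
            if best_j is None:
                break
            chosen.append(best_j)
            best_aic, current = best_cand, cand_model
        self.support_ = np.array(sorted(chosen), dtype=int)
        if current is None:  # no feature improved the null AIC
            self._model = LogisticRegression(C=1e6, max_iter=500).fit(
                np.zeros((n, 1)), y
            )
            self._cols = None
        else:
            self._model = LogisticRegression(C=1e6, max_iter=500).fit(
                X[:, self.support_], y
            )
            self._cols = self.support_
        coef = np.zeros(p)
        if self._cols is not None:
            coef[self._cols] = self._model.coef_.ravel()
        self.coef_ = coef.reshape(1, -1)
        self.intercept_ = float(self._model.intercept_[0])
        return self

    def _design(self, X):
        X = np.asarray(X, dtype=float)
        return np.zeros((X.shape[0], 1)) if self._cols is None else X[:, self._cols]

    def decision_function(self, X):
        return self._model.decision_function(self._design(X))

    def predict_proba(self, X):
        return self._model.predict_proba(self._design(X))

    def predict(self, X):
        return self._model.predict(self._design(X))


class PLSLogistic(BaseEstimator, ClassifierMixin):
    """Partial-least-squares regression on the binary outcome.

    The continuous PLS prediction serves as the decision score; the model is
    linear in the input genes.
    """

    def __init__(self, n_components: int = 2):
        self.n_components = n_components

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        self.classes_ = np.unique(y)
        ncomp = int(min(self.n_components, X.shape[1], max(1, X.shape[0] - 1)))
        self._pls = PLSRegression(n_components=ncomp).fit(X, y)
        self.coef_ = np.asarray(self._pls.coef_).reshape(1, -1)
        y_mean = float(np.asarray(self._pls._y_mean).ravel()[0])
        self.intercept_ = y_mean - float(self._pls._x_mean @ self.coef_.ravel())
        return self

    def decision_function(self, X):
        return self._pls.predict(np.asarray(X, dtype=float)).ravel()

    def predict(self, X):
        return (self.decision_function(X) >= 0.5).astype(int)


@dataclass
class ModelAdapter:
    """Uniform wrapper over a fitted classifier.

    ``decision_scores`` returns a monotone score for AUC (decision function
    when available, else positive-class probability); ``risk`` returns the
    linear predictor for linear models and the predicted non-response
    probability for non-linear ones.
    """

    estimator: object
    linear: bool
    name: str = ""

    def fit(self, X, y):
        self.estimator.fit(X, y)
        return self

    def decision_scores(self, X) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "decision_function"):
            return np.asarray(est.decision_function(X), dtype=float).ravel()
        return np.asarray(est.predict_proba(X), dtype=float)[:, 1]

    def risk(self, X) -> np.ndarray:
        if self.linear:
            return self.decision_scores(X)
        return self.probability(X)

    def probability(self, X) -> np.ndarray:
        est = self.estimator
        if hasattr(est, "predict_proba"):
            return np.asarray(est.predict_proba(X), dtype=float)[:, 1]
        # margin-only models: squashed decision score (uncalibrated)
        return expit(self.decision_scores(X))

    @property
    def coefficients(self) -> np.ndarray | None:
        est = self.estimator
        if hasattr(est, "coef_"):
            return np.asarray(est.coef_).ravel()
        return None

    @property
    def intercept(self) -> float | None:
        est = self.estimator
        if hasattr(est, "intercept_"):
            return float(np.atleast_1d(est.intercept_)[0])
        return None

    def embedded_support(self, tol: float = 1e-10) -> np.ndarray | None:
        """Indices of features with non-zero coefficients (linear models)."""
        coef = self.coefficients
        if coef is None:
            return None
        return np.flatnonzero(np.abs(coef) > tol)


@dataclass(frozen=True)
class ComboSpec:
    """One selector × classifier combination (selector None = standalone
    embedded model: the classifier runs on all genes and its own non-zero
    coefficients define the model genes)."""

    combo_id: str
    selector: str | None
    classifier: str


@dataclass
class ClassifierSpec:
    name: str
    factory: callable  # (params: dict, seed: int) -> estimator
    grid: list[dict]
    linear: bool

    def build(self, params: dict, seed: int) -> ModelAdapter:
        return ModelAdapter(self.factory(params, seed), self.linear, self.name)


@dataclass
class SelectorSpec:
    name: str
    select: callable  # (X, y, gene_names, k, seed) -> list[str]


def _topk(importance: np.ndarray, gene_names, k: int) -> list[str]:
    order = np.lexsort((np.asarray(gene_names, dtype=str), -np.abs(importance)))
    return sorted(np.asarray(gene_names, dtype=str)[order[:k]])


def _sel_lasso(X, y, genes, k, seed):
    m = LogisticRegression(
        l1_ratio=1, C=1.0, solver="liblinear", max_iter=1000, random_state=seed
    ).fit(X, y)
    return sorted(np.asarray(genes, dtype=str)[np.abs(m.coef_.ravel()) > 1e-10])


def _sel_enet(X, y, genes, k, seed):
    m = LogisticRegression(
        l1_ratio=0.5, C=1.0, solver="saga",
        max_iter=2000, random_state=seed,
    ).fit(X, y)
    return sorted(np.asarray(genes, dtype=str)[np.abs(m.coef_.ravel()) > 1e-10])


def _sel_ridge_rank(X, y, genes, k, seed):
    m = LogisticRegression(l1_ratio=0, C=1.0, max_iter=1000).fit(X, y)
    return _topk(m.coef_.ravel(), genes, k)


def _sel_stepwise(X, y, genes, k, seed):
    m = ForwardStepwiseLogistic(max_features=k).fit(X, y)
    return sorted(np.asarray(genes, dtype=str)[m.support_])


def _sel_rf(X, y, genes, k, seed):
    m = RandomForestClassifier(n_estimators=150, random_state=seed, n_jobs=1).fit(X, y)
    return _topk(m.feature_importances_, genes, k)


def _sel_gbm(X, y, genes, k, seed):
    m = GradientBoostingClassifier(
        n_estimators=100, max_depth=2, random_state=seed
    ).fit(X, y)
    return _topk(m.feature_importances_, genes, k)


def _sel_xgb(X, y, genes, k, seed):
    m = XGBClassifier(
        n_estimators=100, max_depth=3, learning_rate=0.3,
        random_state=seed, n_jobs=1, verbosity=0,
    ).fit(X, y)
    return _topk(m.feature_importances_, genes, k)


def _sel_pls(X, y, genes, k, seed):
    ncomp = int(min(2, X.shape[1], max(1, X.shape[0] - 1)))
    m = PLSRegression(n_components=ncomp).fit(X, np.asarray(y, dtype=float))
    return _topk(np.asarray(m.coef_).ravel(), genes, k)


def _sel_rfe_svm(X, y, genes, k, seed):
    base = LinearSVC(C=1.0, dual=False, max_iter=5000, random_state=seed)
    step = max(1, int(0.25 * X.shape[1]))
    m = RFE(base, n_features_to_select=min(k, X.shape[1]), step=step).fit(X, y)
    return sorted(np.asarray(genes, dtype=str)[m.support_])


SELECTOR_ORDER = [
    "lasso", "enet", "ridge_rank", "stepwise", "rf_imp",
    "gbm_imp", "xgb_imp", "pls_load", "rfe_svm",
]

CLASSIFIER_ORDER = [
    "rf", "lasso", "ridge", "enet", "stepwise_glm", "glmboost",
    "lda", "pls_glm", "gbm", "xgb", "svm", "naive_bayes",
]

# The five standalone embedded-sparsity models completing the 113-entry grid.
EMBEDDED_ORDER = ["lasso", "ridge", "enet", "glmboost", "stepwise_glm"]


def _classifier_specs() -> dict[str, ClassifierSpec]:
    return {
        "rf": ClassifierSpec(
            "rf",
            lambda p, s: RandomForestClassifier(
                n_estimators=p.get("n_estimators", 15), max_depth=5,
                max_features="sqrt", random_state=s, n_jobs=1,
            ),
            [{"n_estimators": 15}],
            linear=False,
        ),
        "lasso": ClassifierSpec(
            "lasso",
            lambda p, s: LogisticRegression(
                l1_ratio=1, C=p.get("C", 1.0), solver="liblinear",
                max_iter=1000, random_state=s,
            ),
            [{"C": 0.1}, {"C": 1.0}],
            linear=True,
        ),
        "ridge": ClassifierSpec(
            "ridge",
            lambda p, s: LogisticRegression(
                l1_ratio=0, C=p.get("C", 1.0), solver="liblinear",
                max_iter=1000, random_state=s,
            ),
            [{"C": 0.1}, {"C": 1.0}],
            linear=True,
        ),
        "enet": ClassifierSpec(
            "enet",
            lambda p, s: LogisticRegression(
                l1_ratio=0.5, C=p.get("C", 1.0),
                solver="saga", max_iter=300, tol=1e-3, random_state=s,
            ),
            [{"C": 1.0}],
            linear=True,
        ),
        "stepwise_glm": ClassifierSpec(
            "stepwise_glm",
            lambda p, s: ForwardStepwiseLogistic(max_features=p.get("max_features", 10)),
            [{"max_features": 10}],
            linear=True,
        ),
        "glmboost": ClassifierSpec(
            "glmboost",
            lambda p, s: ComponentwiseLogitBoost(n_iter=p.get("n_iter", 100)),
            [{"n_iter": 100}],
            linear=True,
        ),
        "lda": ClassifierSpec(
            "lda",
            lambda p, s: LinearDiscriminantAnalysis(),
            [{}],
            linear=True,
        ),
        "pls_glm": ClassifierSpec(
            "pls_glm",
            lambda p, s: PLSLogistic(n_components=p.get("n_components", 2)),
            [{"n_components": 2}],
            linear=True,
        ),
        "gbm": ClassifierSpec(
            "gbm",
            lambda p, s: GradientBoostingClassifier(
                n_estimators=p.get("n_estimators", 30), max_depth=2, random_state=s,
            ),
            [{"n_estimators": 30}],
            linear=False,
        ),
        "xgb": ClassifierSpec(
            "xgb",
            lambda p, s: XGBClassifier(
                n_estimators=p.get("n_estimators", 20), max_depth=2,
                learning_rate=0.3, tree_method="hist", max_bin=64,
                random_state=s, n_jobs=1, verbosity=0,
            ),
            [{"n_estimators": 20}],
            linear=False,
        ),
        "svm": ClassifierSpec(
            "svm",
            lambda p, s: SVC(
                kernel="rbf", C=p.get("C", 1.0), gamma="scale", random_state=s,
            ),
            [{"C": 1.0}],
            linear=False,
        ),
        "naive_bayes": ClassifierSpec(
            "naive_bayes",
            lambda p, s: GaussianNB(),
            [{}],
            linear=False,
        ),
    }


def _selector_specs() -> dict[str, SelectorSpec]:
    return {
        "lasso": SelectorSpec("lasso", _sel_lasso),
        "enet": SelectorSpec("enet", _sel_enet),
        "ridge_rank": SelectorSpec("ridge_rank", _sel_ridge_rank),
        "stepwise": SelectorSpec("stepwise", _sel_stepwise),
        "rf_imp": SelectorSpec("rf_imp", _sel_rf),
        "gbm_imp": SelectorSpec("gbm_imp", _sel_gbm),
        "xgb_imp": SelectorSpec("xgb_imp", _sel_xgb),
        "pls_load": SelectorSpec("pls_load", _sel_pls),
        "rfe_svm": SelectorSpec("rfe_svm", _sel_rfe_svm),
    }


@dataclass
class AlgorithmRegistry:
    """Named selectors, named classifiers, and an explicit combination
    manifest.  The default manifest has exactly 113 entries:
    9 selectors × 12 classifiers + 5 standalone embedded models."""

    feature_selectors: dict[str, SelectorSpec] = field(default_factory=_selector_specs)
    classifiers: dict[str, ClassifierSpec] = field(default_factory=_classifier_specs)
    manifest: list[ComboSpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.manifest:
            self.manifest = default_manifest()
        for combo in self.manifest:
            if combo.selector is not None and combo.selector not in self.feature_selectors:
                raise ValueError(
                    f"manifest entry {combo.combo_id!r} names unregistered "
                    f"selector {combo.selector!r}"
                )
            if combo.classifier not in self.classifiers:
                raise ValueError(
                    f"manifest entry {combo.combo_id!r} names unregistered "
                    f"classifier {combo.classifier!r}"
                )
        ids = [c.combo_id for c in self.manifest]
        if len(set(ids)) != len(ids):
            raise ValueError("manifest combo ids must be unique")


def default_manifest() -> list[ComboSpec]:
    combos = [
        ComboSpec(f"{sel}+{clf}", sel, clf)
        for sel in SELECTOR_ORDER
        for clf in CLASSIFIER_ORDER
    ]
    combos += [ComboSpec(f"{name}-embedded", None, name) for name in EMBEDDED_ORDER]
    return combos


def default_registry() -> AlgorithmRegistry:
    return AlgorithmRegistry()


def reduced_manifest() -> list[ComboSpec]:
    """A 20-combo manifest for desk-scale experiments.

    Restricted to the embedded-sparsity selector family (lasso and elastic
    net — the family containing the study's winning Lasso selection), whose
    selected-set size adapts to the signal, crossed with ten classifiers.
    """
    classifiers = [
        "lasso", "ridge", "enet", "lda", "naive_bayes",
        "svm", "pls_glm", "glmboost", "rf", "xgb",
    ]
    return [
        ComboSpec(f"{sel}+{clf}", sel, clf)
        for sel in ("lasso", "enet")
        for clf in classifiers
    ]
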