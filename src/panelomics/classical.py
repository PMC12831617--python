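"""Non-deep multi-omics feature rankers.

Four established rankers operating on the standardized combined matrix:

* ``select_kbest_rank`` — univariate ANOVA-F filter (for two classes,
  F equals the square of the pooled Student t statistic);
* ``elastic_net_rank`` — L1+L2-penalized linear regression on 0/1
  labels, ranking by |coefficient|;
* ``svm_rfe_rank`` — linear-SVM recursive feature elimination with the
  squared weight as the elimination criterion;
* ``rf_rank`` — random-forest importance, either mean impurity decrease
  or tree-path attribution (mean |per-sample contribution|, which sums
  exactly to prediction minus base rate for each sample).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import f_classif
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.svm import SVC

from .errors import TrainingError
from .tables import FeatureRanking


@dataclass
class ElasticNetConfig:
    alpha: float | None = None  # None -> chosen by internal CV over alpha_grid
    l1_ratio: float = 0.5
    cv_folds_for_alpha: int = 5
    alpha_grid: tuple = tuple(np.logspace(-4, 0, 40))

    def __post_init__(self) -> None:
        if not (0 <= self.l1_ratio <= 1):
            raise ValueError("l1_ratio must lie in [0, 1]")
        if self.alpha is not None and self.alpha <= 0:
            raise ValueError("alpha must be positive")


@dataclass
class SvmRfeConfig:
    C: float = 1.0
    step: int = 1
    n_select: int = 5

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass
class RfConfig:
    n_trees: int = 500
    max_features: str | float = "sqrt"
    seed: int = 0
    importance_mode: str = "shap"  # or "impurity"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.importance_mode not in ("impurity", "shap"):
            raise ValueError("importance_mode must be 'impurity' or 'shap'")


def _ids(feature_ids, p) -> list[str]:
    if feature_ids is None:
        return [f"f{j}" for j in range(p)]
    feature_ids = list(feature_ids)
    if len(feature_ids) != p:
        raise ValueError("feature_ids length does not match X columns")
    return feature_ids


def _ranking_from_scores(method, feature_ids, scores, k) -> FeatureRanking:
    """Order by descending score, ties broken lexicographically by id."""
    order = sorted(range(len(feature_ids)), key=lambda j: (-scores[j], feature_ids[j]))
    ordered = [feature_ids[j] for j in order]
    return FeatureRanking(
        method=method,
        ordered_features=ordered,
        scores=np.asarray([scores[j] for j in order], dtype=float),
        selected=ordered[:k],
        raw_scores=dict(zip(feature_ids, map(float, scores))),
    )


def select_kbest_rank(
    X: np.ndarray, y: np.ndarray, k: int, feature_ids: Sequence[str] | None = None
) -> FeatureRanking:
    """Univariate F-filter: rank by descending one-way ANOVA F.

    A constant feature gets F = 0 and ranks last.  For two classes the
    F statistic is exactly the square of the pooled-variance Student t.
    """
    X = np.asarray(X, dtype=float)
    feature_ids = _ids(feature_ids, X.shape[1])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant features raise a runtime warning
        F, _ = f_classif(X, np.asarray(y, dtype=int))
    F = np.where(np.isfinite(F), F, 0.0)
    return _ranking_from_scores("selectkbest", feature_ids, F, k)


def elastic_net_rank(
    X: np.ndarray,
    y: np.ndarray,
    config: ElasticNetConfig | None = None,
    n_select: int = 5,
    feature_ids: Sequence[str] | None = None,
) -> FeatureRanking:
    """Elastic-net coefficient ranking on the regression objective.

    The penalized *linear regression* objective is fit with 0/1 labels
    as the response; features are ranked by |coefficient| descending,
    with zero-coefficient features appended afterwards in input order.
    When ``config.alpha`` is None the penalty is chosen by internal
    K-fold CV over a fixed logarithmic grid (deterministic).
    """
    config = config or ElasticNetConfig()
    X = np.asarray(X, dtype=float)
    yf = np.asarray(y, dtype=float)
    feature_ids = _ids(feature_ids, X.shape[1])
    if config.alpha is None:
        # the grid search can run at the default tolerance; the returned
        # coefficients come from a tight refit at the chosen alpha below
        cv_model = ElasticNetCV(
            l1_ratio=config.l1_ratio,
            alphas=np.asarray(config.alpha_grid),
            cv=config.cv_folds_for_alpha,
            max_iter=10_000,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cv_model.fit(X, yf)
        alpha = float(cv_model.alpha_)
    else:
        alpha = config.alpha
    model = ElasticNet(alpha=alpha, l1_ratio=config.l1_ratio, max_iter=100_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X, yf)
    coef = model.coef_
    coef = np.asarray(coef, dtype=float)
    if np.all(coef == 0):
        warnings.warn(
            f"elastic net at alpha={alpha:g} shrank all coefficients to zero; "
            "ranking degenerates to input order",
            UserWarning,
            stacklevel=2,
        )
        ordered = list(feature_ids)
        scores = np.zeros(len(ordered))
        return FeatureRanking(
            method="elasticnet",
            ordered_features=ordered,
            scores=scores,
            selected=ordered[:n_select],
            raw_scores={f: 0.0 for f in feature_ids},
        )
    nonzero = [j for j in range(len(coef)) if coef[j] != 0]
    zero = [j for j in range(len(coef)) if coef[j] == 0]
    nonzero.sort(key=lambda j: (-abs(coef[j]), feature_ids[j]))
    order = nonzero + zero  # zeros keep input order
    ordered = [feature_ids[j] for j in order]
    return FeatureRanking(
        method="elasticnet",
        ordered_features=ordered,
        scores=np.abs(coef[order]),
        selected=ordered[:n_select],
        raw_scores=dict(zip(feature_ids, map(float, coef))),
    )


def svm_rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    config: SvmRfeConfig | None = None,
    feature_ids: Sequence[str] | None = None,
) -> FeatureRanking:
    """Linear-SVM recursive feature elimination.

    Train a soft-margin linear SVM, score each surviving feature by its
    squared weight, remove the ``step`` lowest-scoring features (ties
    broken lexicographically, lowest first), and repeat until
    ``n_select`` survive.  Survivors are ranked by the final weights;
    eliminated features follow in reverse elimination order.
    """
    config = config or SvmRfeConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    feature_ids = _ids(feature_ids, X.shape[1])
    p = len(feature_ids)
    if not (1 <= config.n_select <= p):
        raise ValueError(f"n_select must be in [1, {p}]")

    surviving = list(range(p))
    eliminated: list[tuple[str, float]] = []
    it = 0
    while True:
        try:
            clf = SVC(kernel="linear", C=config.C)
            clf.fit(X[:, surviving], y)
        except Exception as err:  # pragma: no cover - libsvm failure
            raise TrainingError(f"SVM failed at RFE iteration {it}: {err}") from err
        w2 = np.asarray(clf.coef_).ravel() ** 2
        if len(surviving) == config.n_select:
            final_scores = {feature_ids[j]: float(s) for j, s in zip(surviving, w2)}
            break
        n_drop = min(config.step, len(surviving) - config.n_select)
        local = sorted(
            range(len(surviving)), key=lambda i: (w2[i], feature_ids[surviving[i]])
        )[:n_drop]
        for i in sorted(local, reverse=True):
            eliminated.append((feature_ids[surviving[i]], float(w2[i])))
            surviving.pop(i)
        it += 1

    survivors_sorted = sorted(final_scores, key=lambda f: (-final_scores[f], f))
    ordered = survivors_sorted + [fid for fid, _ in reversed(eliminated)]
    raw = dict(final_scores)
    raw.update({fid: s for fid, s in eliminated})
    return FeatureRanking(
        method="svmrfe",
        ordered_features=ordered,
        scores=np.arange(len(ordered), 0, -1, dtype=float),
        selected=survivors_sorted,
        raw_scores=raw,
    )


# ---------------------------------------------------------------------------
# random forest with tree-path attribution
# ---------------------------------------------------------------------------


def tree_path_attributions(forest: RandomForestClassifier, X: np.ndarray):
    """Per-sample additive feature contributions to the class-1 probability.

    Walks every sample's root-to-leaf path in every tree and credits
    each split's change in the node's class-1 fraction to the split
    feature, averaging over trees.  By construction the contributions
    plus the forest's base rate reproduce ``predict_proba`` exactly.

    Returns ``(contributions (n, p), base_value scalar)``.
    """
    X = np.asarray(X, dtype=np.float32)
    n, p = X.shape
    contrib = np.zeros((n, p))
    base = 0.0
    for est in forest.estimators_:
        tree = est.tree_
        value = tree.value[:, 0, :]
        prob1 = value[:, 1] / value.sum(axis=1)
        base += prob1[0]
        feature = tree.feature
        threshold = tree.threshold
        left, right = tree.children_left, tree.children_right
        for i in range(n):
            node = 0
            while left[node] != -1:
                f = feature[node]
                nxt = left[node] if X[i, f] <= threshold[node] else right[node]
                contrib[i, f] += prob1[nxt] - prob1[node]
                node = nxt
    n_trees = len(forest.estimators_)
    return contrib / n_trees, base / n_trees


def rf_rank(
    X: np.ndarray,
    y: np.ndarray,
    config: RfConfig | None = None,
    n_select: int = 5,
    feature_ids: Sequence[str] | None = None,
) -> FeatureRanking:
    """Random-forest importance ranking (impurity or tree-path mode)."""
    config = config or RfConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    feature_ids = _ids(feature_ids, X.shape[1])
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        random_state=config.seed,
    )
    forest.fit(X, y)
    if config.importance_mode == "impurity":
        scores = forest.feature_importances_
    else:
        contrib, _ = tree_path_attributions(forest, X)
        scores = np.abs(contrib).mean(axis=0)
    return _ranking_from_scores(f"rf[{config.importance_mode}]", feature_ids, scores, n_select)
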