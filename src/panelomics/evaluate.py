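"""Panel evaluation, cross-method consensus, and the benchmark harness.

A candidate biomarker panel is scored the way the study design
prescribes: the panel's features feed an L2-regularized logistic
regression under stratified 5-fold cross-validation; accuracy (at
probability threshold 0.5) and ROC AUC are computed on each held-out
fold and reported as mean +/- sd, with pooled out-of-fold scores
defining the plotted ROC curve.  Imputation and standardization are
refit inside every training fold, so panel *evaluation* never leaks.

Panel *selection* is a different matter: the benchmark's default
protocol selects each method's top features on the full table before
cross-validation (select-then-evaluate), which is optimistic on null
data.  A leakage-safe mode that re-runs selection inside each training
fold is available and reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from .classical import (
    ElasticNetConfig,
    RfConfig,
    SvmRfeConfig,
    elastic_net_rank,
    rf_rank,
    select_kbest_rank,
    svm_rfe_rank,
)
from .errors import PanelomicsError
from .fusion import GraphFusionConfig, mogonet_lite_fit, mogonet_lite_rank
from .tables import (
    LAYERS,
    FeatureRanking,
    OmicsTable,
    PhenotypeLabels,
    impute_and_standardize,
)
from .transformer import TransformerConfig, transformer_rfe_rank


@dataclass
class PanelEvaluation:
    """Cross-validated performance of one feature panel."""

    panel: list[str]
    accuracy_mean: float
    accuracy_sd: float
    auc_mean: float
    auc_sd: float
    roc_points: np.ndarray  # (m, 2) pooled out-of-fold (fpr, tpr)
    n_folds: int
    seed: int
    fold_accuracy: np.ndarray = field(default_factory=lambda: np.array([]))
    fold_auc: np.ndarray = field(default_factory=lambda: np.array([]))


@dataclass
class ConsensusResult:
    """Features appearing in the top lists of >= 2 ranking methods."""

    counts: dict[str, int]
    consensus_set: set[str]


def evaluate_panel(
    table: OmicsTable,
    labels: PhenotypeLabels,
    panel: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
) -> PanelEvaluation:
    """Stratified K-fold logistic-regression evaluation of a panel."""
    labels = labels.aligned_to(table)
    missing = [f for f in panel if f not in table.data.columns]
    if missing:
        raise PanelomicsError(f"panel features missing from table: {missing}")
    y = labels.label
    if min(labels.n_cases, labels.n_controls) < n_folds:
        raise PanelomicsError(
            f"each class needs >= {n_folds} samples for {n_folds}-fold CV"
        )
    sub = table.subset_features(list(panel))
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    samples = np.array(sub.sample_ids)
    accs, aucs = [], []
    pooled_scores = np.empty(len(y))
    for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
        std, _ = impute_and_standardize(sub, fit_rows=samples[tr_idx])
        X = std.values
        clf = LogisticRegression(C=1.0, max_iter=5000)
        clf.fit(X[tr_idx], y[tr_idx])
        prob = clf.predict_proba(X[te_idx])[:, 1]
        pooled_scores[te_idx] = prob
        accs.append(accuracy_score(y[te_idx], (prob >= 0.5).astype(int)))
        aucs.append(roc_auc_score(y[te_idx], prob))
    fpr, tpr, _ = roc_curve(y, pooled_scores)
    accs, aucs = np.asarray(accs), np.asarray(aucs)
    return PanelEvaluation(
        panel=list(panel),
        accuracy_mean=float(accs.mean()),
        accuracy_sd=float(accs.std(ddof=1)),
        auc_mean=float(aucs.mean()),
        auc_sd=float(aucs.std(ddof=1)),
        roc_points=np.column_stack([fpr, tpr]),
        n_folds=n_folds,
        seed=seed,
        fold_accuracy=accs,
        fold_auc=aucs,
    )


def consensus_features(
    rankings: Sequence[FeatureRanking] | Sequence[Sequence[str]],
    top_n: int = 5,
) -> ConsensusResult:
    """Features selected by more than one ranking method.

    Accepts either :class:`FeatureRanking` objects (their top ``top_n``
    ordered features are used) or plain feature-id lists.
    """
    if len(rankings) < 2:
        raise ValueError("need at least two rankings for a consensus")
    counts: dict[str, int] = {}
    for r in rankings:
        feats = r.ordered_features[:top_n] if isinstance(r, FeatureRanking) else list(r)[:top_n]
        for f in feats:
            counts[f] = counts.get(f, 0) + 1
    return ConsensusResult(
        counts=counts,
        consensus_set={f for f, c in counts.items() if c >= 2},
    )


# ---------------------------------------------------------------------------
# benchmark harness
# ---------------------------------------------------------------------------

METHODS = ("selectkbest", "elasticnet", "svmrfe", "transformer-rfe", "rf", "mogonet-lite")


def _split_by_layer(std: OmicsTable) -> dict[str, np.ndarray]:
    return {
        layer: std.subset_features(std.layer_features(layer)).values
        for layer in LAYERS
        if std.layer_features(layer)
    }


def rank_features(
    method: str,
    std: OmicsTable,
    y: np.ndarray,
    n_select: int,
    seed: int,
    configs: Mapping[str, object] | None = None,
) -> FeatureRanking:
    """Dispatch one ranking method on a standardized table."""
    configs = configs or {}
    X = std.values
    fids = std.feature_ids
    layer_pos = {layer: i for i, layer in enumerate(LAYERS)}
    layer_index = np.array([layer_pos[l] for l in std.feature_layers])
    if method == "selectkbest":
        return select_kbest_rank(X, y, k=n_select, feature_ids=fids)
    if method == "elasticnet":
        cfg = configs.get("elasticnet", ElasticNetConfig())
        return elastic_net_rank(X, y, cfg, n_select=n_select, feature_ids=fids)
    if method == "svmrfe":
        cfg = configs.get("svmrfe", SvmRfeConfig())
        return svm_rfe_rank(X, y, replace(cfg, n_select=n_select), feature_ids=fids)
    if method == "rf":
        cfg = configs.get("rf", RfConfig())
        return rf_rank(X, y, replace(cfg, seed=seed), n_select=n_select, feature_ids=fids)
    if method == "transformer-rfe":
        cfg = configs.get("transformer", TransformerConfig())
        ranking, _ = transformer_rfe_rank(
            X, y, n_select, replace(cfg, seed=seed),
            feature_ids=fids, layer_index=layer_index,
        )
        return ranking
    if method == "mogonet-lite":
        cfg = configs.get("mogonet", GraphFusionConfig())
        model = mogonet_lite_fit(_split_by_layer(std), y, config=replace(cfg, seed=seed))
        fids_by_layer = {
            layer: std.layer_features(layer)
            for layer in LAYERS
            if std.layer_features(layer)
        }
        return mogonet_lite_rank(model, fids_by_layer, n_select=n_select)
    raise ValueError(f"unknown method {method!r}; choose from {METHODS}")


def benchmark_all(
    table: OmicsTable,
    labels: PhenotypeLabels,
    methods: Sequence[str] = METHODS,
    n_select: int = 5,
    n_folds: int = 5,
    seed: int = 0,
    leakage_safe: bool = False,
    configs: Mapping[str, object] | None = None,
) -> tuple[pd.DataFrame, dict[str, PanelEvaluation], dict[str, FeatureRanking]]:
    """Per-method top-``n_select`` panels with CV accuracy and AUC.

    Default protocol: each method selects its panel on the *full*
    standardized table, then the panel is evaluated by
    :func:`evaluate_panel` (selection optimism is inherited
    deliberately).  With ``leakage_safe=True`` selection is re-run
    inside each training fold and held-out performance of the
    fold-specific panels is reported instead; the returned rankings are
    still the full-table ones for interpretability.
    """
    labels = labels.aligned_to(table)
    y = labels.label
    std_full, _ = impute_and_standardize(table)
    rows = []
    evaluations: dict[str, PanelEvaluation] = {}
    rankings: dict[str, FeatureRanking] = {}
    samples = np.array(table.sample_ids)
    for method in methods:
        ranking = rank_features(method, std_full, y, n_select, seed, configs)
        rankings[method] = ranking
        if not leakage_safe:
            ev = evaluate_panel(table, labels, ranking.selected, n_folds, seed)
        else:
            skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
            accs, aucs = [], []
            pooled = np.empty(len(y))
            for tr_idx, te_idx in skf.split(np.zeros(len(y)), y):
                tr_table = table.subset_samples(samples[tr_idx])
                std_tr, _ = impute_and_standardize(tr_table)
                fold_rank = rank_features(method, std_tr, y[tr_idx], n_select, seed, configs)
                panel = fold_rank.selected
                sub = table.subset_features(panel)
                std, _ = impute_and_standardize(sub, fit_rows=samples[tr_idx])
                X = std.values
                clf = LogisticRegression(C=1.0, max_iter=5000)
                clf.fit(X[tr_idx], y[tr_idx])
                prob = clf.predict_proba(X[te_idx])[:, 1]
                pooled[te_idx] = prob
                accs.append(accuracy_score(y[te_idx], (prob >= 0.5).astype(int)))
                aucs.append(roc_auc_score(y[te_idx], prob))
            fpr, tpr, _ = roc_curve(y, pooled)
            accs, aucs = np.asarray(accs), np.asarray(aucs)
            ev = PanelEvaluation(
                panel=list(ranking.selected),
                accuracy_mean=float(accs.mean()),
                accuracy_sd=float(accs.std(ddof=1)),
                auc_mean=float(aucs.mean()),
                auc_sd=float(aucs.std(ddof=1)),
                roc_points=np.column_stack([fpr, tpr]),
                n_folds=n_folds,
                seed=seed,
                fold_accuracy=accs,
                fold_auc=aucs,
            )
        evaluations[method] = ev
        rows.append(
            {
                "method": method,
                "features": ",".join(ranking.selected),
                "accuracy_mean": ev.accuracy_mean,
                "accuracy_sd": ev.accuracy_sd,
                "auc_mean": ev.auc_mean,
                "auc_sd": ev.auc_sd,
            }
        )
    return pd.DataFrame(rows), evaluations, rankings
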