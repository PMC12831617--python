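"""Recursive feature elimination with a cross-attention transformer.

The estimator is a deliberately small attention classifier suited to
tabular omics data with n << p: every feature becomes one token (its
scalar value projected to ``d_model`` plus a learned per-feature
embedding and a learned omics-layer embedding), and a single learned
query token cross-attends over all feature tokens through a stack of
attention blocks.  The query representation feeds a binary logistic
head.  Parameters scale as O(p * d_model), which keeps the model
trainable on cohorts of fewer than a hundred samples.

Feature importance is a model-agnostic permutation-Shapley estimate:
for each evaluation sample, the average marginal change in the model
logit as features are switched on one at a time in random orders, with
absent features held at the background (training-mean) value.  The
per-feature score is the mean absolute attribution over samples.  The
estimate satisfies the efficiency axiom exactly (attributions telescope
to f(x) - f(background) for every permutation).

Elimination removes exactly one lowest-scoring feature per iteration
(ties broken lexicographically by feature id) and retrains from a fresh
seed derived from the master seed and the iteration index, until the
requested number of features survives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .autodiff import Adam, Tensor, bce_with_logits, layer_norm, softmax
from .errors import TrainingError
from .tables import FeatureRanking


@dataclass
class TransformerConfig:
    d_model: int = 16
    n_heads: int = 4
    n_attention_layers: int = 2
    dropout: float = 0.0
    max_epochs: int = 150
    learning_rate: float = 1e-2
    early_stop_patience: int = 20
    min_epochs: int = 40
    val_fraction: float = 0.2
    n_permutations: int = 128
    rfe_n_permutations: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.max_epochs < 1:
            raise ValueError("max_epochs must be >= 1")


@dataclass
class ShapScores:
    """Mean-|attribution| importance per feature plus audit fields."""

    feature_ids: list[str]
    scores: np.ndarray  # (p,) mean |phi| over evaluation samples
    attributions: np.ndarray  # (n_eval, p) signed Shapley estimates
    base_value: np.ndarray  # (n_eval,) model logit at the background
    n_permutations: int
    background: np.ndarray  # (p,) reference input for masked features


@dataclass
class RfeIteration:
    surviving: list[str]
    eliminated: str
    score: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class RfeTrace:
    iterations: list[RfeIteration] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "iteration": np.arange(1, len(self.iterations) + 1),
                "eliminated_feature": [it.eliminated for it in self.iterations],
                "score": [it.score for it in self.iterations],
                "n_surviving_after": [
                    len(it.surviving) - 1 for it in self.iterations
                ],
            }
        )


def _derive_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, index]).generate_state(1)[0] % 2**31)


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------


class CrossAttentionClassifier:
    """Single-query cross-attention binary classifier over feature tokens."""

    def __init__(self, n_features: int, layer_index: np.ndarray, config: TransformerConfig):
        self.p = n_features
        self.config = config
        self.layer_index = np.asarray(layer_index, dtype=int)
        self.n_layers_omics = int(self.layer_index.max()) + 1 if n_features else 1
        self.background: np.ndarray | None = None
        rng = np.random.default_rng(config.seed)
        d, h = config.d_model, config.n_heads
        s = 1.0 / np.sqrt(d)

        def par(*shape, scale=s):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        self.params: dict[str, Tensor] = {
            "value_vec": par(d),
            "feat_emb": par(self.p, d),
            "layer_emb": par(self.n_layers_omics, d),
            "query": par(d),
            "w_out": par(d),
            "b_out": Tensor(np.zeros(1), requires_grad=True),
        }
        for b in range(config.n_attention_layers):
            for name in ("Wq", "Wk", "Wv", "Wo"):
                self.params[f"{name}{b}"] = par(d, d)
            self.params[f"bo{b}"] = Tensor(np.zeros(d), requires_grad=True)
            self.params[f"W1{b}"] = par(d, 2 * d)
            self.params[f"b1{b}"] = Tensor(np.zeros(2 * d), requires_grad=True)
            self.params[f"W2{b}"] = par(2 * d, d)
            self.params[f"b2{b}"] = Tensor(np.zeros(d), requires_grad=True)
            for ln in ("ln1g", "ln2g"):
                self.params[f"{ln}{b}"] = Tensor(np.ones(d), requires_grad=True)
            for ln in ("ln1b", "ln2b"):
                self.params[f"{ln}{b}"] = Tensor(np.zeros(d), requires_grad=True)

    # -- training-time forward (autodiff) -----------------------------
    def _logits(self, X: np.ndarray, dropout_rng: np.random.Generator | None = None) -> Tensor:
        cfg = self.config
        P = self.params
        n = X.shape[0]
        d, h = cfg.d_model, cfg.n_heads
        dh = d // h
        tokens = (
            Tensor(X[:, :, None]) * P["value_vec"]
            + P["feat_emb"]
            + P["layer_emb"].take(self.layer_index, axis=0)
        )  # (n, p, d)
        q = P["query"].reshape(1, d) + Tensor(np.zeros((n, 1)))  # (n, d)
        for b in range(cfg.n_attention_layers):
            qn = layer_norm(q, P[f"ln1g{b}"], P[f"ln1b{b}"])
            Q = (qn @ P[f"Wq{b}"]).reshape(n, h, 1, dh)
            K = (tokens @ P[f"Wk{b}"]).reshape(n, self.p, h, dh).transpose(0, 2, 1, 3)
            V = (tokens @ P[f"Wv{b}"]).reshape(n, self.p, h, dh).transpose(0, 2, 1, 3)
            scores = (Q @ K.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(dh))
            attn = softmax(scores, axis=-1)  # (n, h, 1, p)
            if dropout_rng is not None and cfg.dropout > 0:
                mask = (dropout_rng.random(attn.shape) >= cfg.dropout) / (
                    1.0 - cfg.dropout
                )
                attn = attn * Tensor(mask)
            ctx = (attn @ V).transpose(0, 2, 1, 3).reshape(n, d)
            q = q + ctx @ P[f"Wo{b}"] + P[f"bo{b}"]
            qn2 = layer_norm(q, P[f"ln2g{b}"], P[f"ln2b{b}"])
            q = q + (qn2 @ P[f"W1{b}"] + P[f"b1{b}"]).relu() @ P[f"W2{b}"] + P[f"b2{b}"]
        return (q @ P["w_out"].reshape(d, 1)).reshape(n) + P["b_out"]

    # -- inference-time forward (plain numpy) --------------------------
    def _np_params(self) -> dict[str, np.ndarray]:
        return {k: v.data for k, v in self.params.items()}

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        """Model logit per sample (no dropout, numpy only)."""
        scorer = _KvCache(self, np.asarray(X, dtype=float))
        return scorer.logits()

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.decision_function(X)
        p1 = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X: np.ndarray) -> np.ndarray:
        return (self.decision_function(X) > 0).astype(int)


class _KvCache:
    """Numpy forward pass with per-column-updatable key/value caches.

    Feature tokens are static across attention blocks (only the query
    updates), so the per-block K and V projections of all tokens can be
    cached; switching one feature's value touches one token row.  This
    makes the permutation-Shapley sweep cheap.
    """

    def __init__(self, model: CrossAttentionClassifier, Z: np.ndarray):
        self.m = model
        self.P = model._np_params()
        cfg = model.config
        self.n = Z.shape[0]
        self.d, self.h = cfg.d_model, cfg.n_heads
        self.dh = self.d // self.h
        self.le = self.P["layer_emb"][model.layer_index]  # (p, d)
        self.K: list[np.ndarray] = []
        self.V: list[np.ndarray] = []
        tokens = (
            Z[:, :, None] * self.P["value_vec"] + self.P["feat_emb"] + self.le
        )
        for b in range(cfg.n_attention_layers):
            self.K.append(
                (tokens @ self.P[f"Wk{b}"])
                .reshape(self.n, model.p, self.h, self.dh)
                .transpose(0, 2, 1, 3)
                .copy()
            )
            self.V.append(
                (tokens @ self.P[f"Wv{b}"])
                .reshape(self.n, model.p, self.h, self.dh)
                .transpose(0, 2, 1, 3)
                .copy()
            )

    def snapshot(self):
        return [k.copy() for k in self.K], [v.copy() for v in self.V]

    def restore(self, snap) -> None:
        self.K = [k.copy() for k in snap[0]]
        self.V = [v.copy() for v in snap[1]]

    def update_column(self, j: int, values: np.ndarray) -> None:
        token = (
            values[:, None] * self.P["value_vec"]
            + self.P["feat_emb"][j]
            + self.le[j]
        )  # (n, d)
        for b in range(self.m.config.n_attention_layers):
            self.K[b][:, :, j, :] = (token @ self.P[f"Wk{b}"]).reshape(
                self.n, self.h, self.dh
            )
            self.V[b][:, :, j, :] = (token @ self.P[f"Wv{b}"]).reshape(
                self.n, self.h, self.dh
            )

    @staticmethod
    def _ln(x, g, b, eps=1e-5):
        mu = x.mean(axis=-1, keepdims=True)
        c = x - mu
        var = (c * c).mean(axis=-1, keepdims=True)
        return c / np.sqrt(var + eps) * g + b

    def logits(self) -> np.ndarray:
        P, n, d, h, dh = self.P, self.n, self.d, self.h, self.dh
        q = np.broadcast_to(P["query"], (n, d)).copy()
        for b in range(self.m.config.n_attention_layers):
            qn = self._ln(q, P[f"ln1g{b}"], P[f"ln1b{b}"])
            Q = (qn @ P[f"Wq{b}"]).reshape(n, h, 1, dh)
            scores = (Q @ np.swapaxes(self.K[b], -1, -2)) / np.sqrt(dh)
            scores -= scores.max(axis=-1, keepdims=True)
            e = np.exp(scores)
            attn = e / e.sum(axis=-1, keepdims=True)
            ctx = (attn @ self.V[b]).transpose(0, 2, 1, 3).reshape(n, d)
            q = q + ctx @ P[f"Wo{b}"] + P[f"bo{b}"]
            qn2 = self._ln(q, P[f"ln2g{b}"], P[f"ln2b{b}"])
            q = q + np.maximum(qn2 @ P[f"W1{b}"] + P[f"b1{b}"], 0.0) @ P[f"W2{b}"] + P[f"b2{b}"]
        return q @ P["w_out"] + P["b_out"][0]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _stratified_split(y: np.ndarray, frac: float, rng: np.random.Generator):
    train, val = [], []
    for cls in (0, 1):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        n_val = max(1, int(round(frac * len(idx)))) if len(idx) > 1 else 0
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.sort(np.array(train, int)), np.sort(np.array(val, int))


def fit_transformer(
    X: np.ndarray,
    y: np.ndarray,
    config: TransformerConfig | None = None,
    layer_index: np.ndarray | None = None,
) -> CrossAttentionClassifier:
    """Train the cross-attention classifier with early stopping.

    ``X`` must already be standardized (see
    :func:`panelomics.tables.impute_and_standardize`); ``y`` is 0/1.
    Training is full-batch Adam with early stopping on a 20% stratified
    validation split; the best-validation parameters are restored.
    Fully reproducible from ``config.seed``.
    """
    config = config or TransformerConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (samples x features)")
    classes = set(np.unique(y))
    if classes != {0, 1}:
        raise TrainingError(f"need both classes in y, got {sorted(classes)}")
    if layer_index is None:
        layer_index = np.zeros(X.shape[1], dtype=int)

    model = CrossAttentionClassifier(X.shape[1], layer_index, config)
    model.background = X.mean(axis=0)
    rng = np.random.default_rng(_derive_seed(config.seed, 10**6))
    if config.val_fraction > 0:
        tr, va = _stratified_split(y, config.val_fraction, rng)
        if len(va) == 0 or len(set(y[va])) < 2:
            tr, va = np.arange(len(y)), np.arange(len(y))
    else:
        # no held-out split: train on everything, early-stop on train loss
        tr = va = np.arange(len(y))
    opt = Adam(list(model.params.values()), lr=config.learning_rate)
    drop_rng = np.random.default_rng(_derive_seed(config.seed, 10**6 + 1))
    best_val = np.inf
    best_state = None
    patience = 0
    history = []
    for epoch in range(config.max_epochs):
        opt.zero_grad()
        loss = bce_with_logits(
            model._logits(X[tr], dropout_rng=drop_rng if config.dropout > 0 else None),
            y[tr],
        )
        if not np.isfinite(loss.data):
            raise TrainingError(f"training loss diverged at epoch {epoch}")
        loss.backward()
        opt.step()
        val_logit = model.decision_function(X[va])
        val_loss = float(np.mean(np.logaddexp(0.0, val_logit) - y[va] * val_logit))
        history.append((float(loss.data), val_loss))
        if val_loss < best_val - 1e-6:
            best_val = val_loss
            best_state = {k: v.data.copy() for k, v in model.params.items()}
            patience = 0
        else:
            patience += 1
            if patience >= config.early_stop_patience and epoch + 1 >= config.min_epochs:
                break
    if best_state is not None:
        for k, v in model.params.items():
            v.data = best_state[k]
    model.train_history = history
    return model


# ---------------------------------------------------------------------------
# permutation-Shapley importance
# ---------------------------------------------------------------------------


def shap_importance(
    model,
    X_eval: np.ndarray,
    feature_ids: Sequence[str] | None = None,
    n_permutations: int = 128,
    background: np.ndarray | None = None,
    seed: int = 0,
) -> ShapScores:
    """Monte-Carlo permutation-Shapley attribution of the model logit.

    For each evaluation sample, features are revealed one at a time in
    ``n_permutations`` random orders starting from the background
    vector; a feature's attribution is its average marginal change in
    the model's decision function.  Works for any model exposing
    ``decision_function``; the package's attention classifier uses a
    cached incremental forward pass.
    """
    X_eval = np.asarray(X_eval, dtype=float)
    n, p = X_eval.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    feature_ids = list(feature_ids)
    if len(feature_ids) != p:
        raise ValueError("feature_ids length does not match X_eval columns")
    if background is None:
        background = getattr(model, "background", None)
        if background is None:
            raise ValueError("no background supplied and model has none")
    background = np.asarray(background, dtype=float)
    if background.shape[0] != p:
        raise ValueError(
            f"background has {background.shape[0]} features, X_eval has {p}"
        )
    if isinstance(model, CrossAttentionClassifier) and model.p != p:
        raise ValueError("model feature set does not match X_eval")

    rng = np.random.default_rng(seed)
    phi = np.zeros((n, p))
    fast = isinstance(model, CrossAttentionClassifier)
    if fast:
        cache = _KvCache(model, np.tile(background, (n, 1)))
        base_snap = cache.snapshot()
        base_value = cache.logits()
        for _ in range(n_permutations):
            order = rng.permutation(p)
            cache.restore(base_snap)
            f_prev = base_value
            for j in order:
                cache.update_column(j, X_eval[:, j])
                f_new = cache.logits()
                phi[:, j] += f_new - f_prev
                f_prev = f_new
    else:
        Z0 = np.tile(background, (n, 1))
        base_value = np.asarray(model.decision_function(Z0), dtype=float)
        for _ in range(n_permutations):
            order = rng.permutation(p)
            Z = Z0.copy()
            f_prev = base_value
            for j in order:
                Z[:, j] = X_eval[:, j]
                f_new = np.asarray(model.decision_function(Z), dtype=float)
                phi[:, j] += f_new - f_prev
                f_prev = f_new
    phi /= n_permutations
    return ShapScores(
        feature_ids=feature_ids,
        scores=np.abs(phi).mean(axis=0),
        attributions=phi,
        base_value=base_value,
        n_permutations=n_permutations,
        background=background,
    )


# ---------------------------------------------------------------------------
# recursive feature elimination
# ---------------------------------------------------------------------------


def transformer_rfe_rank(
    X: np.ndarray,
    y: np.ndarray,
    n_select: int,
    config: TransformerConfig | None = None,
    feature_ids: Sequence[str] | None = None,
    layer_index: np.ndarray | None = None,
    estimator_factory: Callable | None = None,
) -> tuple[FeatureRanking, RfeTrace]:
    """Recursive elimination with the attention classifier and Shapley scores.

    Each iteration trains a fresh model (seed derived from the master
    seed and the iteration index), scores surviving features by
    permutation-Shapley importance, and removes the single
    lowest-scoring feature (ties broken lexicographically by id) until
    ``n_select`` remain.  The final ranking lists survivors by their
    final-model scores, then the eliminated features in reverse
    elimination order; eliminated features keep the score frozen at
    elimination time in ``raw_scores``.

    ``estimator_factory(X_sub, y, seed)`` may replace the transformer
    with any model exposing ``decision_function`` and ``background``
    (used by the linear-stub cross-checks).
    """
    config = config or TransformerConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    p = X.shape[1]
    if not (1 <= n_select <= p):
        raise ValueError(f"n_select must be in [1, {p}]")
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(p)]
    feature_ids = list(feature_ids)
    if layer_index is None:
        layer_index = np.zeros(p, dtype=int)
    layer_index = np.asarray(layer_index, dtype=int)

    surviving = list(range(p))
    eliminated: list[tuple[str, float]] = []
    trace = RfeTrace()
    it = 0
    while True:
        seed_i = _derive_seed(config.seed, it)
        Xs = X[:, surviving]
        try:
            if estimator_factory is not None:
                mdl = estimator_factory(Xs, y, seed_i)
            else:
                mdl = fit_transformer(
                    Xs, y, replace(config, seed=seed_i), layer_index[surviving]
                )
            n_perm = (
                config.rfe_n_permutations if len(surviving) > n_select else
                config.n_permutations
            )
            sc = shap_importance(
                mdl,
                Xs,
                feature_ids=[feature_ids[j] for j in surviving],
                n_permutations=n_perm,
                seed=_derive_seed(config.seed, 10**7 + it),
            )
        except TrainingError as err:
            raise TrainingError(
                f"iteration {it} ({len(surviving)} features): {err}"
            ) from err
        if len(surviving) == n_select:
            final_scores = dict(zip(sc.feature_ids, sc.scores))
            break
        # eliminate the single lowest-scoring feature; ties lexicographic
        order = sorted(range(len(surviving)), key=lambda i: (sc.scores[i], sc.feature_ids[i]))
        drop_local = order[0]
        fid = sc.feature_ids[drop_local]
        trace.iterations.append(
            RfeIteration(
                surviving=[feature_ids[j] for j in surviving],
                eliminated=fid,
                score=float(sc.scores[drop_local]),
                diagnostics={"iteration_seed": seed_i},
            )
        )
        eliminated.append((fid, float(sc.scores[drop_local])))
        surviving.pop(drop_local)
        it += 1

    survivors_sorted = sorted(
        final_scores, key=lambda f: (-final_scores[f], f)
    )
    ordered = survivors_sorted + [fid for fid, _ in reversed(eliminated)]
    raw = dict(final_scores)
    raw.update({fid: s for fid, s in eliminated})
    ranking = FeatureRanking(
        method="transformer-rfe",
        ordered_features=ordered,
        scores=np.arange(len(ordered), 0, -1, dtype=float),
        selected=survivors_sorted,
        raw_scores=raw,
    )
    return ranking, trace
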