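"""Graph-convolution fusion classifier over sample-similarity networks.

A compact multi-view classifier for multi-omics tables: each omics
layer yields a sample-similarity network (SSN) from cosine similarity
with k-nearest-neighbor sparsification; a per-view graph convolutional
network (GCN) over the normalized SSN produces view-specific class
probabilities; and a view-correlation fusion head — a dense network on
the flattened outer product of the per-view probability vectors (the
label-space cross-view correlation tensor) — produces the final class
probabilities.  Training is transductive: every sample sits in the
graph, but the loss (sum of per-view cross-entropies plus the fusion
cross-entropy) is evaluated on the training mask only.

Post-hoc feature importance is single-feature ablation: the increase
in training-mask fusion loss when a feature column is replaced by its
training mean (rebuilding that layer's SSN), clamped at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .autodiff import Adam, Tensor, cross_entropy, softmax
from .errors import PanelomicsError, TrainingError
from .tables import FeatureRanking


@dataclass
class GraphFusionConfig:
    knn_k: int = 10
    gcn_hidden: int = 32
    gcn_layers: int = 2
    vcdn_hidden: int = 16
    max_epochs: int = 300
    learning_rate: float = 1e-2
    seed: int = 0


@dataclass
class SampleSimilarityNetwork:
    """Symmetric kNN-sparsified cosine-similarity graph over samples."""

    adjacency: np.ndarray  # includes self-loops
    knn_k: int

    def normalized(self) -> np.ndarray:
        """Symmetric degree normalization D^-1/2 A D^-1/2."""
        deg = self.adjacency.sum(axis=1)
        d_inv = 1.0 / np.sqrt(deg)
        return self.adjacency * d_inv[:, None] * d_inv[None, :]

    def edge_list(self):
        import pandas as pd

        i, j = np.nonzero(np.triu(self.adjacency, k=1))
        return pd.DataFrame(
            {"sample_i": i, "sample_j": j, "weight": self.adjacency[i, j]}
        )


def build_ssn(X_layer: np.ndarray, knn_k: int, sample_ids: Sequence[str] | None = None) -> SampleSimilarityNetwork:
    """Cosine-similarity kNN graph over sample profiles.

    Each sample keeps its ``knn_k`` most similar neighbors; the graph
    is symmetrized by elementwise max and self-loops of weight 1 are
    added.  Cosine similarity makes the graph invariant to a uniform
    rescaling of all feature values.
    """
    X = np.asarray(X_layer, dtype=float)
    n = X.shape[0]
    if n <= knn_k:
        raise ValueError(f"need n_samples > knn_k, got {n} <= {knn_k}")
    norms = np.linalg.norm(X, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        name = sample_ids[zero[0]] if sample_ids is not None else f"index {zero[0]}"
        raise PanelomicsError(f"zero-norm sample profile: {name}")
    sim = (X / norms[:, None]) @ (X / norms[:, None]).T
    np.fill_diagonal(sim, -np.inf)
    adj = np.zeros((n, n))
    for i in range(n):
        nbr = np.argpartition(-sim[i], knn_k)[:knn_k]
        adj[i, nbr] = np.maximum(sim[i, nbr], 0.0)
    adj = np.maximum(adj, adj.T)  # symmetrize by max
    adj += np.eye(n)
    return SampleSimilarityNetwork(adjacency=adj, knn_k=knn_k)


class GraphFusionModel:
    """Trained per-view GCNs plus the cross-view fusion head."""

    def __init__(self, layer_names, params, config, ssns, X_by_layer, train_mask, train_means):
        self.layer_names = layer_names
        self.params = params
        self.config = config
        self.ssns = ssns
        self.X_by_layer = X_by_layer
        self.train_mask = train_mask
        self.train_means = train_means

    # forward over arbitrary inputs/graphs (numpy constants, Tensor params)
    def _forward(self, X_by_layer: Mapping[str, np.ndarray], ssns) -> tuple[Tensor, list[Tensor]]:
        P = self.params
        view_probs: list[Tensor] = []
        for v, name in enumerate(self.layer_names):
            A = Tensor(ssns[name].normalized())
            H = Tensor(np.asarray(X_by_layer[name], dtype=float))
            for layer in range(self.config.gcn_layers - 1):
                H = (A @ H @ P[f"W{v}_{layer}"] + P[f"b{v}_{layer}"]).relu()
            logits = A @ H @ P[f"W{v}_out"] + P[f"b{v}_out"]
            view_probs.append(softmax(logits, axis=-1))
        if len(view_probs) == 1:
            cross = view_probs[0]
        else:
            cross = view_probs[0]
            for vp in view_probs[1:]:
                n = cross.shape[0]
                cross = (
                    cross.reshape(n, -1, 1) * vp.reshape(n, 1, -1)
                ).reshape(n, -1)
        h = (cross @ P["Wf1"] + P["bf1"]).relu()
        fused_logits = h @ P["Wf2"] + P["bf2"]
        return fused_logits, view_probs

    def predict_proba(self, X_by_layer=None, ssns=None) -> np.ndarray:
        X_by_layer = X_by_layer or self.X_by_layer
        ssns = ssns or self.ssns
        logits, _ = self._forward(X_by_layer, ssns)
        z = logits.data - logits.data.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def view_probabilities(self) -> dict[str, np.ndarray]:
        _, view_probs = self._forward(self.X_by_layer, self.ssns)
        return {n: vp.data for n, vp in zip(self.layer_names, view_probs)}

    def train_mask_loss(self, X_by_layer=None, ssns=None, y=None) -> float:
        X_by_layer = X_by_layer or self.X_by_layer
        ssns = ssns or self.ssns
        logits, view_probs = self._forward(X_by_layer, ssns)
        loss = cross_entropy(logits, y, self.train_mask)
        for vp in view_probs:
            loss = loss + cross_entropy((vp + 1e-12).log(), y, self.train_mask)
        return float(loss.data)


def mogonet_lite_fit(
    X_by_layer: Mapping[str, np.ndarray],
    y: np.ndarray,
    train_mask: np.ndarray | None = None,
    config: GraphFusionConfig | None = None,
) -> GraphFusionModel:
    """Train the per-view GCNs and fusion head transductively.

    ``X_by_layer`` maps layer name to its standardized samples x
    features matrix (identical sample order across layers); ``y`` is
    0/1; ``train_mask`` marks the samples whose labels contribute to
    the loss (all samples stay in the graphs).  Seed-deterministic.
    """
    config = config or GraphFusionConfig()
    y = np.asarray(y, dtype=int)
    n = len(y)
    if train_mask is None:
        train_mask = np.ones(n, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    if len(set(y[train_mask])) < 2:
        raise TrainingError("train_mask must cover both classes")
    layer_names = list(X_by_layer)
    if not layer_names:
        raise ValueError("need at least one layer")

    ssns = {name: build_ssn(X_by_layer[name], config.knn_k) for name in layer_names}
    train_means = {
        name: np.asarray(X_by_layer[name], dtype=float)[train_mask].mean(axis=0)
        for name in layer_names
    }

    rng = np.random.default_rng(config.seed)
    n_classes = 2
    params: dict[str, Tensor] = {}

    def par(*shape):
        scale = 1.0 / np.sqrt(shape[0])
        return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

    for v, name in enumerate(layer_names):
        p_v = np.asarray(X_by_layer[name]).shape[1]
        dims = [p_v] + [config.gcn_hidden] * (config.gcn_layers - 1)
        for layer in range(config.gcn_layers - 1):
            params[f"W{v}_{layer}"] = par(dims[layer], dims[layer + 1])
            params[f"b{v}_{layer}"] = Tensor(np.zeros(dims[layer + 1]), requires_grad=True)
        params[f"W{v}_out"] = par(dims[-1], n_classes)
        params[f"b{v}_out"] = Tensor(np.zeros(n_classes), requires_grad=True)
    cross_dim = n_classes ** len(layer_names)
    params["Wf1"] = par(cross_dim, config.vcdn_hidden)
    params["bf1"] = Tensor(np.zeros(config.vcdn_hidden), requires_grad=True)
    params["Wf2"] = par(config.vcdn_hidden, n_classes)
    params["bf2"] = Tensor(np.zeros(n_classes), requires_grad=True)

    model = GraphFusionModel(
        layer_names, params, config, ssns,
        {k: np.asarray(v, dtype=float) for k, v in X_by_layer.items()},
        train_mask, train_means,
    )
    opt = Adam(list(params.values()), lr=config.learning_rate)
    for epoch in range(config.max_epochs):
        opt.zero_grad()
        logits, view_probs = model._forward(model.X_by_layer, ssns)
        loss = cross_entropy(logits, y, train_mask)
        for vp in view_probs:
            loss = loss + cross_entropy((vp + 1e-12).log(), y, train_mask)
        if not np.isfinite(loss.data):
            raise TrainingError(f"fusion training diverged at epoch {epoch}")
        loss.backward()
        opt.step()
    model.y = y
    return model


def mogonet_lite_rank(
    model: GraphFusionModel,
    feature_ids_by_layer: Mapping[str, Sequence[str]] | None = None,
    n_select: int = 5,
    n_repeats: int = 1,
) -> FeatureRanking:
    """Mean-replacement ablation importance over all features.

    Each feature column is replaced (in both the GCN input and that
    layer's SSN) by its training-mask mean; importance is the increase
    in training-mask loss, averaged over ``n_repeats`` and clamped at
    zero.  The ablation is deterministic, so a single repeat suffices
    unless a stochastic forward pass is plugged in.
    """
    if feature_ids_by_layer is None:
        feature_ids_by_layer = {
            name: [f"{name}:{j}" for j in range(model.X_by_layer[name].shape[1])]
            for name in model.layer_names
        }
    base_loss = model.train_mask_loss(y=model.y)
    ids: list[str] = []
    scores: list[float] = []
    for name in model.layer_names:
        X = model.X_by_layer[name]
        fids = list(feature_ids_by_layer[name])
        for j, fid in enumerate(fids):
            vals = []
            for _ in range(n_repeats):
                X_abl = X.copy()
                X_abl[:, j] = model.train_means[name][j]
                layers = dict(model.X_by_layer)
                layers[name] = X_abl
                ssns = dict(model.ssns)
                ssns[name] = build_ssn(X_abl, model.config.knn_k)
                vals.append(model.train_mask_loss(layers, ssns, model.y) - base_loss)
            ids.append(fid)
            scores.append(max(float(np.mean(vals)), 0.0))
    order = sorted(range(len(ids)), key=lambda i: (-scores[i], ids[i]))
    ordered = [ids[i] for i in order]
    return FeatureRanking(
        method="mogonet-lite",
        ordered_features=ordered,
        scores=np.asarray([scores[i] for i in order]),
        selected=ordered[:n_select],
        raw_scores=dict(zip(ids, scores)),
    )
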