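"""The node-scoring estimator and model selection.

:class:`GATScorer` is a scikit-learn style estimator: ``fit`` trains the
attention network on a corpus of labeled small graphs by minimizing the
mean squared error between predicted scores and brute-force dismantling
labels; ``predict`` returns one score p_n in [0, 1] per node of an
arbitrary graph.  Scores are computed once per graph (the attack strategy
is static), so prediction is a single forward pass.

Hyperparameters are validated against the search grid: 1–4 attention
layers with output channels in {5, 10, 20, 30, 40, 50} and concatenated
heads in {1, 5, 10, 15, 20, 30}; a 1–4 layer perceptron regressor with
widths in {20, 30, 40, 50, 100}; dropout 0.3, LeakyReLU negative slope
0.2, learning rate 1e-5, 50 epochs (one graph per optimization step,
Adam).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from sklearn.base import BaseEstimator, clone

from gdismantle.features import DEFAULT_FEATURES, compute_node_features
from gdismantle.nn import Adam, GATNetwork, adjacency_mask
from gdismantle.netgen import TrainingSample

CHANNEL_GRID = (5, 10, 20, 30, 40, 50)
HEAD_GRID = (1, 5, 10, 15, 20, 30)
REGRESSOR_GRID = (20, 30, 40, 50, 100)


@dataclass
class ModelConfig:
    """Hyperparameter bundle; all values must lie in the search grid."""

    conv_channels: tuple = (30, 30, 30)
    attention_heads: tuple = (10, 10, 10)
    regressor_widths: tuple = (40, 40)
    dropout: float = 0.3
    negative_slope: float = 0.2
    learning_rate: float = 1e-5
    epochs: int = 50
    seed: int = 0
    feature_names: tuple = DEFAULT_FEATURES

    def __post_init__(self):
        self.conv_channels = _as_tuple(self.conv_channels)
        self.attention_heads = _as_tuple(self.attention_heads)
        if len(self.attention_heads) == 1 and len(self.conv_channels) > 1:
            self.attention_heads = self.attention_heads * len(self.conv_channels)
        self.regressor_widths = _as_tuple(self.regressor_widths)
        self.feature_names = tuple(self.feature_names)
        self.validate()

    def validate(self):
        if not 1 <= len(self.conv_channels) <= 4:
            raise ValueError("between 1 and 4 attention layers")
        if len(self.attention_heads) != len(self.conv_channels):
            raise ValueError("one head count per attention layer")
        for c in self.conv_channels:
            if c not in CHANNEL_GRID:
                raise ValueError(f"channels {c} outside grid {CHANNEL_GRID}")
        for h in self.attention_heads:
            if h not in HEAD_GRID:
                raise ValueError(f"heads {h} outside grid {HEAD_GRID}")
        if not 1 <= len(self.regressor_widths) + 1 <= 4:
            raise ValueError("regressor must have 1 to 4 layers (incl. output)")
        for w in self.regressor_widths:
            if w not in REGRESSOR_GRID:
                raise ValueError(f"regressor width {w} outside grid {REGRESSOR_GRID}")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout in [0, 1)")


def _as_tuple(x):
    if isinstance(x, (int, np.integer)):
        return (int(x),)
    return tuple(int(v) for v in x)


class GATScorer(BaseEstimator):
    """Attention-network node scorer with a scikit-learn interface.

    Parameters mirror :class:`ModelConfig`; ``conv_channels``,
    ``attention_heads`` and ``regressor_widths`` accept an int (uniform
    across layers of the stated count) or an explicit per-layer tuple.

    After ``fit`` the learned weights live in ``network_.params`` and the
    per-epoch mean training loss in ``loss_history_``.
    """

    def __init__(
        self,
        n_conv_layers=3,
        conv_channels=30,
        attention_heads=10,
        n_regressor_layers=2,
        regressor_widths=40,
        dropout=0.3,
        negative_slope=0.2,
        learning_rate=1e-5,
        epochs=50,
        random_state=0,
        feature_names=DEFAULT_FEATURES,
    ):
        self.n_conv_layers = n_conv_layers
        self.conv_channels = conv_channels
        self.attention_heads = attention_heads
        self.n_regressor_layers = n_regressor_layers
        self.regressor_widths = regressor_widths
        self.dropout = dropout
        self.negative_slope = negative_slope
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.random_state = random_state
        self.feature_names = feature_names

    # -- config handling ---------------------------------------------------

    def _config(self) -> ModelConfig:
        cc = self.conv_channels
        if isinstance(cc, (int, np.integer)):
            cc = (int(cc),) * int(self.n_conv_layers)
        ah = self.attention_heads
        if isinstance(ah, (int, np.integer)):
            ah = (int(ah),) * len(cc)
        rw = self.regressor_widths
        if isinstance(rw, (int, np.integer)):
            # n_regressor_layers counts the sigmoid output layer too
            rw = (int(rw),) * max(int(self.n_regressor_layers) - 1, 0)
        return ModelConfig(
            conv_channels=cc,
            attention_heads=ah,
            regressor_widths=rw,
            dropout=self.dropout,
            negative_slope=self.negative_slope,
            learning_rate=self.learning_rate,
            epochs=self.epochs,
            seed=self.random_state,
            feature_names=self.feature_names,
        )

    def initialize(self) -> "GATScorer":
        """Build and randomly initialize the network without training.

        Useful for inspecting the untrained map (its outputs are already
        valid scores in [0, 1]); ``fit`` calls this internally.
        """
        cfg = self._config()
        self.config_ = cfg
        self.feature_names_ = cfg.feature_names
        self.n_features_in_ = len(cfg.feature_names)
        self._rng = np.random.default_rng(cfg.seed)
        self.network_ = GATNetwork(
            self.n_features_in_,
            cfg.conv_channels,
            cfg.attention_heads,
            cfg.regressor_widths,
            dropout=cfg.dropout,
            negative_slope=cfg.negative_slope,
        ).initialize(self._rng)
        self.loss_history_ = []
        return self

    # -- training ----------------------------------------------------------

    def fit(self, X, y=None):
        """Train on a corpus of labeled graphs.

        X is a list of :class:`TrainingSample`, or a list of graphs with
        ``y`` a parallel list of {node: label} mappings.  One graph per
        Adam step, nodes full-batch; deterministic under ``random_state``.
        """
        samples = _as_samples(X, y)
        if not samples:
            raise ValueError("empty training corpus")
        self.initialize()
        prepared = [self._prepare(s) for s in samples]
        rng = self._rng
        net = self.network_
        opt = Adam(net.params, lr=self.config_.learning_rate)
        order = np.arange(len(prepared))
        for _epoch in range(self.config_.epochs):
            rng.shuffle(order)
            losses = []
            for i in order:
                Xf, mask, labels = prepared[i]
                scores, cache = net.forward(Xf, mask, training=True, rng=rng)
                resid = scores - labels
                losses.append(float(np.mean(resid**2)))
                dscores = 2.0 * resid / resid.size
                grads = net.backward(dscores, cache)
                opt.step(net.params, grads)
            self.loss_history_.append(float(np.mean(losses)))
        return self

    def _prepare(self, sample: TrainingSample):
        g = sample.graph
        nodes = sorted(g.nodes)
        feats = sample.features
        if feats is None or tuple(feats.columns) != self.feature_names_:
            feats = compute_node_features(g, self.feature_names_)
        Xf = feats.loc[nodes].to_numpy(dtype=float)
        mask = adjacency_mask(g, nodes)
        labels = np.array([sample.labels[v] for v in nodes], dtype=float)
        if np.any((labels < 0) | (labels > 1)):
            raise ValueError("labels must lie in [0, 1]")
        return Xf, mask, labels

    # -- prediction ----------------------------------------------------------

    def predict(self, G: nx.Graph, features=None) -> np.ndarray:
        """Scores aligned with ``sorted(G.nodes)``; one forward pass."""
        if not hasattr(self, "network_"):
            raise RuntimeError("model is neither fitted nor initialized")
        nodes = sorted(G.nodes)
        if features is None:
            features = compute_node_features(G, self.feature_names_)
        Xf = features.loc[nodes].to_numpy(dtype=float)
        mask = adjacency_mask(G, nodes)
        scores, _ = self.network_.forward(Xf, mask, training=False)
        return scores

    def predict_scores(self, G: nx.Graph, features=None) -> dict:
        """Per-node scores as a mapping node id -> p_n."""
        nodes = sorted(G.nodes)
        return dict(zip(nodes, self.predict(G, features)))

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: hyperparameters + weights (JSON)."""
        payload = {
            "format": "gdismantle-checkpoint",
            "version": 1,
            "params": self.get_params(),
            "weights": {k: v.tolist() for k, v in self.network_.params.items()},
            "loss_history": list(self.loss_history_),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "GATScorer":
        payload = json.loads(Path(path).read_text())
        if payload.get("format") != "gdismantle-checkpoint":
            raise ValueError(f"{path} is not a model checkpoint")
        params = payload["params"]
        for key in ("conv_channels", "attention_heads", "regressor_widths", "feature_names"):
            if isinstance(params[key], list):
                params[key] = tuple(params[key])
        est = cls(**params)
        est.initialize()
        est.network_.params = {k: np.asarray(v) for k, v in payload["weights"].items()}
        est.loss_history_ = payload.get("loss_history", [])
        return est


def _as_samples(X, y):
    if y is None:
        samples = list(X)
        if samples and not isinstance(samples[0], TrainingSample):
            raise TypeError("without y, X must be a list of TrainingSample")
        return samples
    return [TrainingSample(graph=g, labels=dict(lab)) for g, lab in zip(X, y)]


# ---------------------------------------------------------------------------
# Functional wrappers over the estimator.


def build_model(config: ModelConfig) -> GATScorer:
    """Untrained scorer with randomly initialized weights for ``config``."""
    est = GATScorer(
        n_conv_layers=len(config.conv_channels),
        conv_channels=config.conv_channels,
        attention_heads=config.attention_heads,
        n_regressor_layers=len(config.regressor_widths) + 1,
        regressor_widths=config.regressor_widths,
        dropout=config.dropout,
        negative_slope=config.negative_slope,
        learning_rate=config.learning_rate,
        epochs=config.epochs,
        random_state=config.seed,
        feature_names=config.feature_names,
    )
    return est.initialize()


def train_model(model: GATScorer, corpus: Sequence[TrainingSample]) -> GATScorer:
    """Supervised training against the brute-force labels (MSE)."""
    return model.fit(list(corpus))


def predict_scores(model: GATScorer, g: nx.Graph) -> dict:
    return model.predict_scores(g)


def grid_search_select(
    configs: Sequence[ModelConfig],
    corpus: Sequence[TrainingSample],
    validation_graphs: Sequence[nx.Graph],
    target_fraction: float = 0.10,
) -> GATScorer:
    """Train every config and keep the best dismantler.

    Selection criterion: lowest mean dismantling AUC over the validation
    graphs; ties broken by fewer total removals, then by config order.
    """
    from gdismantle.dismantle import static_attack

    configs = list(configs)
    if not configs:
        raise ValueError("empty config list")
    if not validation_graphs:
        raise ValueError("need at least one validation graph")
    best = None
    for i, cfg in enumerate(configs):
        model = build_model(cfg).fit(list(corpus))
        aucs, removals = [], 0
        for g in validation_graphs:
            trace = static_attack(g, model.predict_scores(g), target_fraction)
            aucs.append(trace.auc)
            removals += len(trace.removal_list)
        key = (float(np.mean(aucs)), removals, i)
        if best is None or key < best[0]:
            best = (key, model)
    return best[1]
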