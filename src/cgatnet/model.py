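"""The cell-graph attention network: embedding, GCN, attention read-out, FFN.

The network classifies a whole point pattern (one tissue sample) from
nothing but cell positions and phenotype labels.  The pipeline is

    labels --embedding--> X_0                          (N x d)
    X_{t+1} = sigma(A_tilde X_t W_t), t = 0..l-1       (graph convolutions)
    alpha = tanh(X_l) w,  p = softmax(alpha),  s = X_l^T p   (attention read-out)
    logits = s U + b,  probabilities = softmax(logits)       (FFN, 2 classes)

The attention read-out collapses the N x d node embedding to a fixed
d-dimensional context vector s regardless of sample size, and its simplex
weights p rank cells by their contribution to the prediction — the basis of
the interpretation workflow.

Everything here is plain NumPy with hand-written reverse-mode gradients and
an Adam optimizer; graphs are processed one per optimization step since N
varies between samples.  All randomness is owned by a seeded Generator, so
training is bit-reproducible.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import scipy.sparse as sp

from .graph import CellGraph, build_knn_adjacency
from .io import DEFAULT_CELL_TYPES, PointPattern

logger = logging.getLogger(__name__)

_ACTIVATIONS = ("relu", "tanh")


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults are the standard operating point for ~10^2–10^3-cell samples:
    embedding dimension d=30, l=2 graph-convolution layers, k=20 nearest
    neighbours (between a barely-connected and a complete graph), ReLU.
    """

    d: int = 30
    layers: int = 2
    k: int = 20
    label_dictionary: tuple[str, ...] = DEFAULT_CELL_TYPES
    gcn_activation: str = "relu"
    seed: int = 0

    def __post_init__(self) -> None:
        self.label_dictionary = tuple(self.label_dictionary)
        if self.gcn_activation not in _ACTIVATIONS:
            raise ValueError(
                f"activation must be one of {_ACTIVATIONS}, got {self.gcn_activation!r}"
            )
        if self.d < 1 or self.layers < 1 or self.k < 1:
            raise ValueError("d, layers and k must all be positive")

    @property
    def vocab(self) -> int:
        return len(self.label_dictionary)


@dataclass
class TrainConfig:
    """Optimization settings: Adam, cross-entropy, one graph per step."""

    learning_rate: float = 1e-3
    epochs: int = 100
    seed: int = 0


@dataclass
class CgatParams:
    """All trainable arrays of one pairwise network."""

    embedding: np.ndarray        # V x d
    gcn_weights: list[np.ndarray]  # l matrices, each d x d
    attention_w: np.ndarray      # d
    ffn_weight: np.ndarray       # d x 2
    ffn_bias: np.ndarray         # 2

    def arrays(self) -> dict[str, np.ndarray]:
        out = {
            "embedding": self.embedding,
            "attention_w": self.attention_w,
            "ffn_weight": self.ffn_weight,
            "ffn_bias": self.ffn_bias,
        }
        for t, w in enumerate(self.gcn_weights):
            out[f"gcn_w{t}"] = w
        return out

    def validate(self, config: ModelConfig) -> None:
        d, v = config.d, config.vocab
        if self.embedding.shape != (v, d):
            raise ValueError(f"embedding shape {self.embedding.shape} != {(v, d)}")
        if len(self.gcn_weights) != config.layers:
            raise ValueError("wrong number of GCN weight matrices")
        for w in self.gcn_weights:
            if w.shape != (d, d):
                raise ValueError(f"GCN weight shape {w.shape} != {(d, d)}")
        if self.attention_w.shape != (d,):
            raise ValueError("attention vector shape mismatch")
        if self.ffn_weight.shape != (d, 2) or self.ffn_bias.shape != (2,):
            raise ValueError("FFN shape mismatch")
        for arr in self.arrays().values():
            if not np.isfinite(arr).all():
                raise ValueError("non-finite parameter")


@dataclass
class AttentionResult:
    """Per-cell attention of one forward pass.

    alpha are raw scores, p their softmax (a probability simplex over cells),
    s = X_l^T p the d-dimensional context vector.
    """

    alpha: np.ndarray
    p: np.ndarray
    s: np.ndarray


@dataclass
class PairwiseModel:
    """A trained two-class network.

    ``class_pair`` is ordered (positive, negative); the forward pass emits
    ``[P(negative), P(positive)]``.
    """

    class_pair: tuple[str, str]
    params: CgatParams
    config: ModelConfig
    epochs_run: int = 0
    final_loss: float = float("nan")
    loss_trace: list[float] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_pair[0] == self.class_pair[1]:
            raise ValueError("class pair must contain two distinct classes")

    def predict_proba(self, pattern: PointPattern) -> np.ndarray:
        probs, _ = forward(pattern, self.params, self.config)
        return probs

    def positive_score(self, pattern: PointPattern) -> float:
        """P(positive class); the pairwise ranking score."""
        return float(self.predict_proba(pattern)[1])

    def predict(self, pattern: PointPattern) -> str:
        """Winning class at the 0.5 threshold (argmax of the softmax)."""
        probs = self.predict_proba(pattern)
        return self.class_pair[0] if probs[1] >= probs[0] else self.class_pair[1]


def init_params(config: ModelConfig, rng: np.random.Generator, scale: float = 0.1) -> CgatParams:
    """Small random-normal initialization of every trainable array."""
    d, v = config.d, config.vocab
    return CgatParams(
        embedding=rng.normal(0.0, scale, size=(v, d)),
        gcn_weights=[rng.normal(0.0, scale, size=(d, d)) for _ in range(config.layers)],
        attention_w=rng.normal(0.0, scale, size=d),
        ffn_weight=rng.normal(0.0, scale, size=(d, 2)),
        ffn_bias=np.zeros(2),
    )


def embed_labels(
    labels: Sequence[str] | np.ndarray,
    params: CgatParams,
    label_dictionary: Sequence[str] = DEFAULT_CELL_TYPES,
) -> np.ndarray:
    """Look up each symbolic label's embedding row: the X_0 input features."""
    if isinstance(labels, np.ndarray) and np.issubdtype(labels.dtype, np.integer):
        idx = labels
    else:
        lut = {lab: i for i, lab in enumerate(label_dictionary)}
        try:
            idx = np.array([lut[lab] for lab in labels], dtype=np.int64)
        except KeyError as exc:
            raise KeyError(f"label {exc.args[0]!r} not in dictionary") from None
    if idx.size and (idx.min() < 0 or idx.max() >= params.embedding.shape[0]):
        raise IndexError("label index outside embedding table")
    return params.embedding[idx]


def _activate(z: np.ndarray, activation: str) -> np.ndarray:
    if activation == "relu":
        return np.maximum(z, 0.0)
    if activation == "tanh":
        return np.tanh(z)
    raise ValueError(f"unknown activation {activation!r}")


def gcn_layer(
    X: np.ndarray,
    A_tilde: np.ndarray | sp.spmatrix,
    W: np.ndarray,
    activation: str = "relu",
) -> np.ndarray:
    """One graph-convolution update: sigma(A_tilde X W), elementwise sigma."""
    if X.shape[1] != W.shape[0]:
        raise ValueError(f"shape mismatch: X {X.shape} vs W {W.shape}")
    return _activate(A_tilde @ (X @ W), activation)


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max()
    e = np.exp(z)
    return e / e.sum()


def self_attention(X_l: np.ndarray, w: np.ndarray) -> AttentionResult:
    """Attention read-out: alpha = tanh(X_l) w, p = softmax(alpha), s = X_l^T p."""
    if X_l.ndim != 2 or w.shape != (X_l.shape[1],):
        raise ValueError("shape mismatch between node embeddings and attention vector")
    alpha = np.tanh(X_l) @ w
    p = _softmax(alpha)
    s = X_l.T @ p
    return AttentionResult(alpha=alpha, p=p, s=s)


def _forward_graph(
    graph: CellGraph,
    label_idx: np.ndarray,
    params: CgatParams,
    config: ModelConfig,
    keep_cache: bool = False,
):
    """Forward pass on a prebuilt graph; optionally keep intermediates."""
    A_tilde = graph.A_tilde
    X = params.embedding[label_idx]
    xs = [X]
    for W in params.gcn_weights:
        X = gcn_layer(X, A_tilde, W, config.gcn_activation)
        xs.append(X)
    att = self_attention(X, params.attention_w)
    logits = att.s @ params.ffn_weight + params.ffn_bias
    probs = _softmax(logits)
    if keep_cache:
        return probs, att, {"xs": xs, "logits": logits}
    return probs, att


def forward(
    pattern: PointPattern,
    params: CgatParams,
    config: ModelConfig,
    graph: CellGraph | None = None,
) -> tuple[np.ndarray, AttentionResult]:
    """Full pipeline from a point pattern to 2-class probabilities.

    Returns the probability vector ``[P(class 0), P(class 1)]`` and the
    attention result used for interpretation.  A prebuilt ``graph`` may be
    supplied to avoid recomputing the k-NN adjacency.
    """
    if graph is None:
        graph = build_knn_adjacency(pattern, config.k)
    lut = {lab: i for i, lab in enumerate(config.label_dictionary)}
    label_idx = np.array([lut[lab] for lab in pattern.labels], dtype=np.int64)
    return _forward_graph(graph, label_idx, params, config)


def _backward_graph(
    graph: CellGraph,
    label_idx: np.ndarray,
    params: CgatParams,
    config: ModelConfig,
    y: int,
) -> tuple[float, dict[str, np.ndarray]]:
    """Cross-entropy loss and gradients for one graph with target class y."""
    probs, att, cache = _forward_graph(graph, label_idx, params, config, keep_cache=True)
    xs = cache["xs"]
    X_l = xs[-1]
    loss = -float(np.log(max(probs[y], 1e-300)))

    dlogits = probs.copy()
    dlogits[y] -= 1.0
    g_ffn_w = np.outer(att.s, dlogits)
    g_ffn_b = dlogits
    ds = params.ffn_weight @ dlogits

    # s = X_l^T p
    dX = np.outer(att.p, ds)
    dp = X_l @ ds
    # p = softmax(alpha)
    dalpha = att.p * (dp - float(att.p @ dp))
    # alpha = tanh(X_l) w
    T = np.tanh(X_l)
    g_w = T.T @ dalpha
    dX += np.outer(dalpha, params.attention_w) * (1.0 - T * T)

    A_tilde = graph.A_tilde
    g_gcn = [None] * config.layers
    for t in range(config.layers - 1, -1, -1):
        X_in, X_out = xs[t], xs[t + 1]
        if config.gcn_activation == "relu":
            dZ = dX * (X_out > 0.0)
        else:  # tanh
            dZ = dX * (1.0 - X_out * X_out)
        AX = A_tilde @ X_in
        g_gcn[t] = AX.T @ dZ
        dX = (A_tilde @ dZ) @ params.gcn_weights[t].T

    g_emb = np.zeros_like(params.embedding)
    np.add.at(g_emb, label_idx, dX)

    grads = {
        "embedding": g_emb,
        "attention_w": g_w,
        "ffn_weight": g_ffn_w,
        "ffn_bias": g_ffn_b,
    }
    for t in range(config.layers):
        grads[f"gcn_w{t}"] = g_gcn[t]
    return loss, grads


class _Adam:
    """Standard Adam with bias correction, one state slot per array."""

    def __init__(self, arrays: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in arrays.items()}
        self.v = {k: np.zeros_like(v) for k, v in arrays.items()}

    def step(self, arrays: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, a in arrays.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1.0 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1.0 - self.b2) * g * g
            a -= self.lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)


def train_pairwise(
    cohort: Sequence[PointPattern],
    class_pair: tuple[str, str],
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
) -> PairwiseModel:
    """Train one two-class network end to end.

    Samples of ``class_pair[0]`` are the positive class (target 1), of
    ``class_pair[1]`` the negative (target 0); other classes are ignored.
    Graphs are built once and cached across epochs; each epoch is one pass
    over the shuffled training samples, one graph per Adam step.
    """
    model_config = model_config or ModelConfig()
    train_config = train_config or TrainConfig()
    pos, neg = class_pair
    if pos == neg:
        raise ValueError("class pair must be two distinct classes")
    samples = [p for p in cohort if p.disease_class in (pos, neg)]
    n_pos = sum(p.disease_class == pos for p in samples)
    n_neg = len(samples) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"need at least one sample of each class in {class_pair}; "
            f"got {n_pos} / {n_neg}"
        )

    lut = {lab: i for i, lab in enumerate(model_config.label_dictionary)}
    prepared = []
    for p in samples:
        g = build_knn_adjacency(p, model_config.k)
        idx = np.array([lut[lab] for lab in p.labels], dtype=np.int64)
        prepared.append((g, idx, 1 if p.disease_class == pos else 0))

    rng = np.random.default_rng(train_config.seed)
    params = init_params(model_config, rng)
    arrays = params.arrays()
    opt = _Adam(arrays, train_config.learning_rate)
    trace: list[float] = []
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(prepared))
        total = 0.0
        for j in order:
            g, idx, y = prepared[j]
            loss, grads = _backward_graph(g, idx, params, model_config, y)
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}, sample {j}; aborting"
                )
            opt.step(arrays, grads)
            total += loss
        trace.append(total / len(prepared))
    return PairwiseModel(
        class_pair=(pos, neg),
        params=params,
        config=model_config,
        epochs_run=train_config.epochs,
        final_loss=trace[-1] if trace else float("nan"),
        loss_trace=trace,
        seed=train_config.seed,
    )


def attention_percentile_mask(att: AttentionResult, q: float) -> np.ndarray:
    """Indices of cells whose attention weight p reaches the q-th percentile.

    Linear-interpolation percentile convention, inclusive threshold: q=0
    selects every cell; ties at the threshold are all included.
    """
    if not 0.0 <= q <= 100.0:
        raise ValueError(f"percentile must lie in [0, 100], got {q}")
    thr = np.percentile(att.p, q)
    return np.flatnonzero(att.p >= thr)


def attention_table(
    pattern: PointPattern, att: AttentionResult, q: float = 90.0
):
    """Per-cell attention export: index, position, label, alpha, p, selected."""
    import pandas as pd

    sel = np.zeros(pattern.n_cells, dtype=bool)
    sel[attention_percentile_mask(att, q)] = True
    return pd.DataFrame(
        {
            "cell_index": np.arange(pattern.n_cells),
            "x": pattern.coords[:, 0],
            "y": pattern.coords[:, 1],
            "cell_type": list(pattern.labels),
            "alpha": att.alpha,
            "p": att.p,
            "selected": sel,
        }
    )


def save_model(model: PairwiseModel, path: str | Path) -> Path:
    """Checkpoint: one .npz archive of named arrays plus a config manifest."""
    path = Path(path)
    meta = {
        "class_pair": list(model.class_pair),
        "d": model.config.d,
        "layers": model.config.layers,
        "k": model.config.k,
        "label_dictionary": list(model.config.label_dictionary),
        "gcn_activation": model.config.gcn_activation,
        "seed": model.seed,
        "epochs_run": model.epochs_run,
        "final_loss": model.final_loss,
    }
    np.savez(
        path,
        __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        loss_trace=np.asarray(model.loss_trace),
        **model.params.arrays(),
    )
    return path


def load_model(path: str | Path) -> PairwiseModel:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        config = ModelConfig(
            d=meta["d"],
            layers=meta["layers"],
            k=meta["k"],
            label_dictionary=tuple(meta["label_dictionary"]),
            gcn_activation=meta["gcn_activation"],
            seed=meta["seed"],
        )
        params = CgatParams(
            embedding=z["embedding"],
            gcn_weights=[z[f"gcn_w{t}"] for t in range(meta["layers"])],
            attention_w=z["attention_w"],
            ffn_weight=z["ffn_weight"],
            ffn_bias=z["ffn_bias"],
        )
        trace = list(z["loss_trace"])
    params.validate(config)
    return PairwiseModel(
        class_pair=tuple(meta["class_pair"]),
        params=params,
        config=config,
        epochs_run=meta["epochs_run"],
        final_loss=meta["final_loss"],
        loss_trace=trace,
        seed=meta["seed"],
    )
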