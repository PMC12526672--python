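"""FT-Transformer: feature tokenizer + PreNorm transformer encoder for
tabular classification.

Each numerical feature x_j is mapped to a learned token T_j = b_j + x_j·W_j in
R^d; a learned [CLS] token is prepended and L PreNorm encoder layers
(multi-head self-attention then a ReGLU feed-forward block, each with a
residual connection and a leading layer norm — except the attention sublayer
of layer 1, whose leading norm is omitted) process the token matrix. The
prediction head is Linear(ReLU(LayerNorm(·))) applied to the final [CLS] row
and emits two class logits (class 0 = alert, class 1 = fatigue).

The lightweight default configuration: d = 64, L = 3, 8 heads, feed-forward
hidden width 128, dropout 0.2, trained with AdamW at lr 1e-3, batch size 64,
100 epochs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .autodiff import (AdamW, Parameter, Tensor, concat, cross_entropy,
                       dropout, layer_norm)
from .io import FeatureTable

logger = logging.getLogger(__name__)

CLASS_NAMES = ("alert", "fatigue")  # class 0, class 1


@dataclass
class FTTConfig:
    d_embed: int = 64
    n_layers: int = 3
    n_heads: int = 8
    ffn_hidden: int = 128
    dropout: float = 0.2
    activation: str = "reglu"  # "reglu" | "relu"
    lr: float = 1e-3
    batch_size: int = 64
    epochs: int = 100
    weight_decay: float = 0.0
    seed: int = 0
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.d_embed % self.n_heads:
            raise ValueError("d_embed must be divisible by n_heads")
        if min(self.d_embed, self.n_heads, self.ffn_hidden,
               self.batch_size, self.epochs) < 1:
            raise ValueError("config values must be positive")
        if self.n_layers < 0:
            raise ValueError("n_layers must be >= 0")


def _uniform(rng: np.random.Generator, shape: tuple[int, ...], bound: float,
             dtype) -> np.ndarray:
    return rng.uniform(-bound, bound, size=shape).astype(dtype)


class Linear:
    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, dtype):
        bound = 1.0 / math.sqrt(n_in)
        self.W = Parameter(_uniform(rng, (n_in, n_out), bound, dtype))
        self.b = Parameter(_uniform(rng, (n_out,), bound, dtype))

    def __call__(self, x: Tensor) -> Tensor:
        shape = x.shape
        flat = x.reshape(-1, shape[-1]) @ self.W + self.b
        return flat.reshape(*shape[:-1], self.W.shape[1])

    def params(self) -> list[Parameter]:
        return [self.W, self.b]


class FeatureTokenizer:
    """Per-feature affine embeddings plus the learned [CLS] token."""

    def __init__(self, rng: np.random.Generator, n_features: int, d: int, dtype):
        bound = 1.0 / math.sqrt(d)
        self.W = Parameter(_uniform(rng, (n_features, d), bound, dtype))
        self.b = Parameter(_uniform(rng, (n_features, d), bound, dtype))
        self.cls = Parameter(_uniform(rng, (1, 1, d), bound, dtype))
        self.n_features, self.d = n_features, d

    def __call__(self, x: np.ndarray | Tensor) -> Tensor:
        """x (n, k) → token matrix (n, k+1, d) with [CLS] first."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=self.W.data.dtype))
        if x.shape[-1] != self.n_features:
            raise ValueError(
                f"expected {self.n_features} features, got {x.shape[-1]}")
        if not np.isfinite(x.data).all():
            raise ValueError("non-finite feature values")
        n, k = x.shape
        tokens = (x.reshape(n, k, 1) * self.W.reshape(1, k, self.d)
                  + self.b.reshape(1, k, self.d))
        cls = self.cls.broadcast_to((n, 1, self.d))
        return concat([cls, tokens], axis=1)

    def params(self) -> list[Parameter]:
        return [self.W, self.b, self.cls]


class CategoricalTokenizer:
    """Lookup-table embeddings for categorical features.

    Token for category c of feature j: T_j = b_j + E_j[c]. Provided for
    completeness of the tokenizer design; the EEG pipeline's features are all
    numerical, so the pipeline itself never instantiates this path.
    """

    def __init__(self, rng: np.random.Generator, cardinalities: list[int],
                 d: int, dtype):
        bound = 1.0 / math.sqrt(d)
        self.tables = [Parameter(_uniform(rng, (c, d), bound, dtype))
                       for c in cardinalities]
        self.b = Parameter(_uniform(rng, (len(cardinalities), d), bound, dtype))
        self.d = d

    def __call__(self, x: np.ndarray) -> Tensor:
        """x (n, k) integer category codes → token matrix (n, k, d)."""
        x = np.asarray(x)
        if x.shape[1] != len(self.tables):
            raise ValueError(
                f"expected {len(self.tables)} categorical features, "
                f"got {x.shape[1]}")
        cols = [self.tables[j][x[:, j]].reshape(-1, 1, self.d)
                for j in range(x.shape[1])]
        return concat(cols, axis=1) + self.b.reshape(1, -1, self.d)

    def params(self) -> list[Parameter]:
        return self.tables + [self.b]


class MultiHeadSelfAttention:
    def __init__(self, rng, d: int, n_heads: int, p_drop: float, dtype):
        self.q = Linear(rng, d, d, dtype)
        self.k = Linear(rng, d, d, dtype)
        self.v = Linear(rng, d, d, dtype)
        self.out = Linear(rng, d, d, dtype)
        self.n_heads, self.d = n_heads, d
        self.p_drop = p_drop

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        n, t, d = x.shape
        h, dh = self.n_heads, d // self.n_heads

        def split(z: Tensor) -> Tensor:
            return z.reshape(n, t, h, dh).transpose(0, 2, 1, 3)

        # scale folded into q while it is still (n, t, d): cheaper than
        # scaling the (n, h, t, t) score array
        q = split(self.q(x) * (1.0 / math.sqrt(dh)))
        k, v = split(self.k(x)), split(self.v(x))
        scores = q @ k.transpose(0, 1, 3, 2)
        attn = dropout(scores.softmax(axis=-1), self.p_drop, rng, training)
        ctx = (attn @ v).transpose(0, 2, 1, 3).reshape(n, t, d)
        return self.out(ctx)

    def params(self) -> list[Parameter]:
        return (self.q.params() + self.k.params() + self.v.params()
                + self.out.params())


class FeedForward:
    """ReGLU (default) or ReLU feed-forward block."""

    def __init__(self, rng, d: int, hidden: int, activation: str,
                 p_drop: float, dtype):
        self.activation = activation
        width = 2 * hidden if activation == "reglu" else hidden
        self.lin1 = Linear(rng, d, width, dtype)
        self.lin2 = Linear(rng, hidden, d, dtype)
        self.hidden = hidden
        self.p_drop = p_drop

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        z = self.lin1(x)
        if self.activation == "reglu":
            u = z[..., :self.hidden] * z[..., self.hidden:].relu()
        elif self.activation == "relu":
            u = z.relu()
        else:
            raise ValueError(f"unknown activation {self.activation!r}")
        return self.lin2(dropout(u, self.p_drop, rng, training))

    def params(self) -> list[Parameter]:
        return self.lin1.params() + self.lin2.params()


class LayerNormParams:
    def __init__(self, d: int, dtype):
        self.gamma = Parameter(np.ones(d, dtype=dtype))
        self.beta = Parameter(np.zeros(d, dtype=dtype))

    def __call__(self, x: Tensor) -> Tensor:
        return layer_norm(x, self.gamma, self.beta)

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]


class EncoderLayer:
    """PreNorm layer; the very first attention sublayer has no leading norm."""

    def __init__(self, rng, cfg: FTTConfig, first: bool, dtype):
        d = cfg.d_embed
        self.first = first
        self.norm_attn = None if first else LayerNormParams(d, dtype)
        self.attn = MultiHeadSelfAttention(rng, d, cfg.n_heads, cfg.dropout,
                                           dtype)
        self.norm_ffn = LayerNormParams(d, dtype)
        self.ffn = FeedForward(rng, d, cfg.ffn_hidden, cfg.activation,
                               cfg.dropout, dtype)
        self.p_drop = cfg.dropout

    def __call__(self, x: Tensor, rng, training: bool) -> Tensor:
        a_in = x if self.norm_attn is None else self.norm_attn(x)
        x = x + dropout(self.attn(a_in, rng, training), self.p_drop, rng,
                        training)
        x = x + dropout(self.ffn(self.norm_ffn(x), rng, training),
                        self.p_drop, rng, training)
        return x

    def params(self) -> list[Parameter]:
        p = [] if self.norm_attn is None else self.norm_attn.params()
        return p + self.attn.params() + self.norm_ffn.params() + self.ffn.params()


class FTTransformer:
    """The assembled model; ``forward`` maps (n, k) features to (n, 2) logits."""

    def __init__(self, n_features: int, cfg: FTTConfig):
        self.cfg = cfg
        self.n_features = n_features
        dtype = np.dtype(cfg.dtype)
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 0)))
        self.tokenizer = FeatureTokenizer(rng, n_features, cfg.d_embed, dtype)
        self.layers = [EncoderLayer(rng, cfg, first=(i == 0), dtype=dtype)
                       for i in range(cfg.n_layers)]
        self.norm_head = LayerNormParams(cfg.d_embed, dtype)
        self.head = Linear(rng, cfg.d_embed, 2, dtype)

    def params(self) -> list[Parameter]:
        out = self.tokenizer.params()
        for layer in self.layers:
            out += layer.params()
        return out + self.norm_head.params() + self.head.params()

    def forward(self, x: np.ndarray | Tensor,
                rng: np.random.Generator | None = None,
                training: bool = False) -> Tensor:
        tokens = self.tokenizer(x)
        for layer in self.layers:
            tokens = layer(tokens, rng, training)
        cls = tokens[:, 0, :]
        return self.head(self.norm_head(cls).relu())

    __call__ = forward


@dataclass
class FittedModel:
    """Trained classifier with its normalisation statistics and training log."""

    model: FTTransformer
    mean: np.ndarray
    std: np.ndarray
    cfg: FTTConfig
    loss_history: list[float] = field(default_factory=list)
    classes: tuple[str, str] = CLASS_NAMES

    def _normalise(self, X: np.ndarray) -> np.ndarray:
        X = (np.asarray(X, dtype=np.float64) - self.mean) / self.std
        return X.astype(self.cfg.dtype)

    def predict_logits(self, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
        if X.shape[1] != self.model.n_features:
            raise ValueError(
                f"model expects {self.model.n_features} features, got {X.shape[1]}")
        Xn = self._normalise(X)
        out = [self.model.forward(Xn[i:i + batch_size]).data
               for i in range(0, len(Xn), batch_size)]
        return np.concatenate(out, axis=0)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        z = self.predict_logits(X).astype(np.float64)
        z -= z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Hard class labels (0 = alert, 1 = fatigue)."""
        return self.predict_proba(X).argmax(axis=1)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        arrays = {f"param_{i}": p.data for i, p in
                  enumerate(self.model.params())}
        np.savez(path, mean=self.mean, std=self.std,
                 loss_history=np.asarray(self.loss_history),
                 n_features=self.model.n_features,
                 classes=np.array(self.classes),
                 config=np.bytes_(repr(asdict(self.cfg)).encode()), **arrays)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        import ast

        with np.load(path) as z:
            cfg = FTTConfig(**ast.literal_eval(z["config"].item().decode()))
            model = FTTransformer(int(z["n_features"]), cfg)
            for i, p in enumerate(model.params()):
                p.data = z[f"param_{i}"].astype(p.data.dtype)
            return cls(model=model, mean=z["mean"], std=z["std"], cfg=cfg,
                       loss_history=list(z["loss_history"]),
                       classes=tuple(str(c) for c in z["classes"]))


def labels_from_table(table: FeatureTable) -> np.ndarray:
    """Integer class labels per row (0 = alert, 1 = fatigue)."""
    return (table.meta["state"] == "fatigue").to_numpy().astype(np.int64)


def fit(X: np.ndarray | FeatureTable, y: np.ndarray | None = None,
        cfg: FTTConfig | None = None) -> FittedModel:
    """Train on features/labels (or a FeatureTable) with minibatch AdamW.

    Features are z-scored with training statistics (stored on the model);
    per-epoch mean cross-entropy is logged; a non-finite loss aborts.
    """
    if isinstance(X, FeatureTable):
        y = labels_from_table(X)
        X = X.X
    if y is None:
        raise ValueError("labels are required")
    cfg = cfg or FTTConfig()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std = np.where(std > 0, std, 1.0)
    Xn = ((X - mean) / std).astype(cfg.dtype)
    if not np.isfinite(Xn).all():
        raise ValueError("non-finite features after normalisation")

    model = FTTransformer(X.shape[1], cfg)
    opt = AdamW(model.params(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 1)))
    fitted = FittedModel(model=model, mean=mean, std=std, cfg=cfg)
    n = len(Xn)
    for epoch in range(cfg.epochs):
        perm = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = perm[start:start + cfg.batch_size]
            logits = model.forward(Xn[idx], rng=rng, training=True)
            loss = cross_entropy(logits, y[idx])
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss.data}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        fitted.loss_history.append(float(np.mean(losses)))
        logger.debug("epoch %d: loss %.4f", epoch, fitted.loss_history[-1])
    return fitted


def predict(model: FittedModel, table: FeatureTable | np.ndarray,
            ) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample class probabilities and hard labels (deterministic)."""
    X = table.X if isinstance(table, FeatureTable) else table
    proba = model.predict_proba(X)
    return proba, proba.argmax(axis=1)
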