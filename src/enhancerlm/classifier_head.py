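"""CNN → scaled-dot-product-attention → normalization → dropout →
softmax classification head over language-model representations.

The head consumes per-position hidden states from the encoder, extracts
local motif-scale features with a single valid-mode 1-D convolution
bank (default 30 filters of width 3, the grid-search optimum), lets a
single scaled dot-product attention layer reweight positions against
each other, mean-pools over positions, and classifies the pooled vector
through batch normalization, inverted dropout and an affine softmax
layer trained with categorical cross-entropy.

All forward and backward passes are explicit NumPy; the backward pass
is validated against finite differences in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .language_model import LanguageModel, encode
from .sequence_io import DnaSequence


@dataclass
class ConvParams:
    """1-D convolution bank: W has shape (filters, width, in_channels)."""

    W: np.ndarray
    b: np.ndarray

    @property
    def n_filters(self) -> int:
        return self.W.shape[0]

    @property
    def width(self) -> int:
        return self.W.shape[1]


@dataclass
class AttentionParams:
    """Separate affine projections producing Q, K and V from the conv
    features; Q and K share the key dimension d_k used in the √d_k
    scaling."""

    Wq: np.ndarray
    Wk: np.ndarray
    Wv: np.ndarray
    bq: np.ndarray
    bk: np.ndarray
    bv: np.ndarray

    @property
    def d_k(self) -> int:
        return self.Wq.shape[0]


@dataclass
class NormParams:
    """Learnable affine of the normalization layer; ε guards zero variance."""

    gamma: np.ndarray
    beta: np.ndarray
    eps: float = 1e-5


@dataclass
class RunningStats:
    """Exponential moving batch moments used at evaluation time."""

    mean: np.ndarray
    var: np.ndarray
    momentum: float = 0.1


@dataclass(frozen=True)
class HeadConfig:
    """Classifier hyperparameters; the two named constructors carry the
    per-task grid-search optima."""

    n_filters: int = 30
    kernel_size: int = 3
    conv_layers: int = 1
    dropout: float = 1e-2
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    patience: int = 5
    max_epochs: int = 30
    seed: int = 0
    n_classes: int = 2
    pooling: str = "mean"  # or "attention_sum"
    val_fraction: float = 0.1
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")
        if self.conv_layers < 1:
            raise ValueError("at least one convolution layer is required")
        if self.learning_rate <= 0 or self.patience < 1:
            raise ValueError("learning rate must be positive, patience >= 1")

    @classmethod
    def identification(cls, **overrides) -> "HeadConfig":
        """Enhancer vs. non-enhancer optima: dropout 1e-2, lr 1e-3,
        weight decay 1e-4, patience 5."""
        defaults = dict(dropout=1e-2, learning_rate=1e-3, weight_decay=1e-4, patience=5)
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def strength(cls, **overrides) -> "HeadConfig":
        """Strong vs. weak enhancer optima: dropout 1e-1, lr 2e-2,
        weight decay 5e-3, patience 7."""
        defaults = dict(dropout=1e-1, learning_rate=2e-2, weight_decay=5e-3, patience=7)
        defaults.update(overrides)
        return cls(**defaults)


# ---------------------------------------------------------------------------
# Layer primitives
# ---------------------------------------------------------------------------


def conv1d_relu(features: np.ndarray, params: ConvParams) -> np.ndarray:
    """Valid (no padding) 1-D cross-correlation plus offset and ReLU.

    ``features`` is (positions, channels) or (batch, positions,
    channels); the output has positions − width + 1 positions and one
    channel per filter.
    """
    X = np.asarray(features)
    single = X.ndim == 2
    if single:
        X = X[None]
    B, P, C = X.shape
    F, width, Cw = params.W.shape
    if Cw != C:
        raise ValueError(f"filter channels {Cw} != input channels {C}")
    if P < width:
        raise ValueError(f"input has {P} positions, shorter than kernel width {width}")
    P_out = P - width + 1
    out = np.zeros((B, P_out, F), dtype=np.result_type(X, params.W))
    for w in range(width):
        out += X[:, w : w + P_out, :] @ params.W[:, w, :].T
    out += params.b
    np.maximum(out, 0.0, out=out)
    return out[0] if single else out


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    """Numerically stable softmax; invariant to additive shifts."""
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    shifted = z - z.max(axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / e.sum(axis=axis, keepdims=True)


def scaled_dot_attention(
    Q: np.ndarray, K: np.ndarray, V: np.ndarray, return_weights: bool = False
):
    """Weight = softmax(QKᵀ/√d_k) (row-stochastic, square with side =
    number of positions); output = Weight·V."""
    Q, K, V = (np.asarray(a) for a in (Q, K, V))
    d_k = Q.shape[-1]
    if d_k == 0 or K.shape[-1] != d_k:
        raise ValueError("Q and K must share a positive key dimension")
    if Q.shape[-2] != K.shape[-2] or K.shape[-2] != V.shape[-2]:
        raise ValueError("Q, K, V must agree in the number of positions")
    scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(d_k)
    weights = softmax(scores, axis=-1)
    out = weights @ V
    return (out, weights) if return_weights else out


def batch_normalize(
    Z: np.ndarray,
    params: NormParams,
    mode: str = "training",
    running: RunningStats | None = None,
) -> np.ndarray:
    """Standardize per feature by mini-batch moments (training) or by
    running moments (evaluation), then apply the learnable affine γ, β.

    In training mode the running statistics, when supplied, are updated
    in place with momentum.
    """
    Z = np.asarray(Z)
    if mode == "training":
        if Z.shape[0] < 1:
            raise ValueError("training-mode normalization needs a non-empty batch")
        mu = Z.mean(axis=0)
        var = Z.var(axis=0)
        if running is not None:
            running.mean += running.momentum * (mu - running.mean)
            running.var += running.momentum * (var - running.var)
    elif mode == "evaluation":
        if running is None:
            raise ValueError("evaluation-mode normalization needs running statistics")
        mu, var = running.mean, running.var
    else:
        raise ValueError(f"unknown mode {mode!r}")
    z_hat = (Z - mu) / np.sqrt(var + params.eps)
    return params.gamma * z_hat + params.beta


def dropout(
    A: np.ndarray,
    p: float,
    mode: str = "training",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Inverted dropout: keep each activation with probability 1−p and
    scale by 1/(1−p) so the expectation is unchanged; identity at
    evaluation time."""
    if not 0 <= p < 1:
        raise ValueError("dropout probability must be in [0, 1)")
    if mode == "evaluation" or p == 0.0:
        return np.asarray(A)
    if rng is None:
        raise ValueError("training-mode dropout needs an rng")
    keep = rng.random(np.shape(A)) >= p
    return np.asarray(A) * keep / (1.0 - p)


def cross_entropy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Categorical cross-entropy −Σ y log ŷ with a 1e-12 probability
    floor; averages over the batch when given matrices."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    logp = np.log(np.maximum(y_pred, 1e-12))
    per_example = -(y_true * logp).sum(axis=-1)
    return float(per_example.mean())


# ---------------------------------------------------------------------------
# Assembled head
# ---------------------------------------------------------------------------


@dataclass
class ClassifierHead:
    convs: list[ConvParams]
    attn: AttentionParams
    norm: NormParams
    running: RunningStats
    W_out: np.ndarray
    b_out: np.ndarray
    config: HeadConfig = field(default_factory=HeadConfig)

    @property
    def conv(self) -> ConvParams:
        """First convolution bank (the one consuming encoder features)."""
        return self.convs[0]

    @property
    def receptive_span(self) -> int:
        """Positions consumed by the conv stack: Σ(width−1) + 1."""
        return sum(c.width - 1 for c in self.convs) + 1

    def parameters(self) -> dict[str, np.ndarray]:
        out = {
            "attn.Wq": self.attn.Wq, "attn.Wk": self.attn.Wk, "attn.Wv": self.attn.Wv,
            "attn.bq": self.attn.bq, "attn.bk": self.attn.bk, "attn.bv": self.attn.bv,
            "norm.gamma": self.norm.gamma, "norm.beta": self.norm.beta,
            "W_out": self.W_out, "b_out": self.b_out,
        }
        for li, conv in enumerate(self.convs):
            out[f"conv{li}.W"] = conv.W
            out[f"conv{li}.b"] = conv.b
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for key, arr in values.items():
            if key.startswith("conv"):
                prefix, attr = key.split(".")
                setattr(self.convs[int(prefix[4:])], attr, arr.copy())
            elif "." in key:
                obj_name, attr = key.split(".")
                setattr(getattr(self, obj_name), attr, arr.copy())
            else:
                setattr(self, key, arr.copy())

    # -- forward ----------------------------------------------------------

    def _conv_stack(self, X: np.ndarray):
        """Apply the conv banks in sequence; returns the final ReLU output
        and the per-layer (input, pre-activation) caches."""
        caches = []
        out = X
        for conv in self.convs:
            F_, width, _ = conv.W.shape
            P = out.shape[1]
            if P < width:
                raise ValueError(f"{P} positions < kernel width {width}")
            P_out = P - width + 1
            pre = np.zeros((out.shape[0], P_out, F_), dtype=out.dtype)
            for w in range(width):
                pre += out[:, w : w + P_out, :] @ conv.W[:, w, :].T
            pre += conv.b
            caches.append((out, pre))
            out = np.maximum(pre, 0.0)
        return out, caches

    def forward(
        self,
        features: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ):
        """Full head forward over (batch, positions, channels) encoder
        features; returns (class probabilities, cache for backward)."""
        X = np.asarray(features)
        if X.ndim != 3:
            raise ValueError("expected (batch, positions, channels) features")
        Fc, conv_caches = self._conv_stack(X)

        Q = Fc @ self.attn.Wq.T + self.attn.bq
        K = Fc @ self.attn.Wk.T + self.attn.bk
        V = Fc @ self.attn.Wv.T + self.attn.bv
        d_k = self.attn.d_k
        scores = Q @ np.swapaxes(K, -1, -2) / math.sqrt(d_k)
        scores -= scores.max(axis=-1, keepdims=True)
        A = np.exp(scores)
        A /= A.sum(axis=-1, keepdims=True)
        Y = A @ V  # (B, P_out, F)

        if self.config.pooling == "attention_sum":
            pooled = Y.sum(axis=1)
        else:
            pooled = Y.mean(axis=1)

        if training:
            mu = pooled.mean(axis=0)
            var = pooled.var(axis=0)
            self.running.mean += self.running.momentum * (mu - self.running.mean)
            self.running.var += self.running.momentum * (var - self.running.var)
        else:
            mu, var = self.running.mean, self.running.var
        inv_std = 1.0 / np.sqrt(var + self.norm.eps)
        z_hat = (pooled - mu) * inv_std
        z_scaled = self.norm.gamma * z_hat + self.norm.beta

        p_drop = self.config.dropout if training else 0.0
        if p_drop > 0:
            if rng is None:
                raise ValueError("training-mode forward needs an rng")
            keep = (rng.random(z_scaled.shape) >= p_drop) / (1.0 - p_drop)
        else:
            keep = np.ones_like(z_scaled)
        dropped = z_scaled * keep

        logits = dropped @ self.W_out.T + self.b_out
        shifted = logits - logits.max(axis=1, keepdims=True)
        expz = np.exp(shifted)
        probs = expz / expz.sum(axis=1, keepdims=True)
        cache = (X, conv_caches, Fc, Q, K, V, A, Y, pooled, mu, var, inv_std, z_hat,
                 keep, dropped, probs, training)
        return probs, cache

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        probs, _ = self.forward(features, training=False)
        return probs

    def calibrate_running_stats(self, features: np.ndarray) -> None:
        """Set the normalization layer's running moments to the pooled
        pre-normalization statistics of a reference set (typically the
        training data), replacing the exponential moving average."""
        X = np.asarray(features)
        Fc, _ = self._conv_stack(X)
        Q = Fc @ self.attn.Wq.T + self.attn.bq
        K = Fc @ self.attn.Wk.T + self.attn.bk
        V = Fc @ self.attn.Wv.T + self.attn.bv
        Y = scaled_dot_attention(Q, K, V)
        pooled = Y.sum(axis=1) if self.config.pooling == "attention_sum" else Y.mean(axis=1)
        self.running.mean = pooled.mean(axis=0)
        self.running.var = pooled.var(axis=0)

    # -- backward ---------------------------------------------------------

    def loss_and_grads(
        self,
        features: np.ndarray,
        y_onehot: np.ndarray,
        rng: np.random.Generator | None = None,
        training: bool = True,
    ):
        """Cross-entropy loss and analytic gradients for one batch."""
        probs, cache = self.forward(features, training=training, rng=rng)
        (X, conv_caches, Fc, Q, K, V, A, Y, pooled, mu, var, inv_std, z_hat,
         keep, dropped, _, _) = cache
        B = X.shape[0]
        loss = cross_entropy(y_onehot, probs)

        dlogits = (probs - y_onehot) / B
        grads: dict[str, np.ndarray] = {}
        grads["W_out"] = dlogits.T @ dropped
        grads["b_out"] = dlogits.sum(axis=0)
        ddropped = dlogits @ self.W_out
        dz_scaled = ddropped * keep
        grads["norm.gamma"] = (dz_scaled * z_hat).sum(axis=0)
        grads["norm.beta"] = dz_scaled.sum(axis=0)
        dz_hat = dz_scaled * self.norm.gamma
        if training:
            # batch-moment normalization backward
            dpooled = (
                inv_std / B
            ) * (B * dz_hat - dz_hat.sum(axis=0) - z_hat * (dz_hat * z_hat).sum(axis=0))
        else:
            dpooled = dz_hat * inv_std

        P_out = Y.shape[1]
        if self.config.pooling == "attention_sum":
            dY = np.repeat(dpooled[:, None, :], P_out, axis=1)
        else:
            dY = np.repeat(dpooled[:, None, :] / P_out, P_out, axis=1)

        dA = dY @ np.swapaxes(V, -1, -2)
        dV = np.swapaxes(A, -1, -2) @ dY
        # softmax (row-wise) backward
        dS = A * (dA - (dA * A).sum(axis=-1, keepdims=True))
        scale = 1.0 / math.sqrt(self.attn.d_k)
        dQ = dS @ K * scale
        dK = np.swapaxes(dS, -1, -2) @ Q * scale

        flatFc = Fc.reshape(-1, Fc.shape[-1])
        grads["attn.Wq"] = dQ.reshape(-1, dQ.shape[-1]).T @ flatFc
        grads["attn.Wk"] = dK.reshape(-1, dK.shape[-1]).T @ flatFc
        grads["attn.Wv"] = dV.reshape(-1, dV.shape[-1]).T @ flatFc
        grads["attn.bq"] = dQ.sum(axis=(0, 1))
        grads["attn.bk"] = dK.sum(axis=(0, 1))
        grads["attn.bv"] = dV.sum(axis=(0, 1))
        dFc = dQ @ self.attn.Wq + dK @ self.attn.Wk + dV @ self.attn.Wv

        dout = dFc
        for li in range(len(self.convs) - 1, -1, -1):
            inp, pre = conv_caches[li]
            conv = self.convs[li]
            width = conv.width
            P_l = pre.shape[1]
            dpre = dout * (pre > 0)
            dWc = np.zeros_like(conv.W)
            dinp = np.zeros_like(inp)
            for w in range(width):
                dWc[:, w, :] = np.einsum("bpf,bpc->fc", dpre, inp[:, w : w + P_l, :])
                dinp[:, w : w + P_l, :] += dpre @ conv.W[:, w, :]
            grads[f"conv{li}.W"] = dWc
            grads[f"conv{li}.b"] = dpre.sum(axis=(0, 1))
            dout = dinp
        return loss, grads, probs


def init_head(input_channels: int, config: HeadConfig) -> ClassifierHead:
    """Randomly initialised head for encoder features with the given
    channel width.  Q/K/V project the conv features to d_k = n_filters."""
    rng = np.random.default_rng(config.seed)
    dtype = config.dtype
    F_, width = config.n_filters, config.kernel_size

    def w(shape, fan_in):
        return (rng.standard_normal(shape) / math.sqrt(fan_in)).astype(dtype)

    convs = []
    in_ch = input_channels
    for _ in range(config.conv_layers):
        convs.append(
            ConvParams(W=w((F_, width, in_ch), width * in_ch), b=np.zeros(F_, dtype=dtype))
        )
        in_ch = F_
    attn = AttentionParams(
        Wq=w((F_, F_), F_), Wk=w((F_, F_), F_), Wv=w((F_, F_), F_),
        bq=np.zeros(F_, dtype=dtype), bk=np.zeros(F_, dtype=dtype), bv=np.zeros(F_, dtype=dtype),
    )
    norm = NormParams(gamma=np.ones(F_, dtype=dtype), beta=np.zeros(F_, dtype=dtype))
    running = RunningStats(mean=np.zeros(F_, dtype=dtype), var=np.ones(F_, dtype=dtype))
    W_out = w((config.n_classes, F_), F_)
    b_out = np.zeros(config.n_classes, dtype=dtype)
    return ClassifierHead(convs, attn, norm, running, W_out, b_out, config)


def save_head(head: ClassifierHead, path) -> "Path":
    """Checkpoint head parameters, running stats and config (.npz)."""
    from pathlib import Path
    import json

    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    np.savez(
        path,
        __config=np.array(json.dumps(vars(head.config))),
        __running_mean=head.running.mean,
        __running_var=head.running.var,
        **head.parameters(),
    )
    return path


def load_head(path) -> ClassifierHead:
    import json

    with np.load(path, allow_pickle=True) as data:
        cfg = HeadConfig(**json.loads(str(data["__config"])))
        head = init_head(data["conv0.W"].shape[2], cfg)
        head.set_parameters({k: data[k] for k in head.parameters()})
        head.running.mean = data["__running_mean"].copy()
        head.running.var = data["__running_var"].copy()
    return head


def classify(
    sequences: list[DnaSequence],
    lm: LanguageModel,
    head: ClassifierHead,
    mode: str = "evaluation",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Per-sequence class probabilities: encode with the language model,
    then run the head.  Evaluation mode is deterministic."""
    min_len = lm.vocab.k + head.receptive_span - 1
    for seq in sequences:
        if len(seq) < min_len:
            raise ValueError(
                f"sequence {seq.id!r} of length {len(seq)} is shorter than "
                f"k + kernel span - 1 = {min_len}"
            )
    features = encode(sequences, lm)
    probs, _ = head.forward(features, training=(mode == "training"), rng=rng)
    return probs
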