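"""Self-supervised next-k-mer language model (NumPy implementation).

The model follows the ULMFiT recipe adapted to DNA: a stochastic
embedding layer (whole-vector and per-component embedding dropout), a
stack of three weight-dropped LSTM layers (DropConnect on the input and
recurrent gate matrices, one mask per batch), and an affine decoder
producing next-k-mer logits.  Training minimises categorical
cross-entropy with Adam and early stopping on a held-out split.

Everything — forward, backward-through-time, the optimiser — is
implemented directly on NumPy arrays.  Training uses float32 for speed
and memory; the public cell/step functions operate in the dtype of
their inputs, so float64 oracle comparisons remain exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .kmer_tokenizer import (
    KmerVocabulary,
    TokenStream,
    build_vocabulary,
    numericalize,
)
from .sequence_io import DnaSequence

GATES = ("i", "f", "o", "c")


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite."""


@dataclass(frozen=True)
class EmbeddingDropoutConfig:
    """Stochastic embedding layer: zero whole k-mer vectors with
    probability ``p_embeddings``, then individual components of the
    survivors with probability ``p_embeddings_dim``.  Dropped values are
    replaced by zeros without rescaling; at the default 1e-3 the
    expectation shift is negligible."""

    p_embeddings: float = 1e-3
    p_embeddings_dim: float = 1e-3

    def __post_init__(self) -> None:
        if not (0 <= self.p_embeddings < 1 and 0 <= self.p_embeddings_dim < 1):
            raise ValueError("embedding dropout probabilities must be in [0, 1)")


@dataclass
class LstmLayerParams:
    """One LSTM layer's weights.

    Input weights ``W_*`` have shape (hidden, input); recurrent weights
    ``U_*`` are (hidden, hidden).  The candidate-cell path ``c`` carries
    no bias (the gate equations define biases only for the input, forget
    and output gates); an optional ``b_c`` can be supplied.
    """

    W_i: np.ndarray
    W_f: np.ndarray
    W_o: np.ndarray
    W_c: np.ndarray
    U_i: np.ndarray
    U_f: np.ndarray
    U_o: np.ndarray
    U_c: np.ndarray
    b_u: np.ndarray
    b_f: np.ndarray
    b_o: np.ndarray
    b_c: np.ndarray | None = None

    @property
    def hidden_size(self) -> int:
        return self.W_i.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_i.shape[1]

    def stacked(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(W, U, b) stacked over gates in order i, f, o, c → (4H, ·)."""
        W = np.concatenate([self.W_i, self.W_f, self.W_o, self.W_c], axis=0)
        U = np.concatenate([self.U_i, self.U_f, self.U_o, self.U_c], axis=0)
        b_c = self.b_c if self.b_c is not None else np.zeros_like(self.b_u)
        b = np.concatenate([self.b_u, self.b_f, self.b_o, b_c])
        return W, U, b


@dataclass
class LstmState:
    """Hidden and memory-cell vectors of one LSTM layer."""

    h: np.ndarray
    c: np.ndarray


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_cell_step(x_t: np.ndarray, state: LstmState, params: LstmLayerParams) -> LstmState:
    """One LSTM time step.

    Gates: I_u = sigmoid(W_i x + U_i h + b_u) and analogously for the
    forget and output gates; candidate cin = tanh(W_c x + U_c h); then
    c_t = I_u ⊙ cin + I_f ⊙ c_{t−1} and h_t = I_o ⊙ tanh(c_t).
    Accepts a single vector or a (batch, input) matrix.
    """
    x_t = np.asarray(x_t)
    if x_t.ndim == 1:
        inner = lstm_cell_step(x_t[None, :], LstmState(state.h[None, :], state.c[None, :]), params)
        return LstmState(inner.h[0], inner.c[0])
    if x_t.shape[1] != params.input_size:
        raise ValueError(f"input width {x_t.shape[1]} != layer input size {params.input_size}")
    if state.h.shape[-1] != params.hidden_size:
        raise ValueError("state width does not match layer hidden size")
    i = _sigmoid(x_t @ params.W_i.T + state.h @ params.U_i.T + params.b_u)
    f = _sigmoid(x_t @ params.W_f.T + state.h @ params.U_f.T + params.b_f)
    o = _sigmoid(x_t @ params.W_o.T + state.h @ params.U_o.T + params.b_o)
    cin = x_t @ params.W_c.T + state.h @ params.U_c.T
    if params.b_c is not None:
        cin = cin + params.b_c
    g = np.tanh(cin)
    c = i * g + f * state.c
    h = o * np.tanh(c)
    return LstmState(h, c)


def apply_dropconnect(
    params: LstmLayerParams,
    p: float,
    rng: np.random.Generator | None,
    training: bool = True,
) -> LstmLayerParams:
    """Weight-drop the gate matrices: zero elements of W_i/W_f/W_o and
    U_i/U_f/U_o independently with probability ``p``.

    One mask per call — the caller reuses the returned (masked) params
    for the whole forward+backward pass of a batch.  In evaluation mode
    (or p=0) the params are returned unchanged.
    """
    if not (0 <= p < 1):
        raise ValueError("dropconnect probability must be in [0, 1)")
    if not training or p == 0.0:
        return params
    if rng is None:
        raise ValueError("training-mode dropconnect needs an rng")

    def mask(w: np.ndarray) -> np.ndarray:
        return w * (rng.random(w.shape) >= p)

    return replace(
        params,
        W_i=mask(params.W_i), W_f=mask(params.W_f), W_o=mask(params.W_o),
        U_i=mask(params.U_i), U_f=mask(params.U_f), U_o=mask(params.U_o),
    )


def embed_with_dropout(
    tokens: TokenStream | np.ndarray,
    E: np.ndarray,
    cfg: EmbeddingDropoutConfig,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Look up token embeddings, applying stochastic-embedding dropout in
    training mode.  Evaluation mode is an exact row lookup."""
    ids = tokens.ids if isinstance(tokens, TokenStream) else np.asarray(tokens)
    X = E[ids]
    if not training or (cfg.p_embeddings == 0 and cfg.p_embeddings_dim == 0):
        return X
    if rng is None:
        raise ValueError("training-mode embedding dropout needs an rng")
    keep_row = rng.random(ids.shape) >= cfg.p_embeddings
    keep_dim = rng.random(X.shape) >= cfg.p_embeddings_dim
    return X * keep_row[..., None] * keep_dim


@dataclass(frozen=True)
class LmTrainConfig:
    """Language-model architecture and optimisation settings.

    Defaults are the grid-search optima for this architecture:
    lr 1e-4, weight decay 1e-2, batch 64, embedding dropout 1e-3,
    DropConnect 0.4, patience 50, 400-dim embeddings, three 256-unit
    LSTM layers.
    """

    k: int = 2
    learning_rate: float = 1e-4
    weight_decay: float = 1e-2
    batch_size: int = 64
    embedding_dropout: float = 1e-3
    dropconnect: float = 0.4
    patience: int = 50
    max_epochs: int = 10
    seed: int = 0
    embedding_size: int = 400
    hidden_size: int = 256
    n_layers: int = 3
    val_fraction: float = 0.1
    dtype: str = "float32"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1:
            raise ValueError("learning rate and batch size must be positive")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")


@dataclass
class LanguageModel:
    """Embedding matrix, three weight-dropped LSTM layers and decoder."""

    vocab: KmerVocabulary
    E: np.ndarray
    layers: list[LstmLayerParams]
    W_dec: np.ndarray
    b_dec: np.ndarray
    emb_dropout: EmbeddingDropoutConfig = field(default_factory=EmbeddingDropoutConfig)
    dropconnect: float = 0.4
    history: list[dict] = field(default_factory=list)

    @property
    def hidden_size(self) -> int:
        return self.layers[-1].hidden_size

    def parameters(self) -> dict[str, np.ndarray]:
        out = {"E": self.E, "W_dec": self.W_dec, "b_dec": self.b_dec}
        for li, layer in enumerate(self.layers):
            for name in ("W_i", "W_f", "W_o", "W_c", "U_i", "U_f", "U_o", "U_c", "b_u", "b_f", "b_o"):
                out[f"layer{li}.{name}"] = getattr(layer, name)
            if layer.b_c is not None:
                out[f"layer{li}.b_c"] = layer.b_c
        return out

    def set_parameters(self, values: dict[str, np.ndarray]) -> None:
        for key, arr in values.items():
            if "." in key:
                prefix, name = key.split(".")
                setattr(self.layers[int(prefix[5:])], name, arr.copy())
            else:
                setattr(self, key, arr.copy())


def _init_layer(input_size: int, hidden: int, rng: np.random.Generator, dtype: str,
                cell_bias: bool = False) -> LstmLayerParams:
    s = 1.0 / math.sqrt(hidden)

    def w(shape):
        return rng.uniform(-s, s, size=shape).astype(dtype)

    return LstmLayerParams(
        W_i=w((hidden, input_size)), W_f=w((hidden, input_size)),
        W_o=w((hidden, input_size)), W_c=w((hidden, input_size)),
        U_i=w((hidden, hidden)), U_f=w((hidden, hidden)),
        U_o=w((hidden, hidden)), U_c=w((hidden, hidden)),
        b_u=np.zeros(hidden, dtype=dtype), b_f=np.zeros(hidden, dtype=dtype),
        b_o=np.zeros(hidden, dtype=dtype),
        b_c=np.zeros(hidden, dtype=dtype) if cell_bias else None,
    )


def init_language_model(
    vocab: KmerVocabulary, cfg: LmTrainConfig, cell_bias: bool = False
) -> LanguageModel:
    """Randomly initialised model (also the 'random embeddings' ablation
    arm).  Decoder weights start near zero so that the initial
    next-k-mer cross-entropy is close to ln(vocabulary size)."""
    rng = np.random.default_rng(cfg.seed)
    dtype = cfg.dtype
    E = rng.uniform(-0.1, 0.1, size=(vocab.size, cfg.embedding_size)).astype(dtype)
    layers = []
    in_size = cfg.embedding_size
    for _ in range(cfg.n_layers):
        layers.append(_init_layer(in_size, cfg.hidden_size, rng, dtype, cell_bias))
        in_size = cfg.hidden_size
    W_dec = (0.01 * rng.standard_normal((vocab.size, cfg.hidden_size))).astype(dtype)
    b_dec = np.zeros(vocab.size, dtype=dtype)
    return LanguageModel(
        vocab=vocab, E=E, layers=layers, W_dec=W_dec, b_dec=b_dec,
        emb_dropout=EmbeddingDropoutConfig(cfg.embedding_dropout, cfg.embedding_dropout),
        dropconnect=cfg.dropconnect,
    )


# ---------------------------------------------------------------------------
# Vectorised LSTM layer forward/backward (full BPTT, batch-first)
# ---------------------------------------------------------------------------


def _layer_forward(X: np.ndarray, params: LstmLayerParams):
    """Run one layer over a (B, T, I) input; returns (H_out, cache)."""
    B, T, _ = X.shape
    Hd = params.hidden_size
    W, U, b = params.stacked()
    Ax = X @ W.T + b  # (B, T, 4H)
    I = np.empty((B, T, Hd), dtype=X.dtype)
    F = np.empty_like(I)
    O = np.empty_like(I)
    G = np.empty_like(I)
    C = np.empty_like(I)
    TH = np.empty_like(I)
    Hs = np.empty_like(I)
    h = np.zeros((B, Hd), dtype=X.dtype)
    c = np.zeros((B, Hd), dtype=X.dtype)
    for t in range(T):
        a = Ax[:, t] + h @ U.T
        i = _sigmoid(a[:, :Hd])
        f = _sigmoid(a[:, Hd : 2 * Hd])
        o = _sigmoid(a[:, 2 * Hd : 3 * Hd])
        g = np.tanh(a[:, 3 * Hd :])
        c = i * g + f * c
        th = np.tanh(c)
        h = o * th
        I[:, t], F[:, t], O[:, t], G[:, t] = i, f, o, g
        C[:, t], TH[:, t], Hs[:, t] = c, th, h
    cache = (X, I, F, O, G, C, TH, Hs, W, U)
    return Hs, cache


def _layer_backward(dH_out: np.ndarray, cache) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """BPTT through one layer.

    ``dH_out`` is the loss gradient w.r.t. this layer's hidden outputs.
    Returns (dX, gradients keyed like the stacked weights).
    """
    X, I, F, O, G, C, TH, Hs, W, U = cache
    B, T, Hd = I.shape
    dAx = np.empty((B, T, 4 * Hd), dtype=X.dtype)
    dU = np.zeros_like(U)
    dh_next = np.zeros((B, Hd), dtype=X.dtype)
    dc_next = np.zeros((B, Hd), dtype=X.dtype)
    for t in range(T - 1, -1, -1):
        dh = dH_out[:, t] + dh_next
        i, f, o, g, th = I[:, t], F[:, t], O[:, t], G[:, t], TH[:, t]
        do = dh * th
        dc = dc_next + dh * o * (1.0 - th * th)
        di = dc * g
        dg = dc * i
        c_prev = C[:, t - 1] if t > 0 else np.zeros((B, Hd), dtype=X.dtype)
        df = dc * c_prev
        dc_next = dc * f
        da = np.concatenate(
            [di * i * (1 - i), df * f * (1 - f), do * o * (1 - o), dg * (1 - g * g)],
            axis=1,
        )
        dAx[:, t] = da
        h_prev = Hs[:, t - 1] if t > 0 else np.zeros((B, Hd), dtype=X.dtype)
        dU += da.T @ h_prev
        dh_next = da @ U
    flatA = dAx.reshape(-1, 4 * Hd)
    dW = flatA.T @ X.reshape(-1, X.shape[-1])
    db = flatA.sum(axis=0)
    dX = dAx @ W
    grads = {"W": dW, "U": dU, "b": db}
    return dX, grads


def _split_gate_grads(grads: dict[str, np.ndarray], params: LstmLayerParams, prefix: str,
                      masks: dict[str, np.ndarray] | None) -> dict[str, np.ndarray]:
    """Unstack (4H, ·) gradients into per-gate arrays, applying the
    DropConnect masks (gradient of a masked weight flows only through
    surviving entries)."""
    Hd = params.hidden_size
    out: dict[str, np.ndarray] = {}
    for gi, gate in enumerate(GATES):
        sl = slice(gi * Hd, (gi + 1) * Hd)
        dw = grads["W"][sl]
        du = grads["U"][sl]
        if masks is not None and gate in ("i", "f", "o"):
            dw = dw * masks[f"W_{gate}"]
            du = du * masks[f"U_{gate}"]
        out[f"{prefix}.W_{gate}"] = dw
        out[f"{prefix}.U_{gate}"] = du
    out[f"{prefix}.b_u"] = grads["b"][:Hd]
    out[f"{prefix}.b_f"] = grads["b"][Hd : 2 * Hd]
    out[f"{prefix}.b_o"] = grads["b"][2 * Hd : 3 * Hd]
    if params.b_c is not None:
        out[f"{prefix}.b_c"] = grads["b"][3 * Hd :]
    return out


def _dropconnect_masks(
    params: LstmLayerParams, p: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    masks = {}
    for name in ("W_i", "W_f", "W_o", "U_i", "U_f", "U_o"):
        masks[name] = (rng.random(getattr(params, name).shape) >= p).astype(
            getattr(params, name).dtype
        )
    return masks


def _masked_params(params: LstmLayerParams, masks: dict[str, np.ndarray] | None) -> LstmLayerParams:
    if masks is None:
        return params
    return replace(params, **{name: getattr(params, name) * m for name, m in masks.items()})


def _stack_streams(streams: list[TokenStream], pad_id: int) -> np.ndarray:
    if not streams:
        raise ValueError("empty batch of token streams")
    T = max(len(s) for s in streams)
    ids = np.full((len(streams), T), pad_id, dtype=np.int64)
    for bi, s in enumerate(streams):
        ids[bi, : len(s)] = s.ids
    return ids


def lm_forward(
    streams: list[TokenStream],
    model: LanguageModel,
    training: bool = False,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Next-k-mer logits, shape (batch, positions, vocab); the logits at
    position t score the token at position t+1.  Evaluation mode is
    deterministic (no stochastic layers)."""
    ids = _stack_streams(streams, model.vocab.pad_id)
    logits, _ = _lm_forward_ids(ids, model, training=training, rng=rng)
    return logits


def _lm_forward_ids(
    ids: np.ndarray,
    model: LanguageModel,
    training: bool,
    rng: np.random.Generator | None,
):
    """Forward over an (B, T) id matrix; returns logits and caches for
    backward."""
    dtype = model.E.dtype
    X = model.E[ids].astype(dtype, copy=True)
    emb_mask = None
    if training and rng is None:
        raise ValueError("training-mode forward needs an rng")
    if training and (model.emb_dropout.p_embeddings > 0 or model.emb_dropout.p_embeddings_dim > 0):
        keep_row = rng.random(ids.shape) >= model.emb_dropout.p_embeddings
        keep_dim = rng.random(X.shape) >= model.emb_dropout.p_embeddings_dim
        emb_mask = keep_row[..., None] & keep_dim
        X *= emb_mask
    layer_caches = []
    layer_masks = []
    H = X
    for params in model.layers:
        masks = (
            _dropconnect_masks(params, model.dropconnect, rng)
            if training and model.dropconnect > 0
            else None
        )
        H, cache = _layer_forward(H, _masked_params(params, masks))
        layer_caches.append(cache)
        layer_masks.append(masks)
    logits = H @ model.W_dec.T + model.b_dec
    caches = (ids, emb_mask, layer_caches, layer_masks, H)
    return logits, caches


def _lm_loss_and_grads(
    ids: np.ndarray, model: LanguageModel, rng: np.random.Generator
) -> tuple[float, dict[str, np.ndarray]]:
    """Masked next-token cross-entropy and gradients for one batch.

    Inputs are ids[:, :-1], targets ids[:, 1:]; positions whose target is
    the pad token are excluded from the loss.
    """
    inputs, targets = ids[:, :-1], ids[:, 1:]
    logits, caches = _lm_forward_ids(inputs, model, training=True, rng=rng)
    _, emb_mask, layer_caches, layer_masks, Hfinal = caches
    B, T, V = logits.shape
    flat = logits.reshape(-1, V)
    flat = flat - flat.max(axis=1, keepdims=True)
    P = np.exp(flat)
    P /= P.sum(axis=1, keepdims=True)
    tgt = targets.reshape(-1)
    valid = tgt != model.vocab.pad_id
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("batch contains no valid prediction targets")
    loss = float(-np.log(np.maximum(P[np.arange(len(tgt)), tgt], 1e-12))[valid].mean())
    dlogits = P
    dlogits[np.arange(len(tgt)), tgt] -= 1.0
    dlogits[~valid] = 0.0
    dlogits /= n_valid
    dlogits = dlogits.reshape(B, T, V).astype(model.E.dtype)

    grads: dict[str, np.ndarray] = {}
    grads["W_dec"] = dlogits.reshape(-1, V).T @ Hfinal.reshape(-1, Hfinal.shape[-1])
    grads["b_dec"] = dlogits.sum(axis=(0, 1))
    dH = dlogits @ model.W_dec
    for li in range(len(model.layers) - 1, -1, -1):
        dH, layer_grads = _layer_backward(dH, layer_caches[li])
        grads.update(_split_gate_grads(layer_grads, model.layers[li], f"layer{li}", layer_masks[li]))
    if emb_mask is not None:
        dH = dH * emb_mask
    dE = np.zeros_like(model.E)
    np.add.at(dE, inputs.reshape(-1), dH.reshape(-1, dH.shape[-1]))
    grads["E"] = dE
    return loss, grads


def lm_eval_loss(streams: list[TokenStream], model: LanguageModel, batch_size: int = 64) -> float:
    """Mean next-k-mer cross-entropy in evaluation mode (no dropout)."""
    ids = _stack_streams(streams, model.vocab.pad_id)
    total, count = 0.0, 0
    for start in range(0, len(ids), batch_size):
        chunk = ids[start : start + batch_size]
        inputs, targets = chunk[:, :-1], chunk[:, 1:]
        logits, _ = _lm_forward_ids(inputs, model, training=False, rng=None)
        V = logits.shape[-1]
        flat = logits.reshape(-1, V)
        flat = flat - flat.max(axis=1, keepdims=True)
        logp = flat - np.log(np.exp(flat).sum(axis=1, keepdims=True))
        tgt = targets.reshape(-1)
        valid = tgt != model.vocab.pad_id
        total += float(-logp[np.arange(len(tgt)), tgt][valid].sum())
        count += int(valid.sum())
    return total / max(count, 1)


class Adam:
    """Adam with decoupled weight decay over a named parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float, weight_decay: float = 0.0,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.wd = lr, weight_decay
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for key, g in grads.items():
            p = params[key]
            m = self.m[key]
            v = self.v[key]
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            update = (m / b1c) / (np.sqrt(v / b2c) + self.eps)
            if self.wd and p.ndim > 1:  # no decay on biases
                update = update + self.wd * p
            p -= self.lr * update


def _corpus_streams(corpus: list[DnaSequence], vocab: KmerVocabulary) -> list[TokenStream]:
    return [numericalize(seq, vocab, add_bos=True) for seq in corpus]


def _train_lm(
    model: LanguageModel,
    streams: list[TokenStream],
    cfg: LmTrainConfig,
    phase: str,
) -> LanguageModel:
    rng = np.random.default_rng(cfg.seed)
    n_val = max(1, int(round(cfg.val_fraction * len(streams)))) if len(streams) > 1 else 0
    order = rng.permutation(len(streams))
    val = [streams[i] for i in order[:n_val]]
    train = [streams[i] for i in order[n_val:]] or list(val)
    ids_train = _stack_streams(train, model.vocab.pad_id)

    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    best_loss = lm_eval_loss(val, model) if val else math.inf
    best_params = {k: v.copy() for k, v in params.items()}
    model.history.append(
        {"phase": phase, "epoch": 0, "train_loss": None, "val_loss": best_loss}
    )
    bad_epochs = 0
    for epoch in range(1, cfg.max_epochs + 1):
        perm = rng.permutation(len(ids_train))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(perm), cfg.batch_size):
            batch = ids_train[perm[start : start + cfg.batch_size]]
            loss, grads = _lm_loss_and_grads(batch, model, rng)
            if not math.isfinite(loss):
                raise TrainingDivergedError(
                    f"{phase}: non-finite loss at epoch {epoch} "
                    f"(lr={cfg.learning_rate}); reduce the learning rate"
                )
            opt.step(params, grads)
            epoch_loss += loss
            n_batches += 1
        val_loss = lm_eval_loss(val, model) if val else epoch_loss / max(n_batches, 1)
        model.history.append(
            {
                "phase": phase,
                "epoch": epoch,
                "train_loss": epoch_loss / max(n_batches, 1),
                "val_loss": val_loss,
            }
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = {k: v.copy() for k, v in params.items()}
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= cfg.patience:
                break
    model.set_parameters(best_params)
    return model


def pretrain_lm(
    corpus: list[DnaSequence],
    k: int,
    cfg: LmTrainConfig,
    vocab: KmerVocabulary | None = None,
) -> LanguageModel:
    """Pretrain a next-k-mer language model on an (unlabeled) corpus.

    Builds the vocabulary from the corpus (unless one is supplied),
    initialises the model and optimises masked next-token cross-entropy
    with Adam; early stopping monitors a seeded 10% held-out split and
    the best-validation parameters are restored, so the final held-out
    loss never exceeds the initial one.  The per-epoch loss history is
    kept on ``model.history``.
    """
    if not corpus:
        raise ValueError("empty pretraining corpus")
    if vocab is None:
        vocab = build_vocabulary(corpus, k)
    elif vocab.k != k:
        raise ValueError(f"vocabulary k={vocab.k} does not match requested k={k}")
    model = init_language_model(vocab, cfg)
    return _train_lm(model, _corpus_streams(corpus, vocab), cfg, phase="pretrain")


def fine_tune_lm(
    model: LanguageModel, task_corpus: list[DnaSequence], cfg: LmTrainConfig
) -> LanguageModel:
    """Continue language-model training on the task corpus (ULMFiT-style
    fine-tuning); the vocabulary is frozen, unseen k-mers map to unk.
    ``max_epochs=0`` leaves the model unchanged."""
    if not task_corpus:
        raise ValueError("empty fine-tuning corpus")
    if cfg.embedding_size != model.E.shape[1] or cfg.hidden_size != model.hidden_size:
        raise ValueError("fine-tuning config sizes do not match the model")
    if cfg.max_epochs == 0:
        return model
    return _train_lm(model, _corpus_streams(task_corpus, model.vocab), cfg, phase="finetune")


def encode(
    sequences: list[DnaSequence], model: LanguageModel, batch_size: int = 64
) -> np.ndarray:
    """Final-LSTM-layer hidden state per k-mer position, evaluation mode.

    Returns an array of shape (n sequences, positions, hidden size);
    sequences must share a common length.
    """
    if not sequences:
        raise ValueError("no sequences to encode")
    lengths = {len(s) for s in sequences}
    if len(lengths) != 1:
        raise ValueError(f"encode requires equal-length sequences, got lengths {sorted(lengths)}")
    streams = [numericalize(seq, model.vocab) for seq in sequences]
    ids = _stack_streams(streams, model.vocab.pad_id)
    outs = []
    for start in range(0, len(ids), batch_size):
        chunk = ids[start : start + batch_size]
        X = model.E[chunk]
        H = X
        for params in model.layers:
            H, _ = _layer_forward(H, params)
        outs.append(H)
    return np.concatenate(outs, axis=0)


def save_model(model: LanguageModel, path: str | Path) -> Path:
    """Checkpoint vocabulary, shapes and all parameter tensors (.npz)."""
    path = Path(path)
    if path.suffix != ".npz":
        path = path.with_suffix(path.suffix + ".npz")
    arrays = {k: v for k, v in model.parameters().items()}
    tokens = np.array(model.vocab.id_to_token, dtype=object)
    np.savez(
        path,
        __tokens=tokens,
        __k=np.array(model.vocab.k),
        __dropconnect=np.array(model.dropconnect),
        __emb_dropout=np.array([model.emb_dropout.p_embeddings, model.emb_dropout.p_embeddings_dim]),
        __n_layers=np.array(len(model.layers)),
        **arrays,
    )
    return path


def load_model(path: str | Path) -> LanguageModel:
    with np.load(path, allow_pickle=True) as data:
        tokens = [str(t) for t in data["__tokens"]]
        vocab = KmerVocabulary(k=int(data["__k"]), token_to_id={t: i for i, t in enumerate(tokens)})
        n_layers = int(data["__n_layers"])
        layers = []
        for li in range(n_layers):
            fields_ = {}
            for name in ("W_i", "W_f", "W_o", "W_c", "U_i", "U_f", "U_o", "U_c", "b_u", "b_f", "b_o"):
                fields_[name] = data[f"layer{li}.{name}"]
            key = f"layer{li}.b_c"
            fields_["b_c"] = data[key] if key in data.files else None
            layers.append(LstmLayerParams(**fields_))
        p_emb, p_dim = data["__emb_dropout"]
        return LanguageModel(
            vocab=vocab,
            E=data["E"],
            layers=layers,
            W_dec=data["W_dec"],
            b_dec=data["b_dec"],
            emb_dropout=EmbeddingDropoutConfig(float(p_emb), float(p_dim)),
            dropconnect=float(data["__dropconnect"]),
        )
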