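"""Transformer risk model with a five-interval cumulative-hazard head.

Architecture, per trajectory:

1. token embeddings, rescaled/shifted by the cosine time encoding of each
   event's day-delta to the prediction endpoint (see :mod:`pancrisk.encoder`);
   an age pseudo-token is prepended;
2. ``L`` transformer blocks: multi-head self-attention (each of ``H`` heads
   projects to width ``d``; concatenated heads are mixed by ``W_agg``),
   residual + layer norm, a two-layer position-wise feedforward with ReLU,
   residual + layer norm;
3. a final linear layer and masked mean pooling give the fixed-length
   encoding ``z`` of the patient state at the endpoint;
4. the risk head predicts non-negative hazard increments for the five
   disjoint intervals (0-3, 3-6, 6-12, 12-36, 36-60 months),
   ``lambda_t = ReLU(z' beta_t + b_t)``, and cumulative scores
   ``s_T = z'c + sum_{t<=T} lambda_t`` with an unclamped baseline ``z'c``;
   cumulative probabilities ``p_T = sigmoid(s_T)`` are non-decreasing in T
   by construction.

Training minimizes masked-mean binary cross-entropy over the five interval
labels plus an L2 penalty.  The whole model runs on the package's numpy
autodiff engine; forward passes are deterministic given parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
from scipy.special import expit

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import (
    DEFAULT_FREQ_END,
    DEFAULT_FREQ_START,
    positional_embedding,
    time_multipliers,
)
from .prep import Trajectory

CHECKPOINT_FORMAT_VERSION = 1
#: lower-triangular matrix turning interval hazards into cumulative sums
_CUMSUM = np.tril(np.ones((5, 5)))


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters (defaults are the tuned optimum)."""

    L: int = 1  # transformer layers
    H: int = 16  # attention heads
    d: int = 64  # embedding / head / model width
    freq_start: float = DEFAULT_FREQ_START
    freq_end: float = DEFAULT_FREQ_END
    max_len: int = 300
    age_mode: str = "token"
    dropout: float = 0.0
    censoring: str = "mask"


# ---------------------------------------------------------------------------
# plain-numpy reference operations (inference path / spec-level API)
# ---------------------------------------------------------------------------


def multi_head_attention(X: np.ndarray, heads: list, W_agg: np.ndarray) -> np.ndarray:
    """Reference multi-head self-attention on a single N x d_in sequence.

    ``heads`` is a list of (W_Q, W_K, W_V), each ``d x d_in``.  Per head,
    ``Z = softmax(Q K^T / sqrt(d)) V`` with row-wise softmax over keys (each
    query's weights sum to 1); head outputs are concatenated and projected
    by ``W_agg`` (H*d x d).
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("X must be a non-empty N x d_in matrix")
    zs = []
    for W_Q, W_K, W_V in heads:
        Q, K, V = X @ W_Q.T, X @ W_K.T, X @ W_V.T
        A = Q @ K.T / np.sqrt(W_Q.shape[0])
        A = A - A.max(axis=-1, keepdims=True)
        S = np.exp(A)
        S /= S.sum(axis=-1, keepdims=True)
        zs.append(S @ V)
    return np.concatenate(zs, axis=-1) @ W_agg


def hazards(z: np.ndarray, beta: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Non-negative interval hazards ``ReLU(z beta + b)``."""
    return np.maximum(0.0, np.asarray(z) @ beta + b)


def cumulative_probabilities(z: np.ndarray, beta: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Cumulative probabilities ``sigmoid(z c + cumsum(ReLU(z beta + b)))``.

    The baseline term ``z c`` is not clamped, so probabilities below 0.5
    are reachable; monotonicity across horizons still holds because the
    hazard increments are non-negative.
    """
    lam = hazards(z, beta, b)
    s = np.asarray(z) @ np.asarray(c).reshape(-1, 1) + lam @ _CUMSUM.T
    return expit(s)


def training_loss(p, y, censor_mask=None, params=None, weight_decay: float = 0.0):
    """Masked-mean binary cross-entropy plus an L2 penalty.

    Works on plain arrays (returns a float) or on autodiff tensors (returns
    a scalar ``Tensor`` for backprop).  Probabilities are clamped to
    ``[1e-7, 1 - 1e-7]``; only unmasked (trajectory, interval) cells enter
    the mean.  ``weight_decay`` is the lambda_2 of the penalty
    ``(lambda_2 / 2) * ||theta||^2``.
    """
    y = np.asarray(y, dtype=np.float64)
    mask = np.ones_like(y) if censor_mask is None else np.asarray(censor_mask, dtype=np.float64)
    denom = mask.sum()
    if denom == 0:
        raise ValueError("no unmasked label cells")
    if isinstance(p, Tensor):
        pc = p.clamp(1e-7, 1.0 - 1e-7)
        bce = -(Tensor(y) * pc.log() + Tensor(1.0 - y) * (1.0 - pc).log())
        loss = (bce * mask).sum() / denom
        if params is not None and weight_decay > 0:
            for t in params.values():
                loss = loss + (t * t).sum() * (weight_decay / 2.0)
        return loss
    pc = np.clip(np.asarray(p, dtype=np.float64), 1e-7, 1.0 - 1e-7)
    bce = -(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    loss = float((bce * mask).sum() / denom)
    if params is not None and weight_decay > 0:
        loss += (weight_decay / 2.0) * sum(float((t.value**2).sum()) for t in params.values())
    return loss


# ---------------------------------------------------------------------------
# trainable model
# ---------------------------------------------------------------------------


class TransformerRiskModel:
    """Trainable transformer over (token, time-delta) sequences."""

    def __init__(self, config: ModelConfig, vocab: dict[str, int]):
        self.config = config
        self.vocab = vocab
        self.M = time_multipliers(config.freq_start, config.freq_end, config.d)
        #: parameter rows kept frozen at zero (the padding embedding)
        self.frozen_rows = {"embedding": 0}

    # -- parameters --------------------------------------------------------

    def init_params(self, rng: np.random.Generator) -> dict[str, Tensor]:
        cfg = self.config
        d, H = cfg.d, cfg.H

        def p(shape, scale):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        params = {
            "embedding": p((len(self.vocab), d), 0.2),
            "W_scale": p((d, d), 1.0 / np.sqrt(d)),
            "W_add": p((d, d), 1.0 / np.sqrt(d)),
            "W_out": p((d, d), 1.0 / np.sqrt(d)),
            "b_out": Tensor(np.zeros(d), requires_grad=True),
            "beta": p((d, 5), 1.0 / np.sqrt(d)),
            "b_haz": Tensor(np.zeros(5), requires_grad=True),
            "c": p((d, 1), 1.0 / np.sqrt(d)),
        }
        params["embedding"].value[0] = 0.0  # padding token
        for layer in range(cfg.L):
            params[f"l{layer}.Wq"] = p((H, d, d), 1.0 / np.sqrt(d))
            params[f"l{layer}.Wk"] = p((H, d, d), 1.0 / np.sqrt(d))
            params[f"l{layer}.Wv"] = p((H, d, d), 1.0 / np.sqrt(d))
            params[f"l{layer}.Wagg"] = p((H * d, d), 1.0 / np.sqrt(H * d))
            params[f"l{layer}.ln1_g"] = Tensor(np.ones(d), requires_grad=True)
            params[f"l{layer}.ln1_b"] = Tensor(np.zeros(d), requires_grad=True)
            params[f"l{layer}.W1"] = p((d, d), 1.0 / np.sqrt(d))
            params[f"l{layer}.b1"] = Tensor(np.zeros(d), requires_grad=True)
            params[f"l{layer}.W2"] = p((d, d), 1.0 / np.sqrt(d))
            params[f"l{layer}.b2"] = Tensor(np.zeros(d), requires_grad=True)
            params[f"l{layer}.ln2_g"] = Tensor(np.ones(d), requires_grad=True)
            params[f"l{layer}.ln2_b"] = Tensor(np.zeros(d), requires_grad=True)
        return params

    # -- batching ----------------------------------------------------------

    def prepare_batch(self, trajs: list[Trajectory]) -> dict:
        """Pad a list of trajectories into dense arrays.

        Returns token ids, the precomputed cosine time-encoding P, the age
        encoding rows, the position mask and the label arrays.
        """
        cfg = self.config
        B = len(trajs)
        N = max((min(len(t.tokens), cfg.max_len) for t in trajs), default=0)
        ids = np.zeros((B, N), dtype=np.int64)
        deltas = np.zeros((B, N), dtype=np.float64)
        mask = np.zeros((B, N), dtype=np.float64)
        ages = np.zeros(B)
        labels = np.zeros((B, 5))
        cmask = np.ones((B, 5))
        for i, t in enumerate(trajs):
            toks, dts = t.tokens[-cfg.max_len:], t.deltas[-cfg.max_len:]
            n = len(toks)
            try:
                ids[i, :n] = [self.vocab[tok] for tok in toks]
            except KeyError as exc:
                raise KeyError(f"token not in vocabulary: {exc.args[0]}") from exc
            deltas[i, :n] = dts
            mask[i, :n] = 1.0
            ages[i] = t.age_days
            labels[i] = t.labels
            cmask[i] = t.censor_mask
        P = positional_embedding(deltas, self.M)  # (B, N, d)
        age_rows = np.cos(ages[:, None] * self.M[None, :])  # (B, d)
        return {
            "ids": ids,
            "P": P,
            "age_rows": age_rows,
            "mask": mask,
            "labels": labels,
            "censor_mask": cmask,
        }

    # -- forward -----------------------------------------------------------

    def _encode(self, params, batch, rng=None, train=False,
                event_embeddings: Tensor | None = None) -> Tensor:
        """Encode a prepared batch into latent states z (B x d).

        ``event_embeddings`` optionally replaces the embedding lookup with an
        explicit (B, N, d) tensor — the hook used by integrated gradients.
        """
        cfg = self.config
        mask = batch["mask"]
        B, N = batch["ids"].shape

        if event_embeddings is None:
            X = ad.gather(params["embedding"], batch["ids"])  # (B,N,d)
        else:
            X = event_embeddings
        P = batch["P"]
        X = (Tensor(P) @ params["W_scale"]) * X + Tensor(P) @ params["W_add"]

        age = Tensor(batch["age_rows"].reshape(B, 1, cfg.d))
        if cfg.age_mode == "token":
            X = ad.concat([age, X], axis=1)
            mask = np.concatenate([np.ones((B, 1)), mask], axis=1)
            N += 1
        else:
            X = X + age

        key_mask = mask[:, None, None, :].astype(bool)  # (B,1,1,N)
        pool_mask = mask[:, :, None]  # (B,N,1)
        scale = 1.0 / np.sqrt(cfg.d)
        for layer in range(cfg.L):
            Xh = X.reshape(B, 1, N, cfg.d)
            Q = Xh @ params[f"l{layer}.Wq"].transpose(0, 2, 1)
            K = Xh @ params[f"l{layer}.Wk"].transpose(0, 2, 1)
            V = Xh @ params[f"l{layer}.Wv"].transpose(0, 2, 1)
            A = (Q @ K.transpose(0, 1, 3, 2)) * scale  # (B,H,N,N)
            S = ad.softmax(A, axis=-1, mask=key_mask)
            Z = (S @ V).transpose(0, 2, 1, 3).reshape(B, N, cfg.H * cfg.d)
            Z = Z @ params[f"l{layer}.Wagg"]
            Z = self._dropout(Z, rng, train)
            X = ad.layer_norm(X + Z, params[f"l{layer}.ln1_g"], params[f"l{layer}.ln1_b"])
            F = (X @ params[f"l{layer}.W1"] + params[f"l{layer}.b1"]).relu()
            F = F @ params[f"l{layer}.W2"] + params[f"l{layer}.b2"]
            F = self._dropout(F, rng, train)
            X = ad.layer_norm(X + F, params[f"l{layer}.ln2_g"], params[f"l{layer}.ln2_b"])

        Y = X @ params["W_out"] + params["b_out"]
        z = (Y * pool_mask).sum(axis=1) / pool_mask.sum(axis=1)  # masked mean
        return z

    def _dropout(self, x: Tensor, rng, train: bool) -> Tensor:
        p = self.config.dropout
        if not train or p <= 0.0:
            return x
        keep = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * keep

    def _head(self, params, z: Tensor) -> Tensor:
        lam = (z @ params["beta"] + params["b_haz"]).relu()
        s = z @ params["c"] + lam @ Tensor(_CUMSUM.T)
        return s.sigmoid()

    def forward(self, params, batch, rng=None, train=False,
                event_embeddings: Tensor | None = None) -> Tensor:
        """Cumulative probabilities (B x 5) for a prepared batch."""
        z = self._encode(params, batch, rng, train, event_embeddings)
        return self._head(params, z)

    # -- inference conveniences --------------------------------------------

    def encode(self, params, trajs: list[Trajectory], batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(trajs), batch_size):
            batch = self.prepare_batch(trajs[i : i + batch_size])
            out.append(self._encode(params, batch).value)
        return np.concatenate(out) if out else np.zeros((0, self.config.d))

    def predict(self, params, trajs: list[Trajectory], batch_size: int = 256) -> np.ndarray:
        """Cumulative probabilities for a list of trajectories (no grad)."""
        out = []
        for i in range(0, len(trajs), batch_size):
            batch = self.prepare_batch(trajs[i : i + batch_size])
            out.append(self.forward(params, batch).value)
        return np.concatenate(out) if out else np.zeros((0, 5))


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(path, model, params: dict, extra: dict | None = None) -> None:
    """Serialize parameters + config + vocabulary into one .npz file."""
    meta = {
        "format_version": CHECKPOINT_FORMAT_VERSION,
        "model_class": type(model).__name__,
        "config": asdict(model.config),
        "vocab": model.vocab,
        "extra": extra or {},
    }
    arrays = {f"param::{k}": v.value for k, v in params.items()}
    with open(path, "wb") as fh:  # file object: keep the exact path, no .npz suffix
        np.savez(fh, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Load a checkpoint; returns ``(model, params, extra)``."""
    from . import baselines  # local import to avoid a cycle

    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        if meta["format_version"] != CHECKPOINT_FORMAT_VERSION:
            raise ValueError(f"unsupported checkpoint format {meta['format_version']}")
        values = {k[len("param::"):]: data[k] for k in data.files if k.startswith("param::")}
    cls = {
        "TransformerRiskModel": TransformerRiskModel,
        "MLPBaseline": baselines.MLPBaseline,
        "BagOfEventsModel": baselines.BagOfEventsModel,
    }[meta["model_class"]]
    model = cls(ModelConfig(**meta["config"]), meta["vocab"])
    params = {k: Tensor(v, requires_grad=True) for k, v in values.items()}
    return model, params, meta["extra"]
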