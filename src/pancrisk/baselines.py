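"""Comparison models sharing the cumulative-hazard risk head.

* **Bag-of-events regression** — each trajectory becomes a vector of code
  frequencies normalized by trajectory length (order-free); the vector
  feeds the same ReLU-hazard / cumulative-sigmoid head as the transformer.
* **Token-averaging MLP** — the transformer's time-encoded embeddings, but
  each token passes independently through two fully connected layers of
  width d (no attention); token-mean pooling feeds the shared head.

Both therefore inherit monotone cumulative probabilities, and both train
with the same engine (:func:`pancrisk.training.train`).  Their gap to the
transformer isolates the value of modelling inter-event dependencies.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoder import time_multipliers
from .model import ModelConfig, _CUMSUM
from .prep import Trajectory


def bag_of_events(traj: Trajectory, vocab: dict[str, int]) -> np.ndarray:
    """Length-normalized code-frequency vector over the joint vocabulary."""
    if not traj.tokens:
        raise ValueError("cannot build a bag-of-events vector for an empty trajectory")
    v = np.zeros(len(vocab))
    for tok in traj.tokens:
        if tok not in vocab:
            raise KeyError(f"token not in vocabulary: {tok}")
        v[vocab[tok]] += 1
    return v / len(traj.tokens)


class _SharedHeadModel:
    """Common risk head and prediction plumbing."""

    def _head(self, params, z: Tensor) -> Tensor:
        lam = (z @ params["beta"] + params["b_haz"]).relu()
        s = z @ params["c"] + lam @ Tensor(_CUMSUM.T)
        return s.sigmoid()

    def predict(self, params, trajs, batch_size: int = 256) -> np.ndarray:
        out = []
        for i in range(0, len(trajs), batch_size):
            batch = self.prepare_batch(trajs[i : i + batch_size])
            out.append(self.forward(params, batch).value)
        return np.concatenate(out) if out else np.zeros((0, 5))


class BagOfEventsModel(_SharedHeadModel):
    """Linear risk regression on bag-of-events vectors."""

    def __init__(self, config: ModelConfig, vocab: dict[str, int]):
        self.config = config
        self.vocab = vocab
        self.frozen_rows = {}

    def init_params(self, rng: np.random.Generator) -> dict:
        V = len(self.vocab)
        return {
            "beta": Tensor(rng.normal(0, 0.01, size=(V, 5)), requires_grad=True),
            "b_haz": Tensor(np.zeros(5), requires_grad=True),
            "c": Tensor(rng.normal(0, 0.01, size=(V, 1)), requires_grad=True),
        }

    def prepare_batch(self, trajs) -> dict:
        X = np.stack([bag_of_events(t, self.vocab) for t in trajs])
        return {
            "X": X,
            "labels": np.stack([t.labels for t in trajs]).astype(float),
            "censor_mask": np.stack([t.censor_mask for t in trajs]).astype(float),
        }

    def forward(self, params, batch, rng=None, train=False) -> Tensor:
        return self._head(params, Tensor(batch["X"]))


class MLPBaseline(_SharedHeadModel):
    """Two-layer per-token feedforward with token-mean pooling (no attention)."""

    def __init__(self, config: ModelConfig, vocab: dict[str, int]):
        self.config = config
        self.vocab = vocab
        self.M = time_multipliers(config.freq_start, config.freq_end, config.d)
        self.frozen_rows = {"embedding": 0}

    def init_params(self, rng: np.random.Generator) -> dict:
        d = self.config.d

        def p(shape, scale):
            return Tensor(rng.normal(0.0, scale, size=shape), requires_grad=True)

        params = {
            "embedding": p((len(self.vocab), d), 0.2),
            "W_scale": p((d, d), 1.0 / np.sqrt(d)),
            "W_add": p((d, d), 1.0 / np.sqrt(d)),
            "W1": p((d, d), 1.0 / np.sqrt(d)),
            "b1": Tensor(np.zeros(d), requires_grad=True),
            "W2": p((d, d), 1.0 / np.sqrt(d)),
            "b2": Tensor(np.zeros(d), requires_grad=True),
            "beta": p((d, 5), 1.0 / np.sqrt(d)),
            "b_haz": Tensor(np.zeros(5), requires_grad=True),
            "c": p((d, 1), 1.0 / np.sqrt(d)),
        }
        params["embedding"].value[0] = 0.0
        return params

    def prepare_batch(self, trajs) -> dict:
        # identical input representation to the transformer
        from .model import TransformerRiskModel

        proxy = TransformerRiskModel.__new__(TransformerRiskModel)
        proxy.config, proxy.vocab, proxy.M = self.config, self.vocab, self.M
        return proxy.prepare_batch(trajs)

    def forward(self, params, batch, rng=None, train=False) -> Tensor:
        cfg = self.config
        B, N = batch["ids"].shape
        mask = batch["mask"]
        X = ad.gather(params["embedding"], batch["ids"])
        P = batch["P"]
        X = (Tensor(P) @ params["W_scale"]) * X + Tensor(P) @ params["W_add"]
        age = Tensor(batch["age_rows"].reshape(B, 1, cfg.d))
        if cfg.age_mode == "token":
            X = ad.concat([age, X], axis=1)
            mask = np.concatenate([np.ones((B, 1)), mask], axis=1)
        else:
            X = X + age
        F = (X @ params["W1"] + params["b1"]).relu()
        F = F @ params["W2"] + params["b2"]
        pool = mask[:, :, None]
        z = (F * pool).sum(axis=1) / pool.sum(axis=1)
        return self._head(params, z)
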