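"""Time-aware trajectory encoding.

Clinical event sequences are irregularly spaced, so instead of index-based
positional encodings the model encodes each event's time distance to the
prediction endpoint.  A bank of ``d_in`` frequency multipliers
``M = 2*pi*linspace(freq_start, freq_end, d_in)`` (cycles/day) turns a time
delta into a cosine feature row ``P = cos(dt * M)``, and two learned linear
maps of P rescale and shift the token embeddings::

    X <- (P @ W_scale) * X + (P @ W_add)

Patient age at the endpoint is a strong pancreatic-cancer risk factor and is
injected either as a dedicated prepended pseudo-token carrying
``cos(age_days * M)`` (default) or added onto every event row.

These are the inference-path reference implementations in plain numpy; the
trainable model mirrors them with autodiff tensors and is tested against
this module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: default frequency grid: periods from 100 years down to 30 days
DEFAULT_FREQ_START = 1.0 / 36500.0
DEFAULT_FREQ_END = 1.0 / 30.0


@dataclass(frozen=True)
class EncoderConfig:
    """Hyperparameters of the time encoder.

    d_in
        Embedding width (equals the model width d).
    freq_start, freq_end
        Bounds of the multiplier grid, in cycles per day.
    vocab_size
        Number of distinct event tokens (including the padding token).
    max_len
        Maximum number of events kept per trajectory.
    age_mode
        "token" prepends one age pseudo-token; "add" adds the age encoding
        to every event row.
    """

    d_in: int = 64
    freq_start: float = DEFAULT_FREQ_START
    freq_end: float = DEFAULT_FREQ_END
    vocab_size: int = 0
    max_len: int = 300
    age_mode: str = "token"

    def __post_init__(self):
        if self.d_in < 1:
            raise ValueError("d_in must be >= 1")
        if not (0 < self.freq_start <= self.freq_end):
            raise ValueError("require 0 < freq_start <= freq_end")
        if self.age_mode not in ("token", "add"):
            raise ValueError("age_mode must be 'token' or 'add'")


def time_multipliers(freq_start: float, freq_end: float, d_in: int) -> np.ndarray:
    """Frequency multipliers ``2*pi*linspace(freq_start, freq_end, d_in)``.

    With ``d_in == 1`` the grid degenerates to the start frequency.
    """
    if d_in < 1:
        raise ValueError("d_in must be >= 1")
    if not (0 < freq_start <= freq_end):
        raise ValueError("require 0 < freq_start <= freq_end")
    if d_in == 1:
        return np.array([2.0 * np.pi * freq_start])
    return 2.0 * np.pi * np.linspace(freq_start, freq_end, d_in)


def positional_embedding(delta_days, M: np.ndarray) -> np.ndarray:
    """Cosine time encoding ``P = cos(dt * M)``; rows lie in [-1, 1].

    ``delta_days`` may be a scalar or an array of deltas; the result gains a
    trailing axis of length ``len(M)``.
    """
    dt = np.asarray(delta_days, dtype=np.float64)
    return np.cos(dt[..., None] * M)


def apply_time_encoding(X: np.ndarray, P: np.ndarray, W_scale: np.ndarray, W_add: np.ndarray) -> np.ndarray:
    """Blend time information into features: ``(P@W_scale)*X + (P@W_add)``."""
    X = np.asarray(X, dtype=np.float64)
    P = np.asarray(P, dtype=np.float64)
    if X.shape != P.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs P {P.shape}")
    return (P @ W_scale) * X + (P @ W_add)


def embed_trajectory(
    tokens: list[str],
    deltas: np.ndarray,
    age_days: float,
    embedding_table: np.ndarray,
    vocab: dict[str, int],
    M: np.ndarray,
    W_scale: np.ndarray,
    W_add: np.ndarray,
    age_mode: str = "token",
) -> np.ndarray:
    """Embed one trajectory into an ``N' x d_in`` feature sequence.

    Each token is looked up in the embedding table and time-encoded with its
    delta to the endpoint.  In "token" mode the age encoding is prepended as
    an extra row (``N' = N + 1``); in "add" mode it is added to every event
    row (``N' = N``, or 1 for an empty trajectory, which degenerates to the
    bare age row).
    """
    missing = [t for t in tokens if t not in vocab]
    if missing:
        raise KeyError(f"token(s) not in vocabulary: {missing[:5]}")
    age_row = np.cos(float(age_days) * M)[None, :]
    if len(tokens) == 0:
        return age_row
    ids = np.array([vocab[t] for t in tokens])
    X = embedding_table[ids]
    P = positional_embedding(np.asarray(deltas, dtype=np.float64), M)
    X = apply_time_encoding(X, P, W_scale, W_add)
    if age_mode == "token":
        return np.concatenate([age_row, X], axis=0)
    if age_mode == "add":
        return X + age_row
    raise ValueError("age_mode must be 'token' or 'add'")
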