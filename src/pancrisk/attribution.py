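"""Integrated-Gradients attribution and global code-importance aggregation.

For one trajectory, Integrated Gradients attributes the model output (by
default the 36-month cumulative probability) to each event's embedding
vector by integrating the gradient along the straight path from an
uninformative baseline — a same-length sequence of the zero-embedding
padding token with identical time deltas — to the actual input:

    IG_i = (x_i - x_i^base) * integral_0^1 dF/dx_i (x^base + a (x - x^base)) da

approximated with a midpoint Riemann sum.  Per-event scores sum the
embedding coordinates, preserving sign and the completeness property
``sum_i IG_i ~= F(x) - F(x_base)``; the residual (completeness gap) is
always reported.

Globally, attribution is run over the highest- and lowest-risk
trajectories; a code's importance is the fraction of its occurrences that
land in the top decile of attributed events within their own trajectory,
normalizing away raw code frequency.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .autodiff import Tensor, backward, zero_grads

logger = logging.getLogger("pancrisk")


@dataclass
class AttributionResult:
    """Per-event attributions for one trajectory."""

    tokens: list
    event_scores: np.ndarray  # one signed score per event
    output_at_input: float
    output_at_baseline: float
    completeness_gap: float


def integrated_gradients(model, params, traj, steps: int = 64, horizon_index: int = 3) -> AttributionResult:
    """Midpoint-rule IG of the chosen cumulative probability w.r.t. event embeddings.

    All interpolation steps are evaluated as one batch.  The age pseudo-token
    and the time encodings are part of the model, not of the attributed
    input, and stay fixed along the path.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    batch1 = model.prepare_batch([traj])
    n = batch1["ids"].shape[1]
    x = params["embedding"].value[batch1["ids"][0]]  # (N, d) true embeddings

    def run(embeddings: np.ndarray, nrow: int) -> Tensor:
        tiled = {
            "ids": np.tile(batch1["ids"], (nrow, 1)),
            "P": np.tile(batch1["P"], (nrow, 1, 1)),
            "age_rows": np.tile(batch1["age_rows"], (nrow, 1)),
            "mask": np.tile(batch1["mask"], (nrow, 1)),
            "labels": np.tile(batch1["labels"], (nrow, 1)),
            "censor_mask": np.tile(batch1["censor_mask"], (nrow, 1)),
        }
        E = Tensor(embeddings, requires_grad=True)
        p = model.forward(params, tiled, event_embeddings=E)
        return E, p

    alphas = (np.arange(steps) + 0.5) / steps
    E, p = run(alphas[:, None, None] * x[None], steps)
    zero_grads(params.values())
    target = p * _onehot(horizon_index)
    backward(target.sum())
    avg_grad = E.grad.mean(axis=0)  # (N, d)
    zero_grads(params.values())

    ig = x * avg_grad  # baseline is the zero embedding
    scores = ig.sum(axis=1)

    _, p_in = run(x[None], 1)
    _, p_base = run(np.zeros_like(x)[None], 1)
    f_in = float(p_in.value[0, horizon_index])
    f_base = float(p_base.value[0, horizon_index])
    gap = abs(float(ig.sum()) - (f_in - f_base))
    return AttributionResult(
        tokens=list(traj.tokens[-n:]) if n else [],
        event_scores=scores,
        output_at_input=f_in,
        output_at_baseline=f_base,
        completeness_gap=gap,
    )


def _onehot(i: int) -> np.ndarray:
    v = np.zeros(5)
    v[i] = 1.0
    return v


def select_extreme_trajectories(trajs: list, scores, k: int = 1000) -> tuple[list, list]:
    """The k highest- and k lowest-scored trajectories, deterministically.

    Ties break by (patient id, endpoint day, position).  If fewer than 2k
    trajectories are available, k is reduced with a warning.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if len(trajs) != len(scores):
        raise ValueError("trajs and scores must align")
    if len(trajs) < 2 * k:
        k = len(trajs) // 2
        logger.warning("pool smaller than 2k; reducing k to %d", k)
    order = sorted(range(len(trajs)), key=lambda i: (scores[i], trajs[i].patient_id, trajs[i].endpoint_day, i))
    lowest = [trajs[i] for i in order[:k]]
    highest = [trajs[i] for i in order[len(trajs) - k:]]
    return highest, lowest


def aggregate_code_importance(results: list) -> pd.DataFrame:
    """Top-decile hit fraction per code across attributed trajectories.

    Within each trajectory the ``ceil(0.1 N)`` highest-attributed events are
    flagged; a code's importance is flagged occurrences / total occurrences
    over all trajectories.  Returns a DataFrame with columns
    ``code, stream, hits, occurrences, importance, rank`` sorted by
    descending importance (ties by code for determinism).
    """
    hits: dict[str, int] = {}
    occ: dict[str, int] = {}
    for res in results:
        n = len(res.tokens)
        if n == 0:
            continue
        n_flag = math.ceil(0.1 * n)
        flagged = sorted(range(n), key=lambda i: (-res.event_scores[i], i))[:n_flag]
        flagged = set(flagged)
        for i, tok in enumerate(res.tokens):
            occ[tok] = occ.get(tok, 0) + 1
            if i in flagged:
                hits[tok] = hits.get(tok, 0) + 1
    rows = [
        {
            "code": tok.split(":", 1)[1] if ":" in tok else tok,
            "stream": tok.split(":", 1)[0].lower() if ":" in tok else "",
            "hits": hits.get(tok, 0),
            "occurrences": occ[tok],
            "importance": hits.get(tok, 0) / occ[tok],
        }
        for tok in occ
    ]
    df = pd.DataFrame(rows).sort_values(["importance", "code"], ascending=[False, True]).reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    return df
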