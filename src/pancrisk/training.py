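"""Training protocol: balanced sampling, plateau LR halving, grid search.

The outcome is rare, so each epoch draws up to four fresh random
trajectories per patient and then balances the stream so that roughly half
of the trajectories in each batch come from cancer patients.  Validation
AUROC is computed after every epoch on a fixed set of last-four evaluation
trajectories; when it fails to improve for more than ``plateau_patience``
epochs, the best parameters so far are reloaded and the learning rate is
halved.  The returned checkpoint is always the one with the highest
validation AUROC ever seen.

Everything is driven by explicit numpy generators, so a (seed, config,
data) triple reproduces the run exactly on one thread.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd

from .autodiff import Tensor, backward, zero_grads
from .model import ModelConfig, TransformerRiskModel, training_loss
from .prep import sample_training_trajectories, select_eval_trajectories

logger = logging.getLogger("pancrisk")

#: hyperparameter search space used for model selection
DEFAULT_GRID = {
    "L": [1, 2, 4],
    "H": [4, 8, 16],
    "d": [64, 128],
    "lr": [0.0005, 0.001, 0.005, 0.01],
    "weight_decay": [0.0, 0.01, 0.1, 0.5],
    "dropout": [0.0, 0.1, 0.2, 0.5],
}


@dataclass
class TrainConfig:
    """Training hyperparameters; defaults are the tuned optimum."""

    L: int = 1
    H: int = 16
    d: int = 64
    lr: float = 0.001
    weight_decay: float = 0.0
    dropout: float = 0.0
    epochs_max: int = 20
    plateau_patience: int = 4
    k_trajectories: int = 4
    batch_size: int = 128
    seed: int = 0
    split: tuple = (0.8, 0.1, 0.1)
    max_len: int = 300
    exclusion_months: int = 3
    censoring: str = "mask"
    horizon_index: int = 3  # 36-month horizon drives model selection
    convergence_check_every: int = 5

    def model_config(self, **overrides) -> ModelConfig:
        kw = dict(L=self.L, H=self.H, d=self.d, dropout=self.dropout,
                  max_len=self.max_len, censoring=self.censoring)
        kw.update(overrides)
        return ModelConfig(**kw)


def split_patients(cohort: list, fractions=(0.8, 0.1, 0.1), seed: int = 0) -> tuple:
    """Patient-level train/dev/test split (no trajectory leakage)."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(cohort))
    n_train = int(round(fractions[0] * len(cohort)))
    n_dev = int(round(fractions[1] * len(cohort)))
    return (
        [cohort[i] for i in order[:n_train]],
        [cohort[i] for i in order[n_train : n_train + n_dev]],
        [cohort[i] for i in order[n_train + n_dev :]],
    )


def balanced_sampler(pool: list, rng: np.random.Generator, batch_size: int = 128):
    """Yield shuffled batches with ~1:1 case:control trajectory balance.

    ``pool`` is a list of trajectories; a trajectory belongs to the case
    stream iff its patient has a cancer diagnosis (``days_to_cancer`` set).
    The minority stream is kept whole and the majority stream subsampled
    without replacement to match, so neither class is starved.
    """
    cases = [t for t in pool if t.days_to_cancer is not None]
    controls = [t for t in pool if t.days_to_cancer is None]
    if not cases or not controls:
        raise ValueError("balanced sampling needs both case and control trajectories")
    n = min(len(cases), len(controls))
    chosen_cases = [cases[i] for i in rng.choice(len(cases), size=n, replace=False)]
    chosen_controls = [controls[i] for i in rng.choice(len(controls), size=n, replace=False)]
    epoch = chosen_cases + chosen_controls
    order = rng.permutation(len(epoch))
    for start in range(0, len(epoch), batch_size):
        yield [epoch[i] for i in order[start : start + batch_size]]


class PlateauScheduler:
    """Best-checkpoint tracking with LR halving after a plateau.

    ``update`` is called once per epoch with the validation metric; it
    reports whether this epoch is the new best and whether the plateau rule
    fired (metric failed to improve for *more than* ``patience`` epochs, by
    strict comparison), in which case the caller reloads the best
    parameters and halves the learning rate.
    """

    def __init__(self, patience: int = 4):
        self.patience = patience
        self.best_metric = -np.inf
        self.best_epoch = None
        self.stale = 0

    def update(self, epoch: int, metric: float) -> dict:
        improved = np.isfinite(metric) and metric > self.best_metric
        if improved:
            self.best_metric = metric
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        halve = self.stale > self.patience
        if halve:
            self.stale = 0
        return {"improved": improved, "halve": halve}


class Adam:
    """Adaptive-moment gradient descent over a named parameter dict."""

    def __init__(self, params: dict, lr: float = 0.001, betas=(0.9, 0.999),
                 eps: float = 1e-8, frozen_rows: dict | None = None):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.value) for k, p in params.items()}
        self.frozen_rows = frozen_rows or {}

    def step(self) -> None:
        self.t += 1
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            p.value -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if k in self.frozen_rows:
                p.value[self.frozen_rows[k]] = 0.0


def _dev_auroc(model, params, dev_trajs, horizon_index: int) -> float:
    from sklearn.metrics import roc_auc_score

    if not dev_trajs:
        return float("nan")
    p = model.predict(params, dev_trajs)[:, horizon_index]
    y = np.array([t.labels[horizon_index] for t in dev_trajs])
    observed = np.array([t.censor_mask[horizon_index] for t in dev_trajs]) == 1
    y, p = y[observed], p[observed]
    if len(np.unique(y)) < 2:
        return float("nan")
    return float(roc_auc_score(y, p))


def train(train_patients: list, dev_patients: list, config: TrainConfig,
          vocab: dict | None = None, model=None):
    """Train a risk model; returns ``(model, best_params, history)``.

    ``model`` may be any object with the ``init_params / prepare_batch /
    forward`` interface (the transformer by default, also the baselines).
    ``history`` is a DataFrame with one row per epoch: loss, validation
    AUROC and the learning rate in force.
    """
    from .prep import build_vocab

    if vocab is None:
        vocab = build_vocab(train_patients + dev_patients)
    if model is None:
        model = TransformerRiskModel(config.model_config(), vocab)
    rng = np.random.default_rng(config.seed)
    params = model.init_params(rng)
    opt = Adam(params, lr=config.lr, frozen_rows=getattr(model, "frozen_rows", {}))
    sched = PlateauScheduler(config.plateau_patience)

    dev_trajs = [
        t
        for rec in dev_patients
        for t in select_eval_trajectories(rec, config.max_len, config.exclusion_months, config.censoring)
    ]
    best_params = {k: p.value.copy() for k, p in params.items()}
    history = []
    for epoch in range(config.epochs_max):
        pool = [
            t
            for rec in train_patients
            for t in sample_training_trajectories(
                rec, config.k_trajectories, rng, config.max_len, config.exclusion_months, config.censoring
            )
        ]
        losses = []
        for batch_trajs in balanced_sampler(pool, rng, config.batch_size):
            batch = model.prepare_batch(batch_trajs)
            p = model.forward(params, batch, rng=rng, train=True)
            loss = training_loss(p, batch["labels"], batch["censor_mask"], params, config.weight_decay)
            if not np.isfinite(loss.value):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}: {loss.value}")
            zero_grads(params.values())
            backward(loss)
            opt.step()
            losses.append(float(loss.value))
        auroc = _dev_auroc(model, params, dev_trajs, config.horizon_index)
        state = sched.update(epoch, auroc)
        if state["improved"]:
            best_params = {k: p.value.copy() for k, p in params.items()}
        history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "dev_auroc": auroc, "lr": opt.lr}
        )
        logger.info("epoch %d loss %.4f dev_auroc %.4f lr %.5f", epoch, history[-1]["loss"], auroc, opt.lr)
        if state["halve"]:
            for k, p in params.items():
                p.value = best_params[k].copy()
            opt = Adam(params, lr=opt.lr / 2.0, frozen_rows=getattr(model, "frozen_rows", {}))
            logger.info("plateau: reloaded best (epoch %s), lr halved to %.6f", sched.best_epoch, opt.lr)

    final = {k: Tensor(v.copy(), requires_grad=True) for k, v in best_params.items()}
    return model, final, pd.DataFrame(history)


def grid_search(space: dict, evaluator, budget: int | None = None, seed: int = 0):
    """Exhaustive (or budgeted random-subsample) search over a config grid.

    ``evaluator`` maps a config dict to a validation score.  Returns the
    argmax config; ties break toward the smaller (L, H, d) model, then
    lexicographically on the remaining items for determinism.
    """
    if not space:
        raise ValueError("empty search space")
    keys = sorted(space)
    configs = [dict(zip(keys, vals)) for vals in product(*(space[k] for k in keys))]
    if budget is not None and budget < len(configs):
        rng = np.random.default_rng(seed)
        idx = sorted(rng.choice(len(configs), size=budget, replace=False))
        configs = [configs[i] for i in idx]

    def tie_key(cfg):
        size = tuple(cfg.get(k, 0) for k in ("L", "H", "d"))
        rest = tuple((k, repr(cfg[k])) for k in sorted(cfg))
        return size + rest

    best, best_score = None, -np.inf
    for cfg in configs:
        score = evaluator(cfg)
        if score > best_score or (score == best_score and best is not None and tie_key(cfg) < tie_key(best)):
            best, best_score = cfg, score
    return best
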