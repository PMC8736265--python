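"""Teacher-forced training with Adam, and the validation-loss epoch rule.

The objective is the summed negative log-likelihood of each correct word
given the image and all preceding words (sparse categorical cross-entropy
with sum reduction per sequence, mean over the batch).  Training unrolls
the recurrence with the ground-truth previous token as each step's input;
the image is injected once at t = -1.  After every epoch the full
validation loss is recorded and the checkpoint finally returned is the one
with minimal validation loss — the generic form of picking the epoch where
held-out loss bottoms out before overfitting sets in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .corpus import PAD_ID
from .model import CaptionModel, LOSS_EPS

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    def __init__(self, epoch: int, batch: int):
        super().__init__(f"non-finite loss at epoch {epoch}, batch {batch}")
        self.epoch = epoch
        self.batch = batch


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 64
    max_epochs: int = 30
    dropout_p: float = 0.5
    seed: int = 0
    optimizer: str = "adam"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    clip_norm: float = 5.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer != "adam":
            raise ValueError(f"unsupported optimizer {self.optimizer!r}")


@dataclass
class EpochTrace:
    epoch: int
    train_loss: float
    val_loss: float
    train_acc: float
    val_acc: float

    def __post_init__(self) -> None:
        for v in (self.train_loss, self.val_loss):
            if not np.isfinite(v) or v < 0:
                raise ValueError("losses must be finite and non-negative")


def sequence_loss(probs: np.ndarray, targets: np.ndarray) -> float:
    """Summed -log p of the correct token, pad positions excluded.

    ``probs`` is (T, V) for one sequence or (B, T, V) for a batch;
    ``targets`` holds the ids to predict at each of the T positions (i.e.
    tokens[1:]).  Reduction is sum per sequence, mean over the batch.
    Probabilities at exactly 0 are clamped to 1e-12 (and logged) so the
    loss stays finite.
    """
    probs = np.asarray(probs, dtype=np.float64)
    targets = np.asarray(targets, dtype=np.int64)
    if probs.ndim == 2:
        probs, targets = probs[None], targets[None]
    mask = targets != PAD_ID
    idx = np.clip(targets - 1, 0, None)
    p_corr = np.take_along_axis(probs, idx[:, :, None], axis=2)[:, :, 0]
    if (p_corr[mask] <= 0).any():
        logger.warning("zero probability on a correct token; clamping at %g", LOSS_EPS)
    nll = -np.log(np.maximum(p_corr, LOSS_EPS)) * mask
    return float(nll.sum(axis=1).mean())


def teacher_forcing_batch(
    model: CaptionModel,
    spatial: np.ndarray,
    penult: np.ndarray,
    tokens: np.ndarray,
) -> np.ndarray:
    """Evaluation-mode per-sequence distributions, (B, L-1, V).

    The ground-truth token at position t is the input for predicting
    position t+1, so each length-L sequence yields L-1 distributions.
    """
    return model.forward_batch(spatial, penult, tokens, training=False)["probs"]


class AdamOptimizer:
    """Adam with global-norm gradient clipping."""

    def __init__(self, params: dict[str, np.ndarray], config: TrainConfig):
        self.cfg = config
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        cfg = self.cfg
        gnorm = np.sqrt(sum(float((g * g).sum()) for g in grads.values()))
        scale = min(1.0, cfg.clip_norm / gnorm) if gnorm > 0 else 1.0
        self.t += 1
        b1c = 1 - cfg.beta1 ** self.t
        b2c = 1 - cfg.beta2 ** self.t
        for k, g in grads.items():
            g = g * scale
            self.m[k] = cfg.beta1 * self.m[k] + (1 - cfg.beta1) * g
            self.v[k] = cfg.beta2 * self.v[k] + (1 - cfg.beta2) * g * g
            params[k] -= cfg.learning_rate * (self.m[k] / b1c) / (
                np.sqrt(self.v[k] / b2c) + cfg.eps
            )


def evaluate_loss(
    model: CaptionModel,
    spatial: np.ndarray,
    penult: np.ndarray,
    tokens: np.ndarray,
    batch_size: int = 64,
) -> tuple[float, float]:
    """Mean per-sequence loss and token accuracy over a dataset, eval mode."""
    losses, accs, weights = [], [], []
    for i in range(0, len(tokens), batch_size):
        out = model.forward_batch(
            spatial[i : i + batch_size], penult[i : i + batch_size],
            tokens[i : i + batch_size], training=False,
        )
        n = len(tokens[i : i + batch_size])
        losses.append(out["loss"] * n)
        accs.append(out["accuracy"] * n)
        weights.append(n)
    total = sum(weights)
    return sum(losses) / total, sum(accs) / total


def train(
    model: CaptionModel,
    train_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    val_data: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: TrainConfig,
) -> tuple[dict[str, np.ndarray], list[EpochTrace]]:
    """Minibatch Adam training; returns (best-epoch parameters, trace).

    ``train_data``/``val_data`` are ``(spatial, penult, tokens)`` triples of
    pre-extracted backbone features and padded id sequences.  Everything
    random — batch order, dropout masks — derives from ``config.seed``, so
    identical configs reproduce identical traces.  The returned parameters
    are the epoch checkpoint with minimal validation loss (first epoch wins
    ties).
    """
    sp_tr, pen_tr, tok_tr = train_data
    rng = np.random.default_rng(config.seed)
    opt = AdamOptimizer(model.params, config)
    model.config.dropout_p = config.dropout_p
    n = len(tok_tr)
    traces: list[EpochTrace] = []
    best_loss = np.inf
    best_params = model.copy_params()

    for epoch in range(config.max_epochs):
        order = rng.permutation(n)
        batch_losses, batch_accs = [], []
        for bi, start in enumerate(range(0, n, config.batch_size)):
            sel = order[start : start + config.batch_size]
            fwd = model.forward_batch(
                sp_tr[sel], pen_tr[sel], tok_tr[sel], training=True, rng=rng
            )
            if not np.isfinite(fwd["loss"]):
                raise TrainingDivergedError(epoch, bi)
            grads = model.backward(fwd)
            opt.step(model.params, grads)
            batch_losses.append(fwd["loss"])
            batch_accs.append(fwd["accuracy"])
        val_loss, val_acc = evaluate_loss(model, *val_data)
        trace = EpochTrace(
            epoch=epoch,
            train_loss=float(np.mean(batch_losses)),
            val_loss=val_loss,
            train_acc=float(np.mean(batch_accs)),
            val_acc=val_acc,
        )
        traces.append(trace)
        logger.info(
            "epoch %d: train_loss=%.4f val_loss=%.4f train_acc=%.3f val_acc=%.3f",
            trace.epoch, trace.train_loss, trace.val_loss, trace.train_acc, trace.val_acc,
        )
        if val_loss < best_loss:
            best_loss = val_loss
            best_params = model.copy_params()

    return best_params, traces


def traces_to_csv(traces: list[EpochTrace], path: str) -> None:
    import pandas as pd

    pd.DataFrame([t.__dict__ for t in traces]).to_csv(path, index=False)
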