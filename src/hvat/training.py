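"""Training: token-budget mini-batching, Nesterov-momentum SGD with
per-branch learning rates, and early stopping on validation AUC.

Mini-batches hold a roughly constant *token* count rather than patient count:
sequences are sorted by length and packed greedily, so patients in a batch
have similar sequence lengths and batches with more patients all have shorter
sequences.  The three parts of the model — transformer branch (with the
embedding tables), static branch, and the fusion/output part — each get their
own learning rate.  Training stops when validation AUC fails to improve for
``patience`` consecutive epochs; the returned model is the checkpoint with the
highest validation AUC.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .evaluation import auc
from .network import BatchTensors, HvatModel, logit_loss, make_batch, predict_sequences
from .tokenization import TokenSequence

logger = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Optimization hyperparameters; defaults are the prototype settings."""

    token_budget: int = 10000
    lr_static_branch: float = 5e-4
    lr_vat_branch: float = 5e-5
    lr_head: float = 1e-4
    momentum: float = 0.9
    patience_epochs: int = 10
    max_epochs: int = 200
    seed: int = 0
    #: patient-count batching instead of the token budget; used by the
    #: orderless tabular models, where sequence length is meaningless.
    batch_patients: int | None = None

    def __post_init__(self) -> None:
        if min(self.lr_static_branch, self.lr_vat_branch, self.lr_head) < 0:
            raise ValueError("learning rates must be non-negative")
        if self.patience_epochs < 1:
            raise ValueError("patience must be >= 1")


@dataclass
class EpochRecord:
    epoch: int
    train_loss: float
    val_auc: float


@dataclass
class TrainLog:
    epochs: list[EpochRecord] = field(default_factory=list)
    best_epoch: int = -1

    @property
    def best_val_auc(self) -> float:
        return self.epochs[self.best_epoch - 1].val_auc if self.best_epoch > 0 else float("nan")


def build_batches(sequences: list[TokenSequence], budget: int) -> list[list[int]]:
    """Greedy length-sorted packing into token-budget batches.

    Returns lists of indices into ``sequences``.  Every batch's token sum is
    <= budget, except that a single sequence longer than the budget forms its
    own batch (with a warning).  Sorting first guarantees that patients within
    a batch have similar sequence lengths.
    """
    if budget <= 0:
        raise ValueError("token budget must be positive")
    order = sorted(range(len(sequences)), key=lambda i: (len(sequences[i].tokens), i))
    batches: list[list[int]] = []
    current: list[int] = []
    current_sum = 0
    for i in order:
        n = len(sequences[i].tokens)
        if n > budget and not current:
            logger.warning("sequence of %d tokens exceeds budget %d; forms its own batch", n, budget)
            batches.append([i])
            continue
        if current and current_sum + n > budget:
            batches.append(current)
            current, current_sum = [], 0
        if n > budget:
            batches.append([i])
            logger.warning("sequence of %d tokens exceeds budget %d; forms its own batch", n, budget)
            continue
        current.append(i)
        current_sum += n
    if current:
        batches.append(current)
    return batches


def initialize_weights(model: HvatModel, seed: int) -> HvatModel:
    """He fan-in initialization of every linear and embedding weight."""
    model.initialize(seed)
    return model


class NesterovSGD:
    """Mini-batch SGD with Nesterov momentum and per-group learning rates."""

    def __init__(self, groups: list[tuple[list, float]], momentum: float = 0.9):
        self.groups = groups
        self.momentum = momentum
        self.velocity = [[np.zeros_like(p.data) for p in params] for params, _ in groups]

    def step(self) -> None:
        mu = self.momentum
        for gi, (params, lr) in enumerate(self.groups):
            for pi, p in enumerate(params):
                if p.grad is None:
                    continue
                v = self.velocity[gi][pi]
                v *= mu
                v += p.grad
                p.data -= lr * (p.grad + mu * v)


def train(
    model: HvatModel,
    train_sequences: list[TokenSequence],
    train_statics: np.ndarray,
    train_labels: np.ndarray,
    val_sequences: list[TokenSequence],
    val_statics: np.ndarray,
    val_labels: np.ndarray,
    config: TrainConfig,
) -> tuple[HvatModel, TrainLog]:
    """Fit the model, early-stopping on validation AUC.

    Each epoch shuffles the order of the (fixed) token-budget batches, runs
    forward/backward/update per batch, then scores validation AUC with
    dropout disabled.  "Improvement" means strictly greater AUC than the best
    seen.  The best checkpoint (highest validation AUC) is restored into the
    model before returning.
    """
    rng = np.random.default_rng(config.seed)
    if config.batch_patients is not None:
        n = len(train_sequences)
        batch_indices = [
            list(range(lo, min(lo + config.batch_patients, n)))
            for lo in range(0, n, config.batch_patients)
        ]
    else:
        batch_indices = build_batches(train_sequences, config.token_budget)
    batches: list[BatchTensors] = [
        make_batch(
            [train_sequences[i] for i in idx],
            train_statics[idx],
            train_labels[idx],
        )
        for idx in (np.asarray(b) for b in batch_indices)
    ]
    groups = model.parameter_groups()
    optimizer = NesterovSGD(
        [
            ([p for _, p in groups["vat"]], config.lr_vat_branch),
            ([p for _, p in groups["static"]], config.lr_static_branch),
            ([p for _, p in groups["head"]], config.lr_head),
        ],
        momentum=config.momentum,
    )

    log = TrainLog()
    best_auc = -np.inf
    best_state: dict | None = None
    epochs_since_improvement = 0
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(len(batches))
        total_loss = 0.0
        dropout_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        for bi in order:
            batch = batches[bi]
            model.zero_grad()
            logits = model.forward_logits(batch, training=True, rng=dropout_rng)
            loss = logit_loss(logits, batch.labels)
            if not np.isfinite(loss.data):
                raise FloatingPointError(f"non-finite training loss at epoch {epoch}")
            loss.backward()
            optimizer.step()
            total_loss += float(loss.data)

        val_scores = predict_sequences(model, val_sequences, val_statics, val_labels)
        val_auc = auc(val_scores, val_labels)
        log.epochs.append(EpochRecord(epoch, total_loss, val_auc))
        if val_auc > best_auc:
            best_auc = val_auc
            best_state = model.state_dict()
            log.best_epoch = epoch
            epochs_since_improvement = 0
        else:
            epochs_since_improvement += 1
        logger.info("epoch %d: train loss %.3f, val AUC %.4f", epoch, total_loss, val_auc)
        if epochs_since_improvement >= config.patience_epochs:
            break

    if best_state is not None:
        model.load_state_dict(best_state)
    return model, log
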