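"""Pseudo-labeling self-training over an unlabeled window pool.

After an initial adversarially regularized fit on the labeled windows, the
model predicts the pool; windows whose top class probability clears a
confidence threshold receive that class as a pseudo-label, join the
training set, and the model is retrained.  A round that accepts nothing
stops the loop.  Ground-truth labels are never overwritten, the pool only
shrinks, and every acceptance is recorded in an audit trail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .adversarial import AdversarialConfig, TrainResult, train_adversarial
from .sync_lstm import SyncLSTMParams, TrainingConfig, predict_proba
from .windowing import EncodedWindow, UnlabeledPool, stack_windows

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PseudoLabelRecord:
    """One accepted pseudo-label: which window, what class, how confident."""

    window_id: int
    assigned_class: int
    confidence: float
    round_index: int


@dataclass
class SelfTrainResult:
    params: SyncLSTMParams
    history: list  # per-round training histories
    audit_trail: list[PseudoLabelRecord] = field(default_factory=list)
    rounds_run: int = 0

    def pseudo_label_error_rate(self, true_labels: dict[int, int]) -> float:
        """Fraction of accepted pseudo-labels disagreeing with held ground
        truth (for simulator audits where the truth is known)."""
        checked = [r for r in self.audit_trail if r.window_id in true_labels]
        if not checked:
            return float("nan")
        wrong = sum(r.assigned_class != true_labels[r.window_id] for r in checked)
        return wrong / len(checked)


def pseudo_label(params: SyncLSTMParams, pool: UnlabeledPool, threshold: float,
                 round_index: int = 0,
                 literal_output_lag: bool = False
                 ) -> tuple[list[PseudoLabelRecord], UnlabeledPool]:
    """Assign argmax labels to pool windows with confidence >= threshold.

    Confidence is the maximum class probability.  Accepted windows leave
    the pool; the remaining pool is returned alongside the records.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    if len(pool) == 0:
        return [], pool
    X, _ = stack_windows(pool.windows)
    probs = predict_proba(X, params, literal_output_lag=literal_output_lag)
    conf = probs.max(axis=1)
    labels = probs.argmax(axis=1)
    accepted: list[PseudoLabelRecord] = []
    remaining: list[EncodedWindow] = []
    for w, c, l in zip(pool.windows, conf, labels):
        if c >= threshold:
            accepted.append(PseudoLabelRecord(window_id=w.uid, assigned_class=int(l),
                                              confidence=float(c),
                                              round_index=round_index))
        else:
            remaining.append(w)
    return accepted, UnlabeledPool(remaining)


def write_audit_trail(records: Sequence[PseudoLabelRecord], path) -> None:
    """Tab-separated audit listing: window id, round, class, confidence."""
    with open(path, "w") as f:
        f.write("window_id\tround\tassigned_class\tconfidence\n")
        for r in records:
            f.write(f"{r.window_id}\t{r.round_index}\t{r.assigned_class}\t"
                    f"{r.confidence:.6f}\n")


def self_train(labeled: Sequence[EncodedWindow], pool: UnlabeledPool,
               config: TrainingConfig,
               adv_config: Optional[AdversarialConfig] = None,
               threshold: float = 0.95, rounds: int = 1,
               pseudo_weight: float = 1.0,
               val_set=None,
               continuous_mask: Optional[np.ndarray] = None) -> SelfTrainResult:
    """Self-training loop: train, pseudo-label, absorb, retrain.

    ``rounds`` counts pseudo-labeling passes after the initial fit (the
    single-pass scheme is ``rounds=1``).  ``pseudo_weight`` down-weights
    pseudo-labeled samples in the loss; 1.0 treats them as ordinary
    training data.  With an empty pool the result equals plain
    adversarially regularized training at the same seed.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    if not labeled:
        raise ValueError("cold start unsupported: the labeled set is empty")
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    X, y = stack_windows(labeled)
    sw = np.ones(len(X))
    pool_ids = pool.ids()
    overlap = {w.uid for w in labeled} & pool_ids
    if overlap:
        raise ValueError(f"pool shares {len(overlap)} ids with the labeled set")

    pool_by_id = {w.uid: w for w in pool.windows}
    result = train_adversarial((X, y, sw), config, adv_config, val_set=val_set,
                               continuous_mask=continuous_mask)
    histories = [result.history]
    audit: list[PseudoLabelRecord] = []
    rounds_run = 0
    for rnd in range(1, rounds + 1):
        accepted, pool = pseudo_label(result.params, pool, threshold,
                                      round_index=rnd,
                                      literal_output_lag=config.literal_output_lag)
        if not accepted:
            logger.info("round %d accepted nothing; stopping early", rnd)
            break
        rounds_run = rnd
        audit.extend(accepted)
        X_new = np.stack([pool_by_id[r.window_id].streams for r in accepted])
        y_new = np.array([r.assigned_class for r in accepted], dtype=int)
        X = np.concatenate([X, X_new])
        y = np.concatenate([y, y_new])
        sw = np.concatenate([sw, np.full(len(accepted), pseudo_weight)])
        logger.info("round %d: accepted %d pseudo-labels (training set now %d)",
                    rnd, len(accepted), len(X))
        result = train_adversarial((X, y, sw), config, adv_config,
                                   val_set=val_set,
                                   continuous_mask=continuous_mask)
        histories.append(result.history)
    return SelfTrainResult(params=result.params, history=histories,
                           audit_trail=audit, rounds_run=rounds_run)
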