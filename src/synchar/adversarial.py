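"""Worst-case input perturbations and adversarially regularized training.

During training the current model is frozen (θ̂) and, for each window, the
bounded additive offset r that most increases the classification loss is
approximated by one linearized gradient step:

    r = ε · g / ||g||_2     (or  ε · sign(g)  under the ∞-norm)

where g is the gradient of the negative log-likelihood with respect to the
input streams.  The training loss mixes the clean and perturbed terms,

    L_total = (1 − λ) · L(x) + λ · L(x + r),

so the module is exactly inert at ε = 0 or λ = 0.  Perturbations live in
the continuous encoded space; positions belonging to one-hot (discrete)
blocks are masked to zero by default, because an additive offset to a
token indicator has no physical reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .sync_lstm import (AdamState, SyncLSTMParams, TrainingConfig,
                        TrainingDivergedError, accuracy, adam_step, bptt_backward,
                        clip_gradients, init_params, learning_rate_at, loss,
                        make_dropout_masks, sync_forward)
from .windowing import EncodedWindow, stack_windows

logger = logging.getLogger(__name__)


@dataclass
class AdversarialConfig:
    """Perturbation budget and mixing weight.

    ε is on the scale of the [0, 1]-normalized continuous channels; λ is
    the weight of the perturbed loss term.
    """

    epsilon: float = 0.05
    norm_type: str = "l2"
    adv_weight: float = 0.5
    mask_discrete_channels: bool = True

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.norm_type not in ("l2", "linf"):
            raise ValueError(f"unknown norm {self.norm_type!r}")
        if not 0.0 <= self.adv_weight <= 1.0:
            raise ValueError("adv_weight must lie in [0, 1]")


@dataclass
class Perturbation:
    """A bounded per-stream, per-slot additive offset for one batch."""

    r: np.ndarray  # same shape as the input batch (B, M, T, D)
    norm_bound: float
    norm_type: str

    def norms(self) -> np.ndarray:
        if self.norm_type == "l2":
            return np.sqrt((self.r ** 2).sum(axis=(1, 2, 3)))
        return np.abs(self.r).max(axis=(1, 2, 3))


def _direction(g: np.ndarray, epsilon: float, norm_type: str) -> np.ndarray:
    """Per-item maximal-ascent offset of norm ε (zero where g = 0)."""
    r = np.zeros_like(g)
    if epsilon == 0.0:
        return r
    if norm_type == "l2":
        norms = np.sqrt((g ** 2).sum(axis=tuple(range(1, g.ndim)), keepdims=True))
        nz = norms.reshape(len(g)) > 0
        r[nz] = epsilon * g[nz] / norms[nz]
    else:
        r = epsilon * np.sign(g)
    return r


def worst_case_perturbation(params: SyncLSTMParams, X: np.ndarray,
                            labels: np.ndarray, config: AdversarialConfig,
                            continuous_mask: Optional[np.ndarray] = None,
                            dropout_masks: Optional[np.ndarray] = None,
                            literal_output_lag: bool = False) -> Perturbation:
    """Single-step linearized worst-case offset against frozen parameters.

    ``continuous_mask`` is the (M, D) boolean mask of continuous feature
    positions; discrete positions receive zero offset when masking is on.
    No gradient flows into the parameters through r.
    """
    single = X.ndim == 3
    if single:
        X = X[None]
        labels = np.atleast_1d(labels)
    cache = sync_forward(X, params, dropout_masks=dropout_masks,
                         literal_output_lag=literal_output_lag)
    _, dX = bptt_backward(cache, labels, gamma=0.0)
    if config.mask_discrete_channels and continuous_mask is not None:
        dX = dX * continuous_mask[None, :, None, :]
    r = _direction(dX, config.epsilon, config.norm_type)
    if single:
        r = r[0:1]
    return Perturbation(r=r, norm_bound=config.epsilon, norm_type=config.norm_type)


def adversarial_loss(params: SyncLSTMParams, X: np.ndarray, labels: np.ndarray,
                     config: AdversarialConfig, gamma: float = 0.0,
                     continuous_mask: Optional[np.ndarray] = None) -> float:
    """(1 − λ)·L(x) + λ·L(x + r) with r from the linearized worst case."""
    clean = loss(sync_forward(X, params), labels, params, gamma)
    if config.epsilon == 0.0:
        return clean
    pert = worst_case_perturbation(params, X, labels, config, continuous_mask)
    adv = loss(sync_forward(X + pert.r, params), labels, params, gamma)
    lam = config.adv_weight
    return (1.0 - lam) * clean + lam * adv


@dataclass
class EpochRecord:
    epoch: int
    lr: float
    clean_loss: float
    adv_loss: float
    val_accuracy: float


@dataclass
class TrainResult:
    params: SyncLSTMParams
    history: list[EpochRecord] = field(default_factory=list)


def _as_arrays(data) -> tuple[np.ndarray, np.ndarray, Optional[np.ndarray]]:
    if isinstance(data, tuple):
        return data if len(data) == 3 else (*data, None)
    X, y = stack_windows(data)
    return X, y, None


def train_adversarial(train_set, config: TrainingConfig,
                      adv_config: Optional[AdversarialConfig] = None,
                      val_set=None,
                      continuous_mask: Optional[np.ndarray] = None,
                      params: Optional[SyncLSTMParams] = None) -> TrainResult:
    """Mini-batch Adam training with the adversarial regularizer.

    ``train_set`` is a sequence of labeled :class:`EncodedWindow` or an
    ``(X, y)`` / ``(X, y, sample_weights)`` tuple.  At ε = 0 the
    perturbation machinery is skipped entirely and the run is plain
    supervised training.  Aborts with :class:`TrainingDivergedError` when
    the loss turns non-finite.
    """
    if adv_config is None:
        adv_config = AdversarialConfig(epsilon=0.0)
    X, y, sw = _as_arrays(train_set)
    if len(X) == 0:
        raise ValueError("empty training set")
    if y.min() < 0:
        raise ValueError("training set contains unlabeled windows")
    Xv, yv = (None, None)
    if val_set is not None:
        Xv, yv, _ = _as_arrays(val_set)
    rng = np.random.default_rng(config.seed)
    if params is None:
        n_classes = int(y.max()) + 1
        params = init_params(X.shape[3], config.hidden, X.shape[1], n_classes,
                             rng, shared=config.share_weights)
    else:
        params = params.copy()
    state = AdamState.zeros(params)
    lam = adv_config.adv_weight
    history: list[EpochRecord] = []
    N = len(X)
    for epoch in range(config.epochs):
        lr = learning_rate_at(epoch, config)
        order = rng.permutation(N)
        clean_sum = adv_sum = 0.0
        n_batches = 0
        for lo in range(0, N, config.batch_size):
            idx = order[lo:lo + config.batch_size]
            xb, yb = X[idx], y[idx]
            swb = sw[idx] if sw is not None else None
            masks = None
            if config.dropout_rate > 0.0:
                masks = make_dropout_masks(
                    rng, (len(xb), xb.shape[1], xb.shape[2], config.hidden),
                    config.dropout_rate)
            cache = sync_forward(xb, params, dropout_masks=masks,
                                 literal_output_lag=config.literal_output_lag)
            clean_loss = loss(cache, yb, params, config.l2_coeff, swb)
            grads, dX = bptt_backward(cache, yb, config.l2_coeff, swb)
            adv_loss_b = clean_loss
            if adv_config.epsilon > 0.0:
                if adv_config.mask_discrete_channels and continuous_mask is not None:
                    dX = dX * continuous_mask[None, :, None, :]
                r = _direction(dX, adv_config.epsilon, adv_config.norm_type)
                # same dropout masks: the perturbed pass sees the same subnetwork
                cache_adv = sync_forward(xb + r, params, dropout_masks=masks,
                                         literal_output_lag=config.literal_output_lag)
                adv_loss_b = loss(cache_adv, yb, params, config.l2_coeff, swb)
                grads_adv, _ = bptt_backward(cache_adv, yb, config.l2_coeff, swb)
                grads = {k: (1.0 - lam) * grads[k] + lam * grads_adv[k]
                         for k in grads}
            total = (1.0 - lam) * clean_loss + lam * adv_loss_b \
                if adv_config.epsilon > 0.0 else clean_loss
            if not np.isfinite(total):
                raise TrainingDivergedError(epoch)
            grads = clip_gradients(grads, config.grad_clip)
            params, state = adam_step(params, grads, state, lr, config)
            clean_sum += clean_loss
            adv_sum += adv_loss_b
            n_batches += 1
        val_acc = accuracy(Xv, yv, params,
                           literal_output_lag=config.literal_output_lag) \
            if Xv is not None and len(Xv) else float("nan")
        history.append(EpochRecord(epoch=epoch, lr=lr,
                                   clean_loss=clean_sum / n_batches,
                                   adv_loss=adv_sum / n_batches,
                                   val_accuracy=val_acc))
        if (epoch + 1) % max(1, config.epochs // 10) == 0:
            logger.info("epoch %d/%d clean %.4f adv %.4f val %.3f", epoch + 1,
                        config.epochs, history[-1].clean_loss,
                        history[-1].adv_loss, val_acc)
    return TrainResult(params=params, history=history)


def train_supervised(train_set, config: TrainingConfig, val_set=None,
                     params: Optional[SyncLSTMParams] = None) -> TrainResult:
    """Plain supervised training: the ε = 0 reduction of the loop above."""
    return train_adversarial(train_set, config,
                             AdversarialConfig(epsilon=0.0),
                             val_set=val_set, params=params)
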