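"""Synchronized peephole-LSTM: forward pass, exact BPTT, Adam training.

The network runs M LSTM lanes in lock-step over M parallel input streams
(the S/V/P channels of a window, or one lane per room).  Each lane is a
peephole LSTM cell:

    i_t = sigmoid(W_xi x_t + W_hi h_{t-1} + w_ci * c_{t-1} + b_i)
    f_t = sigmoid(W_xf x_t + W_hf h_{t-1} + w_cf * c_{t-1} + b_f)
    o_t = sigmoid(W_xo x_t + W_ho h_{t-1} + w_co * c_{t-1} + b_o)
    c_t = f_t * c_{t-1} + i_t * tanh(W_xc x_t + W_hc h_{t-1} + b_c)
    h_t = o_t * tanh(c_t)

Note the deliberate literal choice that **all three** gate peepholes read
c_{t-1}, including the output gate (the common variant reads c_t there);
this keeps the implementation faithful to the printed cell equations and
is covered by the finite-difference gradient check.

The M final hidden states are concatenated into an M*h merged vector and
projected through a softmax output head.  The training objective is mean
cross-entropy plus an L2 penalty on weights (biases excluded):

    L = -(1/k) sum_k log p(y_k) + Gamma * sum(W^2)

Everything is plain float64 NumPy by design — the recurrence and its
gradients are the artifact, checked against central finite differences.

The output projection is written in some sources as reading h_{t-1}; the
default here projects the final state h_T (the only reading consistent
with window classification), with ``literal_output_lag=True`` restoring
the lagged form.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = [
    "TrainingConfig", "SyncLSTMParams", "CellState", "ForwardCache",
    "init_params", "lstm_cell_forward", "sync_forward", "loss",
    "bptt_backward", "clip_gradients", "AdamState", "adam_step",
    "learning_rate_at", "predict_proba", "predict", "make_dropout_masks",
    "save_params", "load_params", "TrainingDivergedError",
]

WEIGHT_KEYS = ("Wxi", "Whi", "wci", "Wxf", "Whf", "wcf",
               "Wxo", "Who", "wco", "Wxc", "Whc", "Wy")
BIAS_KEYS = ("bi", "bf", "bo", "bc", "by")
ALL_KEYS = WEIGHT_KEYS + BIAS_KEYS


class TrainingDivergedError(RuntimeError):
    """Raised when the loss turns non-finite during training."""

    def __init__(self, epoch: int):
        super().__init__(f"training diverged (non-finite loss) at epoch {epoch}")
        self.epoch = epoch


@dataclass
class TrainingConfig:
    """Optimizer and architecture hyperparameters.

    ``momentum`` maps onto Adam's first-moment decay beta1 (Adam has no
    separate momentum knob).  The learning rate warms up linearly from
    ``initial_lr`` to ``target_lr`` over the first tenth of the epochs and
    stays constant after.
    """

    hidden: int = 128
    epochs: int = 100
    initial_lr: float = 0.001
    target_lr: float = 0.005
    momentum: float = 0.5  # Adam beta1
    beta2: float = 0.999
    adam_eps: float = 1e-8
    batch_size: int = 100
    dropout_rate: float = 0.5
    grad_clip: float = 5.0
    l2_coeff: float = 1e-4
    seed: int = 0
    share_weights: bool = True
    literal_output_lag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.initial_lr <= 0 or self.target_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


def learning_rate_at(epoch: int, config: TrainingConfig) -> float:
    """Linear warm-up from initial_lr to target_lr over the first 10% of
    epochs (at least one), constant afterwards."""
    warmup = max(1, math.ceil(0.1 * config.epochs))
    if epoch >= warmup:
        return config.target_lr
    frac = (epoch + 1) / warmup
    return config.initial_lr + frac * (config.target_lr - config.initial_lr)


@dataclass
class SyncLSTMParams:
    """All gate/cell/output weights.

    With ``shared=True`` (default) the gate and cell weights carry no
    stream axis and are reused by every lane; otherwise each weight has a
    leading stream axis.  The output head always maps the merged M*h
    vector to class logits.
    """

    weights: dict[str, np.ndarray]
    n_streams: int
    shared: bool = True

    @property
    def hidden(self) -> int:
        return self.weights["bi"].shape[-1]

    @property
    def input_dim(self) -> int:
        return self.weights["Wxi"].shape[-2]

    @property
    def n_classes(self) -> int:
        return self.weights["by"].shape[-1]

    def lane(self, key: str, m: int) -> np.ndarray:
        """Weight array for lane m (identity under sharing)."""
        w = self.weights[key]
        return w if self.shared or key in ("Wy", "by") else w[m]

    def copy(self) -> "SyncLSTMParams":
        return SyncLSTMParams({k: v.copy() for k, v in self.weights.items()},
                              self.n_streams, self.shared)

    def check_finite(self) -> None:
        for k, v in self.weights.items():
            if not np.all(np.isfinite(v)):
                raise FloatingPointError(f"non-finite entries in {k}")

    def zeros_like(self) -> dict[str, np.ndarray]:
        return {k: np.zeros_like(v) for k, v in self.weights.items()}


@dataclass
class CellState:
    """Per-lane hidden and cell vectors, shape (..., M, h)."""

    h: np.ndarray
    c: np.ndarray


def init_params(input_dim: int, hidden: int, n_streams: int, n_classes: int,
                rng: np.random.Generator, shared: bool = True,
                scale: float = 0.1) -> SyncLSTMParams:
    """Small uniform initialisation; forget-gate bias starts at +1 so early
    training does not wash out the cell state."""
    def u(*shape):
        return rng.uniform(-scale, scale, size=shape)

    def gate(xdim):
        if shared:
            return u(xdim, hidden), u(hidden, hidden), u(hidden)
        return (u(n_streams, xdim, hidden), u(n_streams, hidden, hidden),
                u(n_streams, hidden))

    w: dict[str, np.ndarray] = {}
    for g in ("i", "f", "o"):
        w[f"Wx{g}"], w[f"Wh{g}"], w[f"wc{g}"] = gate(input_dim)
        w[f"b{g}"] = np.zeros(hidden) if shared else np.zeros((n_streams, hidden))
    if shared:
        w["Wxc"], w["Whc"] = u(input_dim, hidden), u(hidden, hidden)
        w["bc"] = np.zeros(hidden)
    else:
        w["Wxc"], w["Whc"] = u(n_streams, input_dim, hidden), u(n_streams, hidden, hidden)
        w["bc"] = np.zeros((n_streams, hidden))
    w["bf"] = w["bf"] + 1.0
    w["Wy"] = u(n_streams * hidden, n_classes)
    w["by"] = np.zeros(n_classes)
    return SyncLSTMParams(w, n_streams, shared)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def lstm_cell_forward(x_t: np.ndarray, state_prev: CellState,
                      params: SyncLSTMParams, m: int = 0):
    """Advance one lane one step.  ``x_t`` is (B, D) or (D,).

    Returns the new state and the gate record (i, f, o, g) — every gate
    activation lies strictly in (0, 1) for finite inputs.
    """
    squeeze = x_t.ndim == 1
    x = np.atleast_2d(x_t)
    h_prev = np.atleast_2d(state_prev.h)
    c_prev = np.atleast_2d(state_prev.c)
    Wxi, Whi, wci = params.lane("Wxi", m), params.lane("Whi", m), params.lane("wci", m)
    Wxf, Whf, wcf = params.lane("Wxf", m), params.lane("Whf", m), params.lane("wcf", m)
    Wxo, Who, wco = params.lane("Wxo", m), params.lane("Who", m), params.lane("wco", m)
    Wxc, Whc = params.lane("Wxc", m), params.lane("Whc", m)
    bi, bf, bo, bc = (params.lane(k, m) for k in ("bi", "bf", "bo", "bc"))

    i = _sigmoid(x @ Wxi + h_prev @ Whi + c_prev * wci + bi)
    f = _sigmoid(x @ Wxf + h_prev @ Whf + c_prev * wcf + bf)
    o = _sigmoid(x @ Wxo + h_prev @ Who + c_prev * wco + bo)  # peephole on c_{t-1}
    g = np.tanh(x @ Wxc + h_prev @ Whc + bc)
    c = f * c_prev + i * g
    h = o * np.tanh(c)
    if squeeze:
        h, c, i, f, o, g = (a[0] for a in (h, c, i, f, o, g))
    return CellState(h=h, c=c), {"i": i, "f": f, "o": o, "g": g}


def make_dropout_masks(rng: np.random.Generator, shape: tuple, rate: float) -> np.ndarray:
    """Inverted-scaling dropout multipliers: 0 or 1/(1-rate)."""
    if rate == 0.0:
        return np.ones(shape)
    return (rng.random(shape) >= rate) / (1.0 - rate)


@dataclass
class ForwardCache:
    """Everything the backward pass needs, plus the per-window outputs."""

    probs: np.ndarray            # (B, K)
    logits: np.ndarray           # (B, K)
    merged: np.ndarray           # (B, M*h)
    X: np.ndarray                # (B, M, T, D)
    steps: list                  # per t: dict of per-lane arrays
    dropout_masks: Optional[np.ndarray]
    merge_step: int              # time index whose hidden states were merged
    params: SyncLSTMParams

    def stream_outputs(self) -> np.ndarray:
        """Per-lane, per-step output projections Y_t^m, shape (B, M, T, K).

        Each lane's block of the output head projects that lane's hidden
        state; the blocks of the merged step sum (with the bias) to the
        class logits.
        """
        B, M, T, _ = self.X.shape
        h = self.params.hidden
        Wy = self.params.weights["Wy"]
        out = np.empty((B, M, T, self.params.n_classes))
        for t, step in enumerate(self.steps):
            for m in range(M):
                out[:, m, t] = step["h_used"][:, m] @ Wy[m * h:(m + 1) * h]
        return out


def _softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def sync_forward(X: np.ndarray, params: SyncLSTMParams,
                 dropout_masks: Optional[np.ndarray] = None,
                 literal_output_lag: bool = False) -> ForwardCache:
    """Advance all M lanes in lock-step over the T slots and classify.

    ``X`` is (B, M, T, D) or (M, T, D) for a single window.  Dropout (an
    (B, M, T, h) multiplier array from :func:`make_dropout_masks`) is
    applied to each lane's hidden output at every step — supply it only in
    training mode.  With ``literal_output_lag`` the output head reads the
    hidden states one step before the end of the window.
    """
    if X.ndim == 3:
        X = X[None]
    B, M, T, D = X.shape
    if M != params.n_streams:
        raise ValueError(f"window has {M} streams, params expect {params.n_streams}")
    h_dim = params.hidden
    h = np.zeros((B, M, h_dim))
    c = np.zeros((B, M, h_dim))
    steps = []
    for t in range(T):
        rec = {"i": np.empty_like(h), "f": np.empty_like(h), "o": np.empty_like(h),
               "g": np.empty_like(h), "c_prev": c.copy(), "h_prev": h.copy(),
               "c": np.empty_like(c), "tanh_c": np.empty_like(c),
               "h_used": np.empty_like(h)}
        new_c = np.empty_like(c)
        new_h = np.empty_like(h)
        for m in range(M):
            state, gates = lstm_cell_forward(
                X[:, m, t], CellState(h=h[:, m], c=c[:, m]), params, m)
            for k, v in gates.items():
                rec[k][:, m] = v
            new_c[:, m] = state.c
            new_h[:, m] = state.h
        rec["c"] = new_c
        rec["tanh_c"] = np.tanh(new_c)
        if dropout_masks is not None:
            new_h = new_h * dropout_masks[:, :, t]
        rec["h_used"] = new_h
        steps.append(rec)
        h, c = new_h, new_c
    merge_step = T - 2 if (literal_output_lag and T >= 2) else T - 1
    merged = steps[merge_step]["h_used"].reshape(B, M * h_dim) if T > 0 else \
        np.zeros((B, M * h_dim))
    logits = merged @ params.weights["Wy"] + params.weights["by"]
    probs = _softmax(logits)
    return ForwardCache(probs=probs, logits=logits, merged=merged, X=X,
                        steps=steps, dropout_masks=dropout_masks,
                        merge_step=merge_step, params=params)


def l2_penalty(params: SyncLSTMParams, gamma: float) -> float:
    """Gamma * sum of squared weight entries, biases excluded."""
    if gamma == 0.0:
        return 0.0
    return gamma * float(sum(np.sum(params.weights[k] ** 2) for k in WEIGHT_KEYS))


def loss(probs_or_cache: Union[np.ndarray, ForwardCache], labels: np.ndarray,
         params: SyncLSTMParams, gamma: float = 0.0,
         sample_weights: Optional[np.ndarray] = None) -> float:
    """Weighted mean cross-entropy plus the L2 weight penalty."""
    probs = probs_or_cache.probs if isinstance(probs_or_cache, ForwardCache) \
        else probs_or_cache
    labels = np.asarray(labels, dtype=int)
    if labels.min() < 0 or labels.max() >= probs.shape[1]:
        raise ValueError("label index out of range")
    nll = -np.log(np.clip(probs[np.arange(len(labels)), labels], 1e-300, None))
    if sample_weights is None:
        data_term = float(nll.mean())
    else:
        w = np.asarray(sample_weights, dtype=float)
        data_term = float((w * nll).sum() / w.sum())
    return data_term + l2_penalty(params, gamma)


def bptt_backward(cache: ForwardCache, labels: np.ndarray,
                  gamma: float = 0.0,
                  sample_weights: Optional[np.ndarray] = None
                  ) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Exact gradients of :func:`loss` w.r.t. every parameter and the input.

    Returns ``(grads, dX)``; ``dX`` (same shape as the input) feeds the
    adversarial perturbation.  Checked against central finite differences
    in the test suite.
    """
    params = cache.params
    B, M, T, D = cache.X.shape
    h_dim = params.hidden
    labels = np.asarray(labels, dtype=int)
    K = params.n_classes

    if sample_weights is None:
        w_norm = np.full(B, 1.0 / B)
    else:
        sw = np.asarray(sample_weights, dtype=float)
        w_norm = sw / sw.sum()
    dlogits = cache.probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits *= w_norm[:, None]

    grads = params.zeros_like()
    grads["Wy"] += cache.merged.T @ dlogits
    grads["by"] += dlogits.sum(axis=0)
    dmerged = dlogits @ params.weights["Wy"].T  # (B, M*h)

    dh_used = np.zeros((B, M, h_dim))
    dc = np.zeros((B, M, h_dim))
    dX = np.zeros_like(cache.X)
    for t in range(T - 1, -1, -1):
        rec = cache.steps[t]
        if t == cache.merge_step:
            dh_used = dh_used + dmerged.reshape(B, M, h_dim)
        if cache.dropout_masks is not None:
            dh_raw = dh_used * cache.dropout_masks[:, :, t]
        else:
            dh_raw = dh_used
        i, f, o, g = rec["i"], rec["f"], rec["o"], rec["g"]
        tanh_c, c_prev, h_prev = rec["tanh_c"], rec["c_prev"], rec["h_prev"]
        do = dh_raw * tanh_c
        dc = dc + dh_raw * o * (1.0 - tanh_c ** 2)
        da_o = do * o * (1.0 - o)
        di = dc * g
        dg = dc * i
        df = dc * c_prev
        da_i = di * i * (1.0 - i)
        da_f = df * f * (1.0 - f)
        da_g = dg * (1.0 - g ** 2)
        dh_prev = np.empty_like(dh_used)
        dc_prev = dc * f
        for m in range(M):
            xs, hp = cache.X[:, m, t], h_prev[:, m]
            lanes = ((("Wxi", "Whi", "wci", "bi"), da_i[:, m]),
                     (("Wxf", "Whf", "wcf", "bf"), da_f[:, m]),
                     (("Wxo", "Who", "wco", "bo"), da_o[:, m]),
                     (("Wxc", "Whc", None, "bc"), da_g[:, m]))
            dx_m = np.zeros((B, D))
            dh_m = np.zeros((B, h_dim))
            for (kx, kh, kc, kb), da in lanes:
                if params.shared:
                    grads[kx] += xs.T @ da
                    grads[kh] += hp.T @ da
                    grads[kb] += da.sum(axis=0)
                    if kc is not None:
                        grads[kc] += (da * c_prev[:, m]).sum(axis=0)
                else:
                    grads[kx][m] += xs.T @ da
                    grads[kh][m] += hp.T @ da
                    grads[kb][m] += da.sum(axis=0)
                    if kc is not None:
                        grads[kc][m] += (da * c_prev[:, m]).sum(axis=0)
                dx_m += da @ params.lane(kx, m).T
                dh_m += da @ params.lane(kh, m).T
                if kc is not None:
                    dc_prev[:, m] += da * params.lane(kc, m)
            dX[:, m, t] = dx_m
            dh_prev[:, m] = dh_m
        # the h fed into this step was itself a dropped output of step t-1
        dh_used = dh_prev
        dc = dc_prev
    if gamma != 0.0:
        for k in WEIGHT_KEYS:
            grads[k] += 2.0 * gamma * params.weights[k]
    return grads, dX


def clip_gradients(grads: dict[str, np.ndarray], threshold: float) -> dict[str, np.ndarray]:
    """Global-norm clipping: if ||g||_2 > threshold, scale all entries by
    threshold/||g||; otherwise return the gradients unchanged."""
    if threshold <= 0:
        raise ValueError("clip threshold must be positive")
    sq = sum(float(np.sum(v ** 2)) for v in grads.values())
    norm = math.sqrt(sq)
    if norm <= threshold:
        return grads
    scale = threshold / norm
    return {k: v * scale for k, v in grads.items()}


@dataclass
class AdamState:
    """First/second moment accumulators and the step counter."""

    m: dict[str, np.ndarray]
    v: dict[str, np.ndarray]
    t: int = 0

    @classmethod
    def zeros(cls, params: SyncLSTMParams) -> "AdamState":
        return cls(m=params.zeros_like(), v=params.zeros_like(), t=0)


def adam_step(params: SyncLSTMParams, grads: dict[str, np.ndarray],
              state: AdamState, lr: float,
              config: TrainingConfig) -> tuple[SyncLSTMParams, AdamState]:
    """One bias-corrected Adam update, in place."""
    b1, b2, eps = config.momentum, config.beta2, config.adam_eps
    state.t += 1
    t = state.t
    for k, g in grads.items():
        state.m[k] = b1 * state.m[k] + (1 - b1) * g
        state.v[k] = b2 * state.v[k] + (1 - b2) * g * g
        mhat = state.m[k] / (1 - b1 ** t)
        vhat = state.v[k] / (1 - b2 ** t)
        params.weights[k] -= lr * mhat / (np.sqrt(vhat) + eps)
    return params, state


def predict_proba(X: np.ndarray, params: SyncLSTMParams,
                  literal_output_lag: bool = False,
                  batch_size: int = 256) -> np.ndarray:
    """Inference-mode class probabilities (no dropout), (N, K)."""
    if X.ndim == 3:
        X = X[None]
    out = []
    for lo in range(0, len(X), batch_size):
        cache = sync_forward(X[lo:lo + batch_size], params,
                             literal_output_lag=literal_output_lag)
        out.append(cache.probs)
    return np.concatenate(out) if out else np.zeros((0, params.n_classes))


def predict(X: np.ndarray, params: SyncLSTMParams, **kw) -> np.ndarray:
    return predict_proba(X, params, **kw).argmax(axis=1)


def accuracy(X: np.ndarray, y: np.ndarray, params: SyncLSTMParams, **kw) -> float:
    if len(y) == 0:
        return float("nan")
    return float((predict(X, params, **kw) == y).mean())


def save_params(params: SyncLSTMParams, path: Union[str, Path],
                config: Optional[TrainingConfig] = None) -> None:
    """Checkpoint as an ``.npz`` container beside a JSON manifest."""
    path = Path(path)
    np.savez(path, **params.weights)
    manifest = {
        "n_streams": params.n_streams,
        "shared": params.shared,
        "shapes": {k: list(v.shape) for k, v in params.weights.items()},
    }
    if config is not None:
        manifest["config"] = {k: getattr(config, k) for k in vars(config)}
    path.with_suffix(".json").write_text(json.dumps(manifest, indent=2))


def load_params(path: Union[str, Path]) -> SyncLSTMParams:
    path = Path(path)
    manifest = json.loads(path.with_suffix(".json").read_text())
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        weights = {k: z[k] for k in z.files}
    return SyncLSTMParams(weights, manifest["n_streams"], manifest["shared"])
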