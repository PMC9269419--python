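"""Scaled-down reference experiments on the simulated milan-like home.

These functions pin the package's standard desk-scale study conditions:
two simulated days, 2 s windows on a 60 s hop, 8 slots per window, a
16-unit hidden state and at most 200 training epochs — small enough to run
on one CPU in minutes while exercising the full windowing → adversarial
training → pseudo-labeling stack.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .adversarial import AdversarialConfig, train_adversarial
from .semi_supervised import self_train
from .sync_lstm import TrainingConfig, accuracy
from .synth_home import SimulationConfig, generate, hide_labels
from .windowing import Dataset, EncodingSpec, assign_label, build_dataset, stack_windows

SCALED_DAYS = 2
SCALED_STEP_MS = 60_000
SCALED_T = 8
SCALED_HIDDEN = 16


def scaled_dataset(seed: int, label_fraction: float = 1.0,
                   days: int = SCALED_DAYS) -> Dataset:
    """Simulate, window and split the milan-like home at desk scale.

    With ``label_fraction`` < 1, the hidden segments' windows fall into the
    unlabeled pool and every window additionally remembers its full-truth
    label through the returned dataset's ``truth`` mapping.
    """
    cfg = SimulationConfig(preset="milan_like", days=days, seed=seed)
    log, truth = generate(cfg)
    if label_fraction < 1.0:
        labeled_segments, _ = hide_labels(log, truth, label_fraction,
                                          seed=seed + 1)
    else:
        labeled_segments = truth
    spec = EncodingSpec.from_log(log, T=SCALED_T)
    ds = build_dataset(log, spec, seed=seed, step_ms=SCALED_STEP_MS,
                       segments=labeled_segments)
    # full-truth labels for pool windows, for pseudo-label audits
    ds.truth = {}
    for w in ds.pool.windows:
        label = assign_label(w.window, truth)
        if label is not None and label in spec.activity_vocab:
            ds.truth[w.uid] = spec.activity_vocab.index(label)
    return ds


def training_config(seed: int, epochs: int = 120) -> TrainingConfig:
    return TrainingConfig(hidden=SCALED_HIDDEN, epochs=epochs, seed=seed)


@dataclass
class SupervisedRun:
    seed: int
    test_accuracy: float
    majority_rate: float


def supervised_run(seed: int, epochs: int = 120,
                   adv: AdversarialConfig | None = None) -> SupervisedRun:
    """Adversarially regularized supervised training on fully labeled data."""
    ds = scaled_dataset(seed)
    cfg = training_config(seed, epochs)
    res = train_adversarial(ds.train, cfg,
                            adv or AdversarialConfig(epsilon=0.05),
                            continuous_mask=ds.spec.continuous_mask())
    Xt, yt = stack_windows(ds.test)
    y_train = np.array([w.label_index for w in ds.train])
    return SupervisedRun(seed=seed,
                         test_accuracy=accuracy(Xt, yt, res.params),
                         majority_rate=float(np.bincount(y_train).max()
                                             / len(y_train)))


@dataclass
class SelfTrainComparison:
    seed: int
    baseline_accuracy: float       # supervised-only on the labeled fraction
    selftrain_accuracy: float
    n_accepted: int
    pseudo_label_error_rate: float


def selftrain_comparison(seed: int, label_fraction: float = 0.10,
                         epochs: int = 60, threshold: float = 0.95,
                         rounds: int = 2) -> SelfTrainComparison:
    """Paired comparison: supervised-only vs pseudo-label self-training on
    a sparsely labeled simulation, on the shared test split."""
    ds = scaled_dataset(seed, label_fraction=label_fraction)
    cfg = training_config(seed, epochs)
    adv = AdversarialConfig(epsilon=0.05)
    mask = ds.spec.continuous_mask()
    Xt, yt = stack_windows(ds.test)
    base = train_adversarial(ds.train, cfg, adv, continuous_mask=mask)
    st = self_train(ds.train, ds.pool, cfg, adv, threshold=threshold,
                    rounds=rounds, continuous_mask=mask)
    return SelfTrainComparison(
        seed=seed,
        baseline_accuracy=accuracy(Xt, yt, base.params),
        selftrain_accuracy=accuracy(Xt, yt, st.params),
        n_accepted=len(st.audit_trail),
        pseudo_label_error_rate=st.pseudo_label_error_rate(ds.truth))
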