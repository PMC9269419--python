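"""Sliding-window segmentation and multi-stream window encoding.

An event log is cut into overlapping fixed-length windows on a regular
start grid (default hop 200 ms).  Each window is then encoded into M
parallel feature streams consumed simultaneously by the synchronized
recurrent network:

* the **S stream** one-hot encodes the sensor id of each event slot,
* the **V stream** carries the sensor value (binary tokens map to {1, 0},
  numeric values are min–max scaled to [0, 1] with bounds frozen on the
  training split),
* the **P stream** one-hot encodes the sensor's room.

Events fill the first slots of every stream in time order; the remaining
slots of the T-slot grid are zero padding.  The three streams share a
common feature width (the widest channel, zero-padded) so that gate
weights can be shared across streams.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .io_events import ActivitySegment, EventLog, SensorEvent

#: admissible window lengths in seconds
MIN_WINDOW_S = 0.25
MAX_WINDOW_S = 7.0
DEFAULT_STEP_MS = 200
DEFAULT_WINDOW_S = 2.0
DEFAULT_TIME_STEPS = 128

UNLABELED = None


class ConfigurationError(ValueError):
    pass


class EncodingError(ValueError):
    pass


@dataclass(frozen=True)
class Window:
    """Events within the half-open interval [I, F)."""

    I: int
    F: int
    events: tuple[SensorEvent, ...]
    label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.I < self.F:
            raise ValueError("window must have positive duration")

    @property
    def duration(self) -> int:
        return self.F - self.I


@dataclass
class EncodingSpec:
    """Vocabularies and shapes fixing the window → tensor mapping.

    ``mode="svp"`` (default) uses M = 3 streams keyed to the sensor-id,
    value and location channels.  ``mode="per_room"`` uses one stream per
    room, each carrying only that room's events as [sensor one-hot, value]
    vectors (location implicit in the stream index).
    """

    sensor_vocab: list[str]
    location_vocab: list[str]
    activity_vocab: list[str]
    T: int = DEFAULT_TIME_STEPS
    mode: str = "svp"
    value_bounds: Optional[tuple[float, float]] = None  # numeric min-max, train split only
    padding: str = "zero"

    def __post_init__(self) -> None:
        if self.T < 1:
            raise ConfigurationError("T must be >= 1")
        if self.mode not in ("svp", "per_room"):
            raise ConfigurationError(f"unknown encoding mode {self.mode!r}")
        for name, vocab in (("sensor", self.sensor_vocab),
                            ("location", self.location_vocab),
                            ("activity", self.activity_vocab)):
            if len(set(vocab)) != len(vocab):
                raise ConfigurationError(f"duplicate tokens in {name} vocabulary")

    @property
    def s_dim(self) -> int:
        return len(self.sensor_vocab)

    @property
    def p_dim(self) -> int:
        return len(self.location_vocab)

    @property
    def M(self) -> int:
        return 3 if self.mode == "svp" else self.p_dim

    @property
    def input_dim(self) -> int:
        """Common per-slot feature width shared by all streams."""
        if self.mode == "svp":
            return max(self.s_dim, 1, self.p_dim)
        return self.s_dim + 1

    @property
    def n_classes(self) -> int:
        return len(self.activity_vocab)

    def continuous_mask(self) -> np.ndarray:
        """(M, input_dim) boolean mask, True on continuous (value) positions.

        One-hot sensor/location blocks are discrete; only value positions
        are continuous.  Used to confine adversarial perturbations to
        positions where an additive offset is meaningful.
        """
        mask = np.zeros((self.M, self.input_dim), dtype=bool)
        if self.mode == "svp":
            mask[1, 0] = True
        else:
            mask[:, self.s_dim] = True
        return mask

    @classmethod
    def from_log(cls, log: EventLog, T: int = DEFAULT_TIME_STEPS,
                 value_events: Optional[Sequence[SensorEvent]] = None) -> "EncodingSpec":
        """Build vocabularies from a log; numeric bounds from ``value_events``
        (pass the training-split events to avoid test leakage)."""
        sensors = sorted(log.sensor_inventory)
        locations = sorted({loc for _, loc in log.sensor_inventory.values()})
        spec = cls(sensor_vocab=sensors, location_vocab=locations,
                   activity_vocab=list(log.activity_vocabulary), T=T)
        if value_events is not None:
            spec.fit_value_bounds(value_events)
        return spec

    def fit_value_bounds(self, events: Sequence[SensorEvent]) -> None:
        numeric = [e.value for e in events if not e.is_binary]
        if numeric:
            lo, hi = min(numeric), max(numeric)
            self.value_bounds = (float(lo), float(hi) if hi > lo else float(lo) + 1.0)
        else:
            self.value_bounds = (0.0, 1.0)


@dataclass
class EncodedWindow:
    """The (M, T, D) multi-stream tensor for one window plus bookkeeping."""

    streams: np.ndarray  # (M, T, input_dim)
    label_index: Optional[int]
    window: Window
    n_truncated: int = 0
    uid: int = -1

    @property
    def n_events(self) -> int:
        return min(len(self.window.events), self.streams.shape[1])


def slide_windows(log: EventLog, length_s: float = DEFAULT_WINDOW_S,
                  step_ms: int = DEFAULT_STEP_MS,
                  include_empty: bool = False) -> list[Window]:
    """Cut the log into overlapping windows on the start grid I0 + k·step.

    Window length must lie in the admissible [0.25, 7] s range; windows
    containing no events are omitted unless ``include_empty``.
    """
    if not MIN_WINDOW_S <= length_s <= MAX_WINDOW_S:
        raise ConfigurationError(
            f"window length {length_s} s outside admissible range "
            f"[{MIN_WINDOW_S}, {MAX_WINDOW_S}] s")
    if step_ms < 1:
        raise ConfigurationError("step must be >= 1 ms")
    if not log.events:
        return []
    length_ms = int(round(length_s * 1000))
    t0 = log.events[0].timestamp
    t_last = log.events[-1].timestamp
    times = np.array([e.timestamp for e in log.events])
    windows: list[Window] = []
    start = t0
    while start + length_ms <= t_last + 1:
        lo = int(np.searchsorted(times, start, side="left"))
        hi = int(np.searchsorted(times, start + length_ms, side="left"))
        if hi > lo or include_empty:
            windows.append(Window(start, start + length_ms, tuple(log.events[lo:hi])))
        start += step_ms
    return windows


def assign_label(window: Window, segments: Sequence[ActivitySegment],
                 policy: str = "majority_overlap") -> Optional[str]:
    """Label a window from disjoint ground-truth segments.

    ``majority_overlap``: the label whose segment overlaps the window
    longest, ties broken toward the earlier-starting segment; no overlap →
    unlabeled.  ``strict_containment``: labeled only when the window lies
    entirely inside one segment.
    """
    if policy == "majority_overlap":
        best: tuple[int, int] = (0, 0)  # (-overlap, start) minimised
        best_label = UNLABELED
        for seg in segments:
            overlap = min(window.F, seg.end) - max(window.I, seg.start)
            if overlap <= 0:
                continue
            key = (-overlap, seg.start)
            if best_label is UNLABELED or key < best:
                best, best_label = key, seg.label
        return best_label
    if policy == "strict_containment":
        for seg in segments:
            if seg.start <= window.I and window.F <= seg.end:
                return seg.label
        return UNLABELED
    raise ValueError(f"unknown policy {policy!r}")


def encode(window: Window, spec: EncodingSpec) -> EncodedWindow:
    """Encode a window as the (M, T, D) stream tensor.

    Events beyond the T slots are truncated oldest-first (the most recent
    T events are kept); the truncation count is recorded.
    """
    D = spec.input_dim
    x = np.zeros((spec.M, spec.T, D))
    events = window.events
    n_truncated = max(0, len(events) - spec.T)
    events = events[n_truncated:]
    lo, hi = spec.value_bounds if spec.value_bounds else (0.0, 1.0)
    room_slots = [0] * spec.M  # next free slot per stream, per_room mode
    for slot, ev in enumerate(events):
        try:
            s_idx = spec.sensor_vocab.index(ev.sensor_id)
        except ValueError:
            raise EncodingError(f"sensor {ev.sensor_id!r} not in vocabulary") from None
        try:
            p_idx = spec.location_vocab.index(ev.location)
        except ValueError:
            raise EncodingError(f"location {ev.location!r} not in vocabulary") from None
        if ev.is_binary:
            v = 1.0 if ev.value in ("ON", "OPEN") else 0.0
        else:
            v = float(np.clip((ev.value - lo) / (hi - lo), 0.0, 1.0))
        if spec.mode == "svp":
            x[0, slot, s_idx] = 1.0
            x[1, slot, 0] = v
            x[2, slot, p_idx] = 1.0
        else:
            s = room_slots[p_idx]
            if s < spec.T:
                x[p_idx, s, s_idx] = 1.0
                x[p_idx, s, spec.s_dim] = v
                room_slots[p_idx] += 1
    label_index = None
    if window.label is not None:
        try:
            label_index = spec.activity_vocab.index(window.label)
        except ValueError:
            raise EncodingError(f"activity {window.label!r} not in vocabulary") from None
    return EncodedWindow(streams=x, label_index=label_index, window=window,
                         n_truncated=n_truncated)


@dataclass
class UnlabeledPool:
    """Encoded windows lacking labels, keyed by provenance id."""

    windows: list[EncodedWindow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def ids(self) -> set[int]:
        return {w.uid for w in self.windows}


@dataclass
class Dataset:
    """Train/val/test splits of labeled windows plus the unlabeled pool."""

    train: list[EncodedWindow]
    val: list[EncodedWindow]
    test: list[EncodedWindow]
    pool: UnlabeledPool
    spec: EncodingSpec
    warnings: list[str] = field(default_factory=list)
    truth: dict[int, int] = field(default_factory=dict)  # uid -> held-out label


def split_counts(n: int, fractions: tuple[float, float, float]) -> tuple[int, int, int]:
    """Floor/remainder rule: floor(n·f_train), floor(n·f_val), rest to test."""
    n_train = math.floor(n * fractions[0])
    n_val = math.floor(n * fractions[1])
    return n_train, n_val, n - n_train - n_val


def build_dataset(log: EventLog, spec: EncodingSpec,
                  split: tuple[float, float, float] = (0.70, 0.10, 0.20),
                  seed: int = 0,
                  segments: Optional[Sequence[ActivitySegment]] = None,
                  length_s: float = DEFAULT_WINDOW_S,
                  step_ms: int = DEFAULT_STEP_MS,
                  label_policy: str = "majority_overlap") -> Dataset:
    """Window, label, encode and split a log.

    Labeled windows are shuffled deterministically by ``seed`` and divided
    by the floor/remainder rule; unlabeled windows go to the pool.  When a
    class would be absent from the training split, one of its members is
    swapped in from val/test (warning recorded when even that is
    impossible).  Numeric value bounds are fitted on the training split
    only, then used to encode every window.
    """
    if abs(sum(split) - 1.0) > 1e-9:
        raise ConfigurationError("split fractions must sum to 1")
    if segments is None:
        from .io_events import extract_segments
        has_markers = any(e.marker is not None for e in log.events)
        segments = extract_segments(
            log, "begin_end_markers" if has_markers else "label_runs").segments
    windows = slide_windows(log, length_s=length_s, step_ms=step_ms)
    labeled: list[Window] = []
    unlabeled: list[Window] = []
    for w in windows:
        label = assign_label(w, segments, policy=label_policy)
        (labeled if label is not None else unlabeled).append(
            Window(w.I, w.F, w.events, label))

    rng = np.random.default_rng(seed)
    order = rng.permutation(len(labeled))
    n_train, n_val, _ = split_counts(len(labeled), split)
    assignment = np.full(len(labeled), 2)  # 0 train, 1 val, 2 test
    assignment[order[:n_train]] = 0
    assignment[order[n_train:n_train + n_val]] = 1

    warnings: list[str] = []
    labels = [w.label for w in labeled]
    for cls in dict.fromkeys(labels):  # preserve first-seen order
        members = [i for i, l in enumerate(labels) if l == cls]
        if not any(assignment[i] == 0 for i in members):
            movable = [i for i in members if assignment[i] != 0]
            if movable and n_train > 0:
                assignment[movable[0]] = 0
            else:
                warnings.append(f"class {cls!r} absent from training split")

    # bounds from training-split events only
    if spec.value_bounds is None:
        train_events = [e for i, w in enumerate(labeled) if assignment[i] == 0
                        for e in w.events]
        spec.fit_value_bounds(train_events)

    splits: tuple[list, list, list] = ([], [], [])
    uid = 0
    for i, w in enumerate(labeled):
        ew = encode(w, spec)
        ew.uid = uid
        uid += 1
        splits[int(assignment[i])].append(ew)
    pool_windows = []
    for w in unlabeled:
        ew = encode(w, spec)
        ew.uid = uid
        uid += 1
        pool_windows.append(ew)
    return Dataset(train=splits[0], val=splits[1], test=splits[2],
                   pool=UnlabeledPool(pool_windows), spec=spec, warnings=warnings)


def stack_windows(windows: Sequence[EncodedWindow]) -> tuple[np.ndarray, np.ndarray]:
    """Stack encoded windows into (N, M, T, D) inputs and (N,) label indices
    (label −1 for unlabeled)."""
    X = np.stack([w.streams for w in windows])
    y = np.array([w.label_index if w.label_index is not None else -1
                  for w in windows], dtype=int)
    return X, y
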