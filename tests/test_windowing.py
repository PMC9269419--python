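"""Sliding windows, label assignment, multi-stream encoding and splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synchar.io_events import ActivitySegment, SensorEvent, read_event_log
from synchar.windowing import (ConfigurationError, EncodingError, EncodingSpec,
                               Window, assign_label, build_dataset, encode,
                               slide_windows, split_counts, stack_windows)


def _log_with_events_at(times_ms, sensor="M001"):
    lines = []
    for t in times_ms:
        s, ms = divmod(t, 1000)
        lines.append(f"2010-01-01 00:00:{s:02d}.{ms:03d} {sensor} ON\n")
    return read_event_log("".join(lines))


class TestSlideWindows:
    def test_grid_enumeration_oracle(self):
        """Exhaustive enumeration: 1.0 s span, 0.5 s length, 200 ms hop
        puts window starts at 0, 200 and 400 ms."""
        log = _log_with_events_at([0, 250, 500, 750, 1000])
        t0 = log.events[0].timestamp
        ws = slide_windows(log, length_s=0.5, step_ms=200)
        assert [w.I - t0 for w in ws] == [0, 200, 400]
        assert all(w.duration == 500 for w in ws)

    def test_empty_log(self):
        assert slide_windows(read_event_log("")) == []

    def test_events_respect_half_open_interval(self):
        log = _log_with_events_at([0, 499, 500])
        ws = slide_windows(log, length_s=0.5, step_ms=500)
        assert [e.timestamp - log.events[0].timestamp for e in ws[0].events] == [0, 499]

    def test_length_outside_admissible_range_rejected(self):
        log = _log_with_events_at([0, 1000])
        for bad in (0.1, 7.5):
            with pytest.raises(ConfigurationError, match="0.25"):
                slide_windows(log, length_s=bad)

    def test_empty_windows_omitted_by_default(self):
        log = _log_with_events_at([0, 5000])
        ws = slide_windows(log, length_s=1.0, step_ms=1000)
        assert all(w.events for w in ws)
        assert len(slide_windows(log, length_s=1.0, step_ms=1000,
                                 include_empty=True)) > len(ws)

    @settings(deadline=None, max_examples=25)
    @given(length=st.sampled_from([0.25, 0.5, 1.0, 2.0, 4.0, 7.0]))
    def test_window_count_monotone_in_length(self, length):
        """Fewer (or equal) start positions fit as the length grows."""
        log = _log_with_events_at(list(range(0, 8000, 400)))
        n = len(slide_windows(log, length_s=length, include_empty=True))
        n_longer = len(slide_windows(log, length_s=7.0, include_empty=True))
        assert n_longer <= n


class TestAssignLabel:
    SEGS = [ActivitySegment(0, 600, "A"), ActivitySegment(600, 1000, "B")]

    def _window(self, i, f):
        return Window(i, f, ())

    def test_window_inside_one_segment(self):
        assert assign_label(self._window(100, 400), self.SEGS) == "A"

    def test_majority_overlap_hand_computed(self):
        # [300, 800): 300 ms in A, 200 ms in B -> A
        assert assign_label(self._window(300, 800), self.SEGS) == "A"
        # [500, 900): 100 ms in A, 300 ms in B -> B
        assert assign_label(self._window(500, 900), self.SEGS) == "B"

    def test_tie_broken_toward_earlier_segment(self):
        assert assign_label(self._window(400, 800), self.SEGS) == "A"

    def test_no_overlap_unlabeled(self):
        assert assign_label(self._window(2000, 2500), self.SEGS) is None

    def test_strict_containment(self):
        assert assign_label(self._window(100, 400), self.SEGS,
                            "strict_containment") == "A"
        assert assign_label(self._window(400, 800), self.SEGS,
                            "strict_containment") is None


class TestEncode:
    def _spec(self, T=4):
        return EncodingSpec(sensor_vocab=["M001", "M002"],
                            location_vocab=["bath", "kitchen"],
                            activity_vocab=["Cook"], T=T,
                            value_bounds=(10.0, 30.0))

    def test_empty_window_all_zero(self):
        ew = encode(Window(0, 1000, ()), self._spec())
        assert ew.streams.shape == (3, 4, 2)
        assert not ew.streams.any()

    def test_two_event_window_hand_indices(self):
        """Hand index computation over the 2x2 vocabularies."""
        events = (SensorEvent(10, "M001", "ON", "kitchen"),
                  SensorEvent(20, "M002", 20.0, "bath"))
        ew = encode(Window(0, 1000, events, label="Cook"), self._spec())
        x = ew.streams
        assert x[0, 0, 0] == 1.0 and x[0, 1, 1] == 1.0   # sensor one-hots
        assert x[1, 0, 0] == 1.0                          # ON -> 1
        assert x[1, 1, 0] == pytest.approx(0.5)           # (20-10)/(30-10)
        assert x[2, 0, 1] == 1.0 and x[2, 1, 0] == 1.0    # location one-hots
        assert x[:, 2:, :].sum() == 0                     # padding slots
        assert ew.label_index == 0

    def test_one_hot_blocks_sum_to_one_on_active_slots(self):
        events = tuple(SensorEvent(i, "M001", "ON", "bath") for i in range(3))
        x = encode(Window(0, 10, events), self._spec()).streams
        assert np.array_equal(x[0].sum(axis=1), [1, 1, 1, 0])
        assert np.array_equal(x[2].sum(axis=1), [1, 1, 1, 0])

    def test_three_parallel_streams_by_default(self):
        assert self._spec().M == 3

    def test_truncation_keeps_newest_events(self):
        events = tuple(SensorEvent(i, "M001" if i < 4 else "M002", "ON", "bath")
                       for i in range(6))
        ew = encode(Window(0, 10, events), self._spec(T=4))
        assert ew.n_truncated == 2
        # oldest two dropped: slots now start at event index 2
        assert ew.streams[0, 2, 1] == 1.0  # M002 at slot 2 (event index 4)

    def test_unknown_token_raises_naming_it(self):
        ev = (SensorEvent(0, "M999", "ON", "bath"),)
        with pytest.raises(EncodingError, match="M999"):
            encode(Window(0, 10, ev), self._spec())

    def test_injective_on_differing_retained_tokens(self):
        spec = self._spec()
        a = encode(Window(0, 10, (SensorEvent(1, "M001", "ON", "bath"),)), spec)
        b = encode(Window(0, 10, (SensorEvent(1, "M002", "ON", "bath"),)), spec)
        assert not np.array_equal(a.streams, b.streams)

    def test_per_room_mode_routes_by_location(self):
        spec = self._spec()
        spec.mode = "per_room"
        events = (SensorEvent(10, "M001", "ON", "kitchen"),
                  SensorEvent(20, "M002", "ON", "bath"))
        x = encode(Window(0, 1000, events), spec).streams
        assert x.shape == (2, 4, 3)   # one stream per room, [S one-hot, V]
        assert x[1, 0, 0] == 1.0      # kitchen stream slot 0: M001
        assert x[0, 0, 1] == 1.0      # bath stream slot 0: M002


class TestBuildDataset:
    def test_split_counting_rule(self):
        assert split_counts(100, (0.70, 0.10, 0.20)) == (70, 10, 20)
        assert split_counts(10, (0.70, 0.10, 0.20)) == (7, 1, 2)
        assert split_counts(9, (0.70, 0.10, 0.20)) == (6, 0, 3)

    def test_default_split_fractions_70_10_20(self, milan_dataset):
        n = sum(map(len, (milan_dataset.train, milan_dataset.val,
                          milan_dataset.test)))
        assert len(milan_dataset.train) == int(np.floor(0.7 * n))
        assert len(milan_dataset.val) == int(np.floor(0.1 * n))

    def test_deterministic_given_seed(self, milan_sim):
        log, segments = milan_sim
        kw = dict(seed=11, step_ms=60_000, segments=segments)
        a = build_dataset(log, EncodingSpec.from_log(log, T=8), **kw)
        b = build_dataset(log, EncodingSpec.from_log(log, T=8), **kw)
        assert [w.uid for w in a.train] == [w.uid for w in b.train]
        assert all(np.array_equal(x.streams, y.streams)
                   for x, y in zip(a.train, b.train))

    def test_split_is_partition(self, milan_dataset):
        ids = [w.uid for part in (milan_dataset.train, milan_dataset.val,
                                  milan_dataset.test) for w in part]
        assert len(ids) == len(set(ids))

    def test_every_class_present_in_train(self, milan_dataset):
        train_classes = {w.label_index for w in milan_dataset.train}
        all_classes = train_classes | {w.label_index for w in milan_dataset.test}
        assert train_classes == all_classes
        assert milan_dataset.warnings == []

    def test_value_bounds_fitted_from_train_split_only(self, milan_dataset):
        lo, hi = milan_dataset.spec.value_bounds
        train_numeric = [e.value for w in milan_dataset.train
                         for e in w.window.events if not e.is_binary]
        assert lo == min(train_numeric) and hi == max(train_numeric)


def test_stack_windows_shapes(milan_dataset):
    X, y = stack_windows(milan_dataset.train[:5])
    assert X.shape[0] == 5 and X.ndim == 4
    assert y.shape == (5,) and (y >= 0).all()
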