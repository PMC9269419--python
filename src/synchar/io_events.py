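"""Reading, writing and segmenting ambient smart-home sensor event logs.

Two text dialects are supported:

* ``casas`` — one whitespace-delimited event per line::

      2010-01-04 08:00:01.123 M003 ON [Kitchen_Activity [begin|end]]

  Dates and times are ISO-like; the optional trailing fields carry an
  activity annotation, either a plain label or a label with a ``begin`` /
  ``end`` marker.

* ``kasteren`` — the sensor readings and the activity annotations live in
  separate tables.  Because this reader takes a single stream, the two
  tables are carried in one file under ``# sensors`` and ``# annotations``
  section headers; annotation rows are ``start<TAB>end<TAB>label`` with the
  same timestamp syntax.  On read, each event falling inside an annotation
  interval receives that interval's label as a plain (marker-less)
  annotation.

Raw CASAS lines do not carry the sensor's room, yet every downstream
encoding needs a location channel, so a two-column sensor map
(``sensor_id<TAB>room``) may be supplied; unmapped sensors get location
``"unknown"``.

Timestamps are integer milliseconds since the Unix epoch (UTC); finer text
precision is truncated.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Iterator, Mapping, Optional, Sequence, TextIO, Union

logger = logging.getLogger(__name__)

BINARY_TOKENS = ("ON", "OFF", "OPEN", "CLOSE")
#: binary tokens mapping to the active state
ACTIVE_TOKENS = frozenset({"ON", "OPEN"})

_EPOCH = datetime(1970, 1, 1, tzinfo=timezone.utc)


class DialectError(ValueError):
    """Unsupported or malformed dialect input."""


def parse_timestamp(date_tok: str, time_tok: str) -> int:
    """Parse ``DATE TIME`` tokens to integer milliseconds since the epoch.

    Sub-millisecond digits are truncated.
    """
    dt = datetime.fromisoformat(f"{date_tok} {time_tok}")
    dt = dt.replace(tzinfo=timezone.utc)
    micros = (dt - _EPOCH) // _resolution
    return micros // 1000


_resolution = datetime.resolution  # 1 microsecond


def format_timestamp(ms: int) -> str:
    """Inverse of :func:`parse_timestamp` at millisecond precision."""
    dt = _EPOCH + (ms * 1000) * _resolution
    return dt.strftime("%Y-%m-%d %H:%M:%S.") + f"{ms % 1000:03d}"


@dataclass(frozen=True)
class SensorEvent:
    """One timestamped sensor reading with an optional activity annotation."""

    timestamp: int
    sensor_id: str
    value: Union[str, float]
    location: str = "unknown"
    annotation: Optional[str] = None
    marker: Optional[str] = None  # "begin" | "end" | None

    def __post_init__(self) -> None:
        if self.timestamp < 0:
            raise ValueError(f"negative timestamp {self.timestamp}")
        if isinstance(self.value, str) and self.value not in BINARY_TOKENS:
            raise ValueError(f"non-binary string value {self.value!r}")
        if self.marker not in (None, "begin", "end"):
            raise ValueError(f"bad marker {self.marker!r}")

    @property
    def is_binary(self) -> bool:
        return isinstance(self.value, str)


@dataclass
class EventLog:
    """An ordered event sequence plus the sensor and activity inventories."""

    events: list[SensorEvent] = field(default_factory=list)
    sensor_inventory: dict[str, tuple[str, str]] = field(default_factory=dict)
    activity_vocabulary: list[str] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[SensorEvent]:
        return iter(self.events)

    def validate(self) -> None:
        prev = -1
        for ev in self.events:
            if ev.timestamp < prev:
                raise ValueError("events not sorted by timestamp")
            prev = ev.timestamp
            if ev.sensor_id not in self.sensor_inventory:
                raise ValueError(f"sensor {ev.sensor_id} missing from inventory")
            if ev.annotation is not None and ev.annotation not in self.activity_vocabulary:
                raise ValueError(f"activity {ev.annotation} missing from vocabulary")


@dataclass(frozen=True)
class ActivitySegment:
    """A half-open ground-truth interval [start, end) carrying one activity."""

    start: int
    end: int
    label: str

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty segment [{self.start}, {self.end})")

    @property
    def duration(self) -> int:
        return self.end - self.start

    def contains(self, ts: int) -> bool:
        return self.start <= ts < self.end


@dataclass
class SegmentExtraction(Sequence):
    """Result of :func:`extract_segments`: ordered disjoint segments plus a
    counter of annotation irregularities (dangling begins, orphan ends)."""

    segments: list[ActivitySegment]
    warnings: int = 0

    def __len__(self) -> int:
        return len(self.segments)

    def __getitem__(self, i):
        return self.segments[i]


@dataclass
class Summary:
    n_sensors: int
    n_activities: int
    n_events: int
    span_days: float


def _infer_type(value: Union[str, float]) -> str:
    if isinstance(value, str):
        return "door" if value in ("OPEN", "CLOSE") else "motion"
    return "temperature"


def _parse_value(tok: str) -> Union[str, float]:
    if tok in BINARY_TOKENS:
        return tok
    v = float(tok)  # may raise ValueError for malformed lines
    if v != v or v in (float("inf"), float("-inf")):
        raise ValueError(f"non-finite value {tok}")
    return v


def read_sensor_map(source: TextIO) -> dict[str, str]:
    """Read a two-column ``sensor_id<TAB>room`` map."""
    out: dict[str, str] = {}
    for line in source:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        sid, room = line.split("\t")
        out[sid] = room
    return out


def _finalize(events: list[SensorEvent], sensor_map: Optional[Mapping[str, str]],
              n_malformed: int, name: str) -> EventLog:
    # stable sort preserves file order among equal timestamps
    events.sort(key=lambda e: e.timestamp)
    inventory: dict[str, tuple[str, str]] = {}
    vocab: list[str] = []
    for ev in events:
        if ev.sensor_id not in inventory:
            loc = ev.location
            if sensor_map and ev.sensor_id in sensor_map:
                loc = sensor_map[ev.sensor_id]
            inventory[ev.sensor_id] = (_infer_type(ev.value), loc)
        if ev.annotation is not None and ev.annotation not in vocab:
            vocab.append(ev.annotation)
    if sensor_map:
        events = [
            replace(ev, location=sensor_map.get(ev.sensor_id, ev.location))
            for ev in events
        ]
    span = (events[-1].timestamp - events[0].timestamp) / 86_400_000.0 if events else 0.0
    return EventLog(
        events=events,
        sensor_inventory=inventory,
        activity_vocabulary=vocab,
        metadata={"name": name, "span_days": span, "n_malformed": n_malformed},
    )


def _read_casas(source: Iterable[str]) -> tuple[list[SensorEvent], int]:
    events: list[SensorEvent] = []
    n_malformed = 0
    for lineno, line in enumerate(source, 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        toks = line.split()
        try:
            if len(toks) < 4:
                raise ValueError("fewer than 4 fields")
            ts = parse_timestamp(toks[0], toks[1])
            value = _parse_value(toks[3])
            annotation = toks[4] if len(toks) > 4 else None
            marker = toks[5] if len(toks) > 5 else None
            events.append(SensorEvent(ts, toks[2], value, annotation=annotation,
                                      marker=marker))
        except ValueError as exc:
            n_malformed += 1
            logger.warning("line %d rejected: %s", lineno, exc)
    return events, n_malformed


def _read_kasteren(source: Iterable[str]) -> tuple[list[SensorEvent], int]:
    events: list[SensorEvent] = []
    annotations: list[ActivitySegment] = []
    n_malformed = 0
    section = "sensors"
    for lineno, line in enumerate(source, 1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            head = line.lstrip("#").strip().lower()
            if head in ("sensors", "annotations"):
                section = head
            continue
        toks = line.split("\t")
        try:
            if section == "sensors":
                date_t, time_t = toks[0].split(" ")
                ts = parse_timestamp(date_t, time_t)
                events.append(SensorEvent(ts, toks[1], _parse_value(toks[2])))
            else:
                d0, t0 = toks[0].split(" ")
                d1, t1 = toks[1].split(" ")
                annotations.append(
                    ActivitySegment(parse_timestamp(d0, t0), parse_timestamp(d1, t1), toks[2])
                )
        except (ValueError, IndexError) as exc:
            n_malformed += 1
            logger.warning("line %d rejected: %s", lineno, exc)
    # materialise interval annotations as plain per-event labels
    labeled = []
    for ev in events:
        label = next((seg.label for seg in annotations if seg.contains(ev.timestamp)), None)
        labeled.append(replace(ev, annotation=label) if label else ev)
    return labeled, n_malformed


def read_event_log(source: Union[str, TextIO], dialect: str = "casas",
                   sensor_map: Optional[Mapping[str, str]] = None,
                   name: str = "") -> EventLog:
    """Parse a text event log.

    Malformed lines are counted in ``metadata["n_malformed"]`` and logged,
    never fatal.  Events are stably sorted by timestamp after reading.
    """
    if isinstance(source, str):
        source = io.StringIO(source)
    if dialect == "casas":
        events, bad = _read_casas(source)
    elif dialect == "kasteren":
        events, bad = _read_kasteren(source)
    else:
        raise DialectError(f"unsupported dialect {dialect!r}")
    return _finalize(events, sensor_map, bad, name)


def _format_value(value: Union[str, float]) -> str:
    return value if isinstance(value, str) else repr(value)


def write_event_log(log: EventLog, dialect: str = "casas",
                    sink: Optional[TextIO] = None) -> str:
    """Serialize a log; ``read_event_log(write_event_log(log))`` round-trips
    field-for-field and the output is byte-stable across calls."""
    buf = io.StringIO()
    if dialect == "casas":
        for ev in log.events:
            parts = [format_timestamp(ev.timestamp), ev.sensor_id, _format_value(ev.value)]
            if ev.annotation is not None:
                parts.append(ev.annotation)
                if ev.marker is not None:
                    parts.append(ev.marker)
            buf.write("\t".join([f"{parts[0]}"] + parts[1:]) + "\n")
    elif dialect == "kasteren":
        buf.write("# sensors\n")
        for ev in log.events:
            buf.write(f"{format_timestamp(ev.timestamp)}\t{ev.sensor_id}\t"
                      f"{_format_value(ev.value)}\n")
        buf.write("# annotations\n")
        for seg in extract_segments(log, policy="label_runs"):
            buf.write(f"{format_timestamp(seg.start)}\t{format_timestamp(seg.end)}\t"
                      f"{seg.label}\n")
    else:
        raise DialectError(f"unsupported dialect {dialect!r}")
    text = buf.getvalue()
    if sink is not None:
        sink.write(text)
    return text


def extract_segments(log: EventLog, policy: str = "begin_end_markers") -> SegmentExtraction:
    """Extract disjoint ground-truth activity segments from annotations.

    ``begin_end_markers`` pairs CASAS-style begin/end marks; a begin without
    a matching end closes at the last event (warning counted), an orphan end
    is dropped (warning counted).  ``label_runs`` groups maximal runs of
    identically plain-labeled events.  Segment ends are exclusive: the
    closing event's timestamp + 1 ms, so every annotated event lies inside
    exactly one segment.
    """
    segments: list[ActivitySegment] = []
    warnings = 0
    if policy == "begin_end_markers":
        open_label: Optional[str] = None
        open_start = 0
        for ev in log.events:
            if ev.marker == "begin":
                if open_label is not None:
                    # previous activity never closed: truncate it here
                    warnings += 1
                    if open_start < ev.timestamp:
                        segments.append(ActivitySegment(open_start, ev.timestamp, open_label))
                open_label, open_start = ev.annotation, ev.timestamp
            elif ev.marker == "end":
                if open_label is None or ev.annotation != open_label:
                    warnings += 1
                    continue
                segments.append(ActivitySegment(open_start, ev.timestamp + 1, open_label))
                open_label = None
        if open_label is not None and log.events:
            warnings += 1
            last = log.events[-1].timestamp
            segments.append(ActivitySegment(open_start, max(last + 1, open_start + 1), open_label))
    elif policy == "label_runs":
        run_label: Optional[str] = None
        run_start = run_last = 0
        for ev in log.events:
            if ev.annotation != run_label:
                if run_label is not None:
                    segments.append(ActivitySegment(run_start, run_last + 1, run_label))
                run_label = ev.annotation
                run_start = ev.timestamp
            run_last = ev.timestamp
        if run_label is not None:
            segments.append(ActivitySegment(run_start, run_last + 1, run_label))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    segments.sort(key=lambda s: s.start)
    return SegmentExtraction(segments, warnings)


def summarize(log: EventLog) -> Summary:
    """Dataset-card style counts: sensors, activities, events, span in days."""
    if not log.events:
        return Summary(0, 0, 0, 0.0)
    span = (log.events[-1].timestamp - log.events[0].timestamp) / 86_400_000.0
    return Summary(
        n_sensors=len(log.sensor_inventory),
        n_activities=len(log.activity_vocabulary),
        n_events=len(log.events),
        span_days=span,
    )
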