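"""Seeded semi-Markov smart-home simulator.

Generates single-resident ambient-sensor event logs with ground-truth
activity segments so that the whole recognition stack is testable without
external recordings.  Activities alternate according to a semi-Markov
chain: the next activity is drawn from a transition matrix and occupied
for a log-normally distributed dwell time (explicit dwell rather than
per-event self-transitions, because real ADL segments are minutes long
and windows should mostly fall inside one segment).  While an activity is
active, the sensors assigned to it fire as Poisson streams — motion and
door sensors emit paired ON/OFF (OPEN/CLOSE) tokens, temperature sensors
emit a slowly drifting numeric value — and a small configurable fraction
of background chatter events (default 2%) falls outside any activity's
sensor set, emulating noise interference.

Three floor-plan presets emulate the shapes of well-known single-resident
recordings: ``milan_like`` (6 rooms, 33 sensors, 15 activities),
``house_c_like`` (6 rooms, 21 sensors, 16 activities) and ``aruba_like``
(5 rooms, 34 sensors, 11 activities).  Each activity draws events from
its own slice of its room's sensors, so activities sharing a room share a
location signature but differ in sensor identity — the realistic source
of confusion between, say, washing dishes and preparing a meal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .io_events import ActivitySegment, EventLog, SensorEvent

PRESETS = ("milan_like", "house_c_like", "aruba_like")

#: simulation clock zero: 2010-01-01 00:00:00 UTC in epoch milliseconds
EPOCH_START_MS = 1_262_304_000_000

DAY_MS = 86_400_000


@dataclass(frozen=True)
class FloorPlan:
    rooms: tuple[str, ...]
    sensors: tuple[tuple[str, str, str], ...]  # (sensor_id, type, room)

    def __post_init__(self) -> None:
        ids = [s[0] for s in self.sensors]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sensor ids")
        for _, _, room in self.sensors:
            if room not in self.rooms:
                raise ValueError(f"sensor room {room!r} not in floor plan")

    def sensor_map(self) -> dict[str, str]:
        return {sid: room for sid, _, room in self.sensors}

    def in_room(self, room: str) -> list[tuple[str, str, str]]:
        return [s for s in self.sensors if s[2] == room]


@dataclass
class ActivityModel:
    """Semi-Markov generator: transitions, dwells, per-activity emissions."""

    activities: tuple[str, ...]
    rooms_of: dict[str, tuple[str, ...]]
    transition: np.ndarray                      # (A, A), rows sum to 1
    dwell_mu: dict[str, float]                  # log-seconds
    dwell_sigma: dict[str, float]
    emission_rates: dict[str, dict[str, float]]  # activity -> sensor -> events/min
    temp_sensors: tuple[str, ...] = ()
    temp_rate_per_min: float = 0.5
    temp_drift_sigma: float = 0.15              # degrees C per reading
    temp_bounds: tuple[float, float] = (15.0, 30.0)
    novel: Optional[tuple[str, int]] = None     # (token, cutover day)

    def __post_init__(self) -> None:
        A = len(self.activities)
        if self.transition.shape != (A, A):
            raise ValueError("transition matrix shape mismatch")
        if not np.allclose(self.transition.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        for a in self.activities:
            if self.dwell_mu[a] <= 0 or self.dwell_sigma[a] <= 0:
                raise ValueError(f"dwell parameters for {a!r} must be positive")
            rooms = set(self.rooms_of[a])
            # emission support must respect the activity's rooms; checked
            # against the floor plan at generation time


@dataclass
class SimulationConfig:
    preset: str = "milan_like"
    days: int = 2
    seed: int = 0
    label_fraction: float = 1.0
    noise_fraction: float = 0.02
    novel_activity: Optional[str] = None
    novel_after_day: int = 0

    def __post_init__(self) -> None:
        if self.preset not in PRESETS + ("custom",):
            raise ValueError(f"unknown preset {self.preset!r}")
        if not 0.0 <= self.label_fraction <= 1.0:
            raise ValueError("label_fraction must lie in [0, 1]")


def _build_preset(name: str) -> tuple[FloorPlan, ActivityModel]:
    if name == "milan_like":
        rooms = ("kitchen", "living", "dining", "master_bedroom",
                 "master_bathroom", "guest_bathroom")
        motion_per_room = {"kitchen": 6, "living": 7, "dining": 4,
                           "master_bedroom": 5, "master_bathroom": 3,
                           "guest_bathroom": 3}  # 28 motion
        doors = [("D001", "door", "living"), ("D002", "door", "kitchen"),
                 ("D003", "door", "master_bedroom")]
        temps = [("T001", "temperature", "kitchen"),
                 ("T002", "temperature", "living")]
        activities = {
            "Bed-to-Toilet": ("master_bedroom", "master_bathroom"),
            "Chores": ("kitchen",),
            "Desk_Activity": ("living",),
            "Dining_Rm_Activity": ("dining",),
            "Eve_Meds": ("kitchen",),
            "Guest_Bathroom": ("guest_bathroom",),
            "Kitchen_Activity": ("kitchen",),
            "Leave_Home": ("living",),
            "Master_Bathroom": ("master_bathroom",),
            "Meditate": ("living",),
            "Watch_TV": ("living",),
            "Sleep": ("master_bedroom",),
            "Read": ("living",),
            "Morning_Meds": ("kitchen",),
            "Master_Bedroom_Activity": ("master_bedroom",),
        }
        dwell_min = {"Bed-to-Toilet": 4, "Chores": 15, "Desk_Activity": 20,
                     "Dining_Rm_Activity": 20, "Eve_Meds": 3,
                     "Guest_Bathroom": 5, "Kitchen_Activity": 20,
                     "Leave_Home": 5, "Master_Bathroom": 6, "Meditate": 15,
                     "Watch_TV": 30, "Sleep": 120, "Read": 20,
                     "Morning_Meds": 3, "Master_Bedroom_Activity": 12}
        door_users = {"Leave_Home": "D001"}
        quiet = {"Sleep": 2.0, "Meditate": 6.0}
    elif name == "house_c_like":
        rooms = ("kitchen", "living", "bedroom", "bathroom", "hall", "study")
        motion_per_room = {"kitchen": 4, "living": 3, "bedroom": 3,
                           "bathroom": 3, "hall": 2, "study": 2}  # 17 motion
        doors = [("D001", "door", "hall"), ("D002", "door", "kitchen"),
                 ("D003", "door", "bathroom")]
        temps = [("T001", "temperature", "living")]
        activities = {
            "Brushing_Teeth": ("bathroom",), "Drinking": ("kitchen",),
            "Dressing": ("bedroom",), "Eating": ("living",),
            "Leaving_House": ("hall",), "Medication": ("kitchen",),
            "Preparing_Breakfast": ("kitchen",), "Preparing_Lunch": ("kitchen",),
            "Preparing_Dinner": ("kitchen",), "Relax": ("living",),
            "Sleeping": ("bedroom",), "Showering": ("bathroom",),
            "Snacks": ("kitchen",), "Shaving": ("bathroom",),
            "Toileting": ("bathroom",), "Others": ("study",),
        }
        dwell_min = {"Brushing_Teeth": 3, "Drinking": 3, "Dressing": 6,
                     "Eating": 20, "Leaving_House": 5, "Medication": 3,
                     "Preparing_Breakfast": 12, "Preparing_Lunch": 15,
                     "Preparing_Dinner": 25, "Relax": 30, "Sleeping": 120,
                     "Showering": 10, "Snacks": 5, "Shaving": 5,
                     "Toileting": 4, "Others": 15}
        door_users = {"Leaving_House": "D001"}
        quiet = {"Sleeping": 2.0}
    elif name == "aruba_like":
        rooms = ("kitchen", "living", "bedroom", "bathroom", "office")
        motion_per_room = {"kitchen": 8, "living": 8, "bedroom": 6,
                           "bathroom": 4, "office": 4}  # 30 motion
        doors = [("D001", "door", "living"), ("D002", "door", "kitchen")]
        temps = [("T001", "temperature", "kitchen"),
                 ("T002", "temperature", "living")]
        activities = {
            "Meal_Preparation": ("kitchen",), "Relax": ("living",),
            "Eating": ("living",), "Work": ("office",),
            "Sleeping": ("bedroom",), "Wash_Dishes": ("kitchen",),
            "Bed_to_Toilet": ("bedroom", "bathroom"),
            "Enter_Home": ("living",), "Leave_Home": ("living",),
            "Housekeeping": ("living",), "Resperate": ("office",),
        }
        dwell_min = {"Meal_Preparation": 25, "Relax": 40, "Eating": 20,
                     "Work": 45, "Sleeping": 150, "Wash_Dishes": 10,
                     "Bed_to_Toilet": 4, "Enter_Home": 3, "Leave_Home": 3,
                     "Housekeeping": 25, "Resperate": 15}
        door_users = {"Enter_Home": "D001", "Leave_Home": "D001"}
        quiet = {"Sleeping": 2.0}
    else:
        raise ValueError(f"unknown preset {name!r}")

    sensors: list[tuple[str, str, str]] = []
    i = 1
    for room in rooms:
        for _ in range(motion_per_room[room]):
            sensors.append((f"M{i:03d}", "motion", room))
            i += 1
    sensors.extend(doors)
    sensors.extend(temps)
    plan = FloorPlan(tuple(rooms), tuple(sensors))

    # partition each room's motion sensors round-robin among its activities
    act_names = tuple(activities)
    room_acts: dict[str, list[str]] = {r: [] for r in rooms}
    for a, rms in activities.items():
        for r in rms:
            room_acts[r].append(a)
    emission: dict[str, dict[str, float]] = {a: {} for a in act_names}
    for room in rooms:
        acts = room_acts[room]
        motions = [sid for sid, typ, r in sensors if r == room and typ == "motion"]
        if not acts:
            continue
        for j, sid in enumerate(motions):
            a = acts[j % len(acts)]
            emission[a][sid] = quiet.get(a, 30.0)
    for a, door in door_users.items():
        emission[a][door] = 6.0
    # guarantee every activity at least one sensor
    for a in act_names:
        if not emission[a]:
            room = activities[a][0]
            sid = next(s for s, t, r in sensors if r == room)
            emission[a][sid] = quiet.get(a, 30.0)

    A = len(act_names)
    transition = (np.ones((A, A)) - np.eye(A)) / (A - 1)
    model = ActivityModel(
        activities=act_names,
        rooms_of={a: tuple(r) for a, r in activities.items()},
        transition=transition,
        dwell_mu={a: math.log(m * 60.0) for a, m in dwell_min.items()},
        dwell_sigma={a: 0.5 for a in act_names},
        emission_rates=emission,
        temp_sensors=tuple(sid for sid, typ, _ in sensors if typ == "temperature"),
    )
    return plan, model


def build_preset(name: str) -> tuple[FloorPlan, ActivityModel]:
    """Floor plan and activity model for one of the named presets."""
    return _build_preset(name)


def _active_indices(model: ActivityModel, day: int) -> np.ndarray:
    """Activity indices available on a given day (novel token gated)."""
    idx = np.arange(len(model.activities))
    if model.novel is not None:
        token, after = model.novel
        if day < after:
            idx = idx[np.array(model.activities) != token]
    return idx


def _draw_next(rng: np.random.Generator, model: ActivityModel,
               current: Optional[int], day: int) -> int:
    avail = _active_indices(model, day)
    if current is None:
        return int(rng.choice(avail))
    row = model.transition[current][avail].copy()
    if row.sum() == 0:
        return int(rng.choice(avail))
    return int(rng.choice(avail, p=row / row.sum()))


def generate(config: SimulationConfig,
             plan: Optional[FloorPlan] = None,
             model: Optional[ActivityModel] = None
             ) -> tuple[EventLog, list[ActivitySegment]]:
    """Simulate ``config.days`` days of events with ground-truth segments.

    Fully reproducible from ``config.seed``.  The returned segment list is
    the complete ground truth; the log's annotations honor
    ``config.label_fraction`` (hidden segments keep their events but lose
    their begin/end marks) and a novel activity is never annotated.
    """
    if plan is None or model is None:
        plan, model = _build_preset(config.preset)
    if config.novel_activity is not None and (
            model.novel is None or model.novel[0] != config.novel_activity):
        model = inject_novel_activity(model, config.novel_activity,
                                      config.novel_after_day, plan)
    rng = np.random.default_rng(config.seed)
    t_end = EPOCH_START_MS + config.days * DAY_MS
    sensor_type = {sid: typ for sid, typ, _ in plan.sensors}
    temp_value = {sid: 21.0 for sid in model.temp_sensors}
    room_of = plan.sensor_map()

    segments: list[ActivitySegment] = []
    raw: list[tuple[int, str, object, Optional[str]]] = []  # ts, sid, value, seg label
    t = EPOCH_START_MS
    current: Optional[int] = None
    while t < t_end and config.days > 0:
        day = (t - EPOCH_START_MS) // DAY_MS
        current = _draw_next(rng, model, current, day)
        act = model.activities[current]
        dwell_s = float(np.clip(rng.lognormal(model.dwell_mu[act],
                                              model.dwell_sigma[act]),
                                30.0, 4 * 3600.0))
        seg_start = t
        seg_end = min(t + int(dwell_s * 1000), t_end)
        if seg_end <= seg_start:
            break
        segments.append(ActivitySegment(seg_start, seg_end, act))
        dur_min = (seg_end - seg_start) / 60_000.0
        for sid, rate in sorted(model.emission_rates[act].items()):
            n = rng.poisson(rate * dur_min)
            if n == 0:
                continue
            starts = np.sort(rng.integers(seg_start, seg_end, size=n))
            if sensor_type[sid] in ("motion", "door"):
                on, off = (("OPEN", "CLOSE") if sensor_type[sid] == "door"
                           else ("ON", "OFF"))
                for s0 in starts:
                    gap = int(rng.uniform(500, 5000))
                    raw.append((int(s0), sid, on, act))
                    raw.append((min(int(s0) + gap, seg_end - 1), sid, off, act))
            else:
                for s0 in starts:
                    raw.append((int(s0), sid, float(temp_value.get(sid, 21.0)), act))
        # temperature drift in the activity's rooms
        act_rooms = set(model.rooms_of[act])
        for sid in model.temp_sensors:
            if room_of[sid] not in act_rooms:
                continue
            n = rng.poisson(model.temp_rate_per_min * dur_min)
            for s0 in np.sort(rng.integers(seg_start, seg_end, size=n)):
                temp_value[sid] = float(np.clip(
                    temp_value[sid] + rng.normal(0.0, model.temp_drift_sigma),
                    *model.temp_bounds))
                raw.append((int(s0), sid, round(temp_value[sid], 2), act))
        t = seg_end
    # background chatter outside any activity's sensor set
    if config.noise_fraction > 0 and raw:
        n_noise = int(round(config.noise_fraction / (1 - config.noise_fraction)
                            * len(raw)))
        all_ids = [sid for sid, typ, _ in plan.sensors if typ != "temperature"]
        for _ in range(n_noise):
            ts = int(rng.integers(EPOCH_START_MS, t_end))
            sid = all_ids[int(rng.integers(len(all_ids)))]
            val = "ON" if sensor_type[sid] == "motion" else "OPEN"
            raw.append((ts, sid, val, None))

    # choose which segments stay annotated
    annotated = set(range(len(segments)))
    novel_token = model.novel[0] if model.novel else None
    if novel_token is not None:
        annotated -= {i for i, s in enumerate(segments) if s.label == novel_token}
    if config.label_fraction < 1.0:
        vis = [i for i in sorted(annotated)]
        keep, _ = _stratified_keep([segments[i] for i in vis],
                                   config.label_fraction,
                                   np.random.default_rng(config.seed + 1))
        annotated = {vis[i] for i in keep}

    raw.sort(key=lambda r: r[0])
    seg_bounds = [(s.start, s.end, i) for i, s in enumerate(segments)]
    first_in: dict[int, int] = {}
    last_in: dict[int, int] = {}
    seg_idx_of: list[Optional[int]] = []
    si = 0
    for k, (ts, sid, val, lab) in enumerate(raw):
        while si < len(seg_bounds) and ts >= seg_bounds[si][1]:
            si += 1
        j = None
        if lab is not None and si < len(seg_bounds) and seg_bounds[si][0] <= ts:
            j = seg_bounds[si][2]
            if segments[j].label == lab:
                first_in.setdefault(j, k)
                last_in[j] = k
            else:
                j = None
        seg_idx_of.append(j)

    events: list[SensorEvent] = []
    for k, (ts, sid, val, lab) in enumerate(raw):
        annotation = marker = None
        j = seg_idx_of[k]
        if j is not None and j in annotated:
            if first_in.get(j) == k:
                annotation, marker = segments[j].label, "begin"
            elif last_in.get(j) == k:
                annotation, marker = segments[j].label, "end"
        events.append(SensorEvent(ts, sid, val, location=room_of[sid],
                                  annotation=annotation, marker=marker))

    inventory = {sid: (typ, room) for sid, typ, room in plan.sensors}
    vocab = [a for a in model.activities if a != novel_token]
    log = EventLog(events=events, sensor_inventory=inventory,
                   activity_vocabulary=vocab,
                   metadata={"name": config.preset, "days": config.days,
                             "seed": config.seed})
    return log, segments


def _stratified_keep(segments: Sequence[ActivitySegment], fraction: float,
                     rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """Indices to keep labeled: floor(fraction·N) total, allocated per class
    by floors then largest fractional part."""
    n = len(segments)
    target = math.floor(fraction * n)
    by_class: dict[str, list[int]] = {}
    for i, s in enumerate(segments):
        by_class.setdefault(s.label, []).append(i)
    alloc = {c: math.floor(fraction * len(idx)) for c, idx in by_class.items()}
    remainder = target - sum(alloc.values())
    order = sorted(by_class,
                   key=lambda c: -(fraction * len(by_class[c]) - alloc[c]))
    for c in order:
        if remainder <= 0:
            break
        if alloc[c] < len(by_class[c]):
            alloc[c] += 1
            remainder -= 1
    keep: list[int] = []
    for c, idx in by_class.items():
        chosen = rng.permutation(len(idx))[:alloc[c]]
        keep.extend(idx[i] for i in sorted(chosen))
    keep_set = set(keep)
    hide = [i for i in range(n) if i not in keep_set]
    return sorted(keep), hide


def hide_labels(log: EventLog, segments: Sequence[ActivitySegment],
                fraction: float, seed: int = 0
                ) -> tuple[list[ActivitySegment], list[ActivitySegment]]:
    """Deterministic stratified subsampling of segments to stay labeled.

    Returns ``(labeled, unlabeled)``; exactly floor(fraction·N) segments
    stay labeled, allocated across activity classes proportionally.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    keep, hide = _stratified_keep(list(segments), fraction, rng)
    return [segments[i] for i in keep], [segments[i] for i in hide]


def inject_novel_activity(model: ActivityModel, token: str, after_day: int,
                          plan: Optional[FloorPlan] = None) -> ActivityModel:
    """Extend the model with an unannotated activity appearing only after
    the cutover day.  Transition rows are renormalized to sum to 1."""
    if token in model.activities:
        raise ValueError(f"activity {token!r} already present")
    A = len(model.activities)
    new_t = np.zeros((A + 1, A + 1))
    new_t[:A, :A] = model.transition
    new_t[:A, A] = 1.0 / A  # comparable mass toward the newcomer
    new_t[A, :A] = 1.0 / A
    new_t /= new_t.sum(axis=1, keepdims=True)
    room = model.rooms_of[model.activities[0]][0]
    emission = dict(model.emission_rates)
    if plan is not None:
        sid = plan.in_room(room)[0][0]
    else:
        sid = next(iter(model.emission_rates[model.activities[0]]))
    emission[token] = {sid: 30.0}
    return ActivityModel(
        activities=model.activities + (token,),
        rooms_of={**model.rooms_of, token: (room,)},
        transition=new_t,
        dwell_mu={**model.dwell_mu, token: math.log(10 * 60.0)},
        dwell_sigma={**model.dwell_sigma, token: 0.5},
        emission_rates=emission,
        temp_sensors=model.temp_sensors,
        temp_rate_per_min=model.temp_rate_per_min,
        temp_drift_sigma=model.temp_drift_sigma,
        temp_bounds=model.temp_bounds,
        novel=(token, after_day),
    )
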