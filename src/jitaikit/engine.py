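"""Geofence-triggered support (GTS) decision engine.

The engine is a per-user state machine.  Before the quit date it learns
smoking locations from self-reported smoking events ("training"); once a
location accumulates enough reports it becomes a circular geofence.  After
the quit date, location fixes are matched against the fences: dwelling
inside one for at least five minutes makes the engine evaluate whether to
fire a support message, and re-evaluate after every further three-hour
interval of continuous presence.  Firing is gated by the per-time-bin
report tally for the fence, the local-time active window, a per-fence
cooldown, and — in the maintenance stage — a month-over-month halving
probability gate.  Support stops three months after the quit date unless
the quit attempt is reset.

All operations are deterministic functions of (event stream, config,
seed); the only randomness (the maintenance decay gate) is driven by a
counter-based generator seeded from the state's ``rng_seed``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta
from enum import Enum
from typing import Iterable, Optional, Union

import numpy as np

from .geo import GeoPoint, haversine_m

__all__ = [
    "Stage",
    "Reason",
    "Situation",
    "LocationFix",
    "SmokingReport",
    "ResetCommand",
    "Geofence",
    "EngineConfig",
    "EngineState",
    "TriggerDecision",
    "OrderingError",
    "new_state",
    "ingest_smoking_report",
    "ingest_location_fix",
    "decide_trigger",
    "detect_relapse",
    "reset_quit_attempt",
    "advance_stage",
    "replay_event_log",
    "time_bin",
]


class Stage(str, Enum):
    TRAINING = "training"
    COMMITTED = "committed"
    MAINTENANCE = "maintenance"
    STOPPED = "stopped"


class Reason(str, Enum):
    OUTSIDE_WINDOW = "outside_window"
    BELOW_THRESHOLD = "below_threshold"
    COOLDOWN = "cooldown"
    DECAYED_OUT = "decayed_out"
    STOPPED = "stopped"
    FIRED = "fired"


class Situation(str, Enum):
    HOME = "home"
    WORK = "work"
    WORKING_FROM_HOME = "working_from_home"
    SOCIALIZING = "socializing"
    OTHER = "other"


class OrderingError(ValueError):
    """Raised when an event arrives out of time order."""


def _require_aware(ts: datetime, what: str) -> None:
    if ts.tzinfo is None:
        raise ValueError(f"{what} timestamp must be timezone-aware")


@dataclass(frozen=True)
class LocationFix:
    timestamp: datetime
    point: GeoPoint
    accuracy_m: float = 0.0

    def __post_init__(self) -> None:
        _require_aware(self.timestamp, "LocationFix")
        if self.accuracy_m < 0:
            raise ValueError("accuracy_m must be nonnegative")


_ORDINAL_RANGE = range(0, 6)


@dataclass(frozen=True)
class SmokingReport:
    timestamp: datetime
    point: Optional[GeoPoint]
    urge_strength: int
    stress: int
    mood: int
    situation: Situation
    others_present: bool
    is_lapse: bool = False

    def __post_init__(self) -> None:
        _require_aware(self.timestamp, "SmokingReport")
        for name in ("urge_strength", "stress", "mood"):
            v = getattr(self, name)
            if v not in _ORDINAL_RANGE:
                raise ValueError(f"{name}={v} outside ordinal range 0-5")
        object.__setattr__(self, "situation", Situation(self.situation))


@dataclass(frozen=True)
class ResetCommand:
    """Restart the quit attempt from ``new_quit_date`` (manual or post-relapse)."""

    timestamp: datetime
    new_quit_date: date

    def __post_init__(self) -> None:
        _require_aware(self.timestamp, "ResetCommand")


Event = Union[LocationFix, SmokingReport, ResetCommand]


@dataclass
class Geofence:
    id: str
    center: GeoPoint
    radius_m: float
    created_at: datetime
    source: str  # "pre_quit" | "lapse"
    report_tally: dict[int, int] = field(default_factory=dict)
    situation_counts: dict[str, int] = field(default_factory=dict)
    context_counts: dict[str, int] = field(default_factory=dict)

    @property
    def total_reports(self) -> int:
        return sum(self.report_tally.values())

    def contains(self, point: GeoPoint) -> bool:
        # boundary (distance == radius) counts as inside
        return haversine_m(self.center, point) <= self.radius_m


@dataclass(frozen=True)
class EngineConfig:
    fence_radius_m: float = 100.0
    min_reports_for_fence: int = 2
    min_dwell_minutes: float = 5.0
    redecision_interval_hours: float = 3.0
    active_window: tuple[time, time] = (time(8, 0), time(21, 30))
    stage2_duration_days: int = 28
    stage3_duration_months: int = 2
    monthly_decay_factor: float = 0.5
    support_stop_months: int = 3
    trigger_threshold: int = 2
    relapse_episodes_per_day_gt: int = 1
    relapse_consecutive_days: int = 2
    month_length_days: int = 30
    dwell_gap_factor: float = 2.0

    def __post_init__(self) -> None:
        if self.fence_radius_m <= 0 or self.min_dwell_minutes <= 0:
            raise ValueError("durations and radii must be positive")
        if self.redecision_interval_hours <= 0 or self.stage2_duration_days <= 0:
            raise ValueError("durations must be positive")
        if not 0 < self.monthly_decay_factor <= 1:
            raise ValueError("monthly_decay_factor must be in (0, 1]")
        start, end = self.active_window
        if start >= end:
            raise ValueError("active_window start must precede end within one day")

    @property
    def support_stop_days(self) -> int:
        return self.support_stop_months * self.month_length_days

    @property
    def redecision_interval(self) -> timedelta:
        return timedelta(hours=self.redecision_interval_hours)

    @property
    def min_dwell(self) -> timedelta:
        return timedelta(minutes=self.min_dwell_minutes)


def time_bin(ts: datetime, config: EngineConfig) -> int:
    """Time-of-day bin index; bins span ``redecision_interval_hours`` and are
    aligned to the active-window start, wrapping at midnight."""
    start = config.active_window[0]
    minutes = ts.hour * 60 + ts.minute - (start.hour * 60 + start.minute)
    return int((minutes % 1440) // (config.redecision_interval_hours * 60))


@dataclass
class _Candidate:
    """A provisional smoking location awaiting promotion to a geofence."""

    points: list[GeoPoint]
    created_at: datetime
    report_tally: dict[int, int] = field(default_factory=dict)
    situation_counts: dict[str, int] = field(default_factory=dict)
    context_counts: dict[str, int] = field(default_factory=dict)

    @property
    def center(self) -> GeoPoint:
        lat = sum(p.latitude for p in self.points) / len(self.points)
        lon = sum(p.longitude for p in self.points) / len(self.points)
        return GeoPoint(lat, lon)


@dataclass
class _Dwell:
    fence_id: str
    entry_time: datetime
    last_fix_time: datetime
    evaluations_done: int = 0


@dataclass
class TriggerDecision:
    fired: bool
    reason: Reason
    time: datetime
    fence_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.fired != (self.reason is Reason.FIRED):
            raise ValueError("fired must hold exactly when reason is 'fired'")


@dataclass
class EngineState:
    rng_seed: int
    stage: Stage = Stage.TRAINING
    quit_date: Optional[date] = None
    fences: list[Geofence] = field(default_factory=list)
    candidates: list[_Candidate] = field(default_factory=list)
    dwell: Optional[_Dwell] = None
    daily_episode_counts: dict[date, int] = field(default_factory=dict)
    messages_sent: list[tuple[datetime, str, str]] = field(default_factory=list)
    last_event_time: Optional[datetime] = None
    fix_intervals_s: list[float] = field(default_factory=list)
    decay_draw_count: int = 0

    def last_message_time(self, fence_id: str) -> Optional[datetime]:
        for ts, fid, _ in reversed(self.messages_sent):
            if fid == fence_id:
                return ts
        return None


def new_state(seed: int, quit_date: Optional[date] = None) -> EngineState:
    return EngineState(rng_seed=int(seed), quit_date=quit_date)


def _check_order(state: EngineState, ts: datetime) -> None:
    if state.last_event_time is not None and ts < state.last_event_time:
        raise OrderingError(
            f"event at {ts.isoformat()} precedes last processed event "
            f"at {state.last_event_time.isoformat()}"
        )


def _nearest_within(
    point: GeoPoint, items: list, radius: float
) -> Optional[int]:
    """Index of the nearest item (by ``.center``) within ``radius``; ties go to
    the earliest-created (lowest index)."""
    best, best_d = None, math.inf
    for i, item in enumerate(items):
        d = haversine_m(item.center, point)
        if d <= radius and d < best_d:
            best, best_d = i, d
    return best


def _report_context_tags(report: SmokingReport) -> list[str]:
    tags = []
    if report.urge_strength >= 4:
        tags.append("strong_urge")
    if report.stress >= 4:
        tags.append("stress")
    if report.mood <= 1:
        tags.append("low_mood")
    if report.others_present:
        tags.append("others_present")
    return tags or ["generic"]


def _bump(counter: dict, key, by: int = 1) -> None:
    counter[key] = counter.get(key, 0) + by


def ingest_smoking_report(
    state: EngineState, report: SmokingReport, config: EngineConfig
) -> EngineState:
    """Assign a smoking report to the location-learning model.

    The report joins the nearest existing fence within the fence radius,
    else the nearest candidate cluster, else it seeds a new candidate.  A
    candidate reaching ``min_reports_for_fence`` reports is promoted to a
    geofence centred on its report centroid.  Post-quit reports also feed
    the daily episode counts used by relapse detection.
    """
    _check_order(state, report.timestamp)
    state.last_event_time = report.timestamp

    post_quit = state.quit_date is not None and report.timestamp.date() >= state.quit_date
    if post_quit:
        _bump(state.daily_episode_counts, report.timestamp.date())
        if not report.is_lapse:
            report = replace(report, is_lapse=True)

    if report.point is None:
        return state

    tbin = time_bin(report.timestamp, config)
    ctx_tags = _report_context_tags(report)
    source = "lapse" if report.is_lapse else "pre_quit"

    fi = _nearest_within(report.point, state.fences, config.fence_radius_m)
    if fi is not None:
        fence = state.fences[fi]
        _bump(fence.report_tally, tbin)
        _bump(fence.situation_counts, report.situation.value)
        for t in ctx_tags:
            _bump(fence.context_counts, t)
        return state

    ci = _nearest_within(report.point, state.candidates, config.fence_radius_m)
    if ci is None:
        cand = _Candidate(points=[report.point], created_at=report.timestamp)
        _bump(cand.report_tally, tbin)
        _bump(cand.situation_counts, report.situation.value)
        for t in ctx_tags:
            _bump(cand.context_counts, t)
        state.candidates.append(cand)
        return state

    cand = state.candidates[ci]
    cand.points.append(report.point)
    _bump(cand.report_tally, tbin)
    _bump(cand.situation_counts, report.situation.value)
    for t in ctx_tags:
        _bump(cand.context_counts, t)
    if len(cand.points) >= config.min_reports_for_fence:
        state.candidates.pop(ci)
        fence = Geofence(
            id=f"f{len(state.fences) + 1}",
            center=cand.center,
            radius_m=config.fence_radius_m,
            created_at=report.timestamp,
            source=source,
            report_tally=dict(cand.report_tally),
            situation_counts=dict(cand.situation_counts),
            context_counts=dict(cand.context_counts),
        )
        state.fences.append(fence)
    return state


def _decay_draw(state: EngineState) -> float:
    """Counter-based uniform draw; reproducible from (rng_seed, draw index)."""
    draw = np.random.default_rng([state.rng_seed, state.decay_draw_count]).random()
    state.decay_draw_count += 1
    return float(draw)


def decide_trigger(
    state: EngineState, fence: Geofence, when: datetime, config: EngineConfig
) -> TriggerDecision:
    """Evaluate whether a dwell-qualified presence in ``fence`` fires a message."""
    local = when.time()
    start, end = config.active_window
    if not (start <= local <= end):
        return TriggerDecision(False, Reason.OUTSIDE_WINDOW, when, fence.id)

    if state.quit_date is None or state.stage in (Stage.TRAINING, Stage.STOPPED):
        return TriggerDecision(False, Reason.STOPPED, when, fence.id)
    quit_dt = datetime.combine(state.quit_date, time(0, 0), tzinfo=when.tzinfo)
    if when < quit_dt or when >= quit_dt + timedelta(days=config.support_stop_days):
        return TriggerDecision(False, Reason.STOPPED, when, fence.id)

    if fence.report_tally.get(time_bin(when, config), 0) < config.trigger_threshold:
        return TriggerDecision(False, Reason.BELOW_THRESHOLD, when, fence.id)

    last = state.last_message_time(fence.id)
    if last is not None and when - last < config.redecision_interval:
        return TriggerDecision(False, Reason.COOLDOWN, when, fence.id)

    if state.stage is Stage.MAINTENANCE:
        stage2_end = quit_dt + timedelta(days=config.stage2_duration_days)
        completed_months = int((when - stage2_end) // timedelta(days=config.month_length_days))
        # frequency halves each post-challenge month: first maintenance month
        # already fires at half the committed-stage rate
        p = config.monthly_decay_factor ** (completed_months + 1)
        if _decay_draw(state) >= p:
            return TriggerDecision(False, Reason.DECAYED_OUT, when, fence.id)

    return TriggerDecision(True, Reason.FIRED, when, fence.id)


def _median(xs: list[float]) -> float:
    s = sorted(xs)
    n = len(s)
    return s[n // 2] if n % 2 else 0.5 * (s[n // 2 - 1] + s[n // 2])


def ingest_location_fix(
    state: EngineState, fix: LocationFix, config: EngineConfig
) -> tuple[EngineState, Optional[TriggerDecision]]:
    """Update dwell tracking with a location fix; may yield a trigger decision.

    A decision is produced when continuous dwell inside one fence first
    reaches ``min_dwell_minutes`` and again at each subsequent
    ``redecision_interval_hours`` boundary.  Leaving the fence, or a gap
    exceeding ``dwell_gap_factor`` x the median fix interval, resets dwell.
    """
    _check_order(state, fix.timestamp)
    prev_time = state.last_event_time
    state.last_event_time = fix.timestamp

    if state.stage not in (Stage.COMMITTED, Stage.MAINTENANCE):
        state.dwell = None
        return state, None

    if prev_time is not None:
        gap_s = (fix.timestamp - prev_time).total_seconds()
        if gap_s > 0:
            state.fix_intervals_s.append(gap_s)
            del state.fix_intervals_s[:-512]

    fi = _nearest_within(fix.point, state.fences, config.fence_radius_m)
    fence = state.fences[fi] if fi is not None else None

    if fence is None:
        state.dwell = None
        return state, None

    d = state.dwell
    gap_broken = False
    if d is not None and len(state.fix_intervals_s) >= 2:
        gap_s = (fix.timestamp - d.last_fix_time).total_seconds()
        gap_broken = gap_s > config.dwell_gap_factor * _median(state.fix_intervals_s)

    if d is None or d.fence_id != fence.id or gap_broken:
        state.dwell = _Dwell(fence.id, fix.timestamp, fix.timestamp)
        return state, None

    d.last_fix_time = fix.timestamp
    elapsed = fix.timestamp - d.entry_time
    due = config.min_dwell + d.evaluations_done * config.redecision_interval
    if elapsed < due:
        return state, None

    decision = decide_trigger(state, fence, fix.timestamp, config)
    d.evaluations_done = int((elapsed - config.min_dwell) // config.redecision_interval) + 1
    if decision.fired:
        msg_id = f"msg-{len(state.messages_sent) + 1}"
        state.messages_sent.append((fix.timestamp, fence.id, msg_id))
    return state, decision


def detect_relapse(state: EngineState, on: date, config: EngineConfig) -> bool:
    """True iff every day in the window ending at ``on`` has strictly more than
    ``relapse_episodes_per_day_gt`` reported smoking episodes."""
    if state.quit_date is None:
        raise ValueError("quit_date must be set before relapse detection")
    for k in range(config.relapse_consecutive_days):
        day = on - timedelta(days=k)
        if state.daily_episode_counts.get(day, 0) <= config.relapse_episodes_per_day_gt:
            return False
    return True


def reset_quit_attempt(state: EngineState, new_quit_date: date) -> EngineState:
    """Restart the quit attempt: stage returns to committed, the decay and
    support-stop clocks restart; fences, tallies and message history persist."""
    if state.last_event_time is not None and new_quit_date < state.last_event_time.date():
        raise ValueError(
            f"new quit date {new_quit_date} precedes last event "
            f"{state.last_event_time.isoformat()}"
        )
    state.quit_date = new_quit_date
    state.stage = Stage.COMMITTED
    state.dwell = None
    return state


_STAGE_ORDER = [Stage.TRAINING, Stage.COMMITTED, Stage.MAINTENANCE, Stage.STOPPED]


def advance_stage(state: EngineState, now: datetime, config: EngineConfig) -> EngineState:
    """Move the stage clock forward (never backward) according to ``now``."""
    if state.quit_date is None:
        return state
    quit_dt = datetime.combine(state.quit_date, time(0, 0), tzinfo=now.tzinfo)
    if now < quit_dt:
        target = Stage.TRAINING
    elif now < quit_dt + timedelta(days=config.stage2_duration_days):
        target = Stage.COMMITTED
    elif now < quit_dt + timedelta(days=config.support_stop_days):
        target = Stage.MAINTENANCE
    else:
        target = Stage.STOPPED
    if _STAGE_ORDER.index(target) > _STAGE_ORDER.index(state.stage):
        state.stage = target
    return state


def replay_event_log(
    events: Iterable[Event], config: EngineConfig, seed: int = 0
) -> tuple[EngineState, list[TriggerDecision]]:
    """Fold the ingest operations over a time-ordered event stream.

    Pure function of (events, config, seed): replays are bit-identical.
    """
    state = new_state(seed)
    decisions: list[TriggerDecision] = []
    for i, event in enumerate(events):
        try:
            advance_stage(state, event.timestamp, config)
            if isinstance(event, ResetCommand):
                _check_order(state, event.timestamp)
                state.last_event_time = event.timestamp
                reset_quit_attempt(state, event.new_quit_date)
            elif isinstance(event, SmokingReport):
                ingest_smoking_report(state, event, config)
            elif isinstance(event, LocationFix):
                _, decision = ingest_location_fix(state, event, config)
                if decision is not None:
                    decisions.append(decision)
            else:  # pragma: no cover - defensive
                raise TypeError(f"unknown event type {type(event).__name__}")
        except OrderingError as exc:
            raise OrderingError(f"record {i}: {exc}") from None
    return state, decisions
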