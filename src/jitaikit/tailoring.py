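"""Message tailoring and ancillary feedback features.

Message bodies are placeholders: only the tag taxonomy and the selection
contract matter here.  Selection filters a library by stage and by the
fence's modal situation, prefers not-yet-sent messages, and cycles once
the eligible set is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Iterable, Optional, Sequence

import numpy as np

from .engine import EngineState, Geofence, SmokingReport, Situation, Stage

__all__ = [
    "SupportMessage",
    "MessageLibrary",
    "ProfileStats",
    "EndOfDayEntry",
    "default_library",
    "select_gts_message",
    "post_report_feedback",
    "morning_message",
    "profile_stats",
    "smoking_pattern_summary",
    "dominant_context",
    "modal_situation",
]

CONTEXT_TAGS = ("strong_urge", "stress", "low_mood", "others_present", "generic")
# fixed tie-break priority for context tags
_CONTEXT_PRIORITY = {t: i for i, t in enumerate(CONTEXT_TAGS)}
PHASE_TAGS = ("pre_quit", "quit_day", "post_quit")


@dataclass(frozen=True)
class SupportMessage:
    id: str
    stage_tags: frozenset[str]
    situation_tags: frozenset[str]
    context_tags: frozenset[str]
    bct_tag: str = ""
    body: str = ""
    phase_tag: Optional[str] = None  # morning messages only

    def __post_init__(self) -> None:
        if not self.stage_tags:
            raise ValueError("message needs at least one stage tag")


@dataclass
class MessageLibrary:
    messages: list[SupportMessage]
    cycle_policy: str = "no_repeat_until_exhausted"

    def __post_init__(self) -> None:
        if not self.messages:
            raise ValueError("message library is empty")
        ids = [m.id for m in self.messages]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate message ids in library")

    def by_id(self, msg_id: str) -> SupportMessage:
        for m in self.messages:
            if m.id == msg_id:
                return m
        raise KeyError(msg_id)


def default_library() -> MessageLibrary:
    """A placeholder library covering every (stage, situation, context) cell."""
    stages = ("training", "committed", "maintenance")
    msgs: list[SupportMessage] = []
    for stage in stages:
        for situ in Situation:
            for ctx in CONTEXT_TAGS:
                msgs.append(
                    SupportMessage(
                        id=f"{stage[:2]}-{situ.value}-{ctx}",
                        stage_tags=frozenset({stage}),
                        situation_tags=frozenset({situ.value}),
                        context_tags=frozenset({ctx}),
                        bct_tag="placeholder",
                        body=f"[{stage}/{situ.value}/{ctx}]",
                    )
                )
    for phase in PHASE_TAGS:
        for k in range(7):
            msgs.append(
                SupportMessage(
                    id=f"morning-{phase}-{k}",
                    stage_tags=frozenset(stages),
                    situation_tags=frozenset(s.value for s in Situation),
                    context_tags=frozenset({"generic"}),
                    bct_tag="placeholder",
                    body=f"[morning/{phase}/{k}]",
                    phase_tag=phase,
                )
            )
    return MessageLibrary(messages=msgs)


def modal_situation(fence: Geofence) -> Optional[str]:
    """Most frequent situation among the fence's reports; ties by enum order."""
    if not fence.situation_counts:
        return None
    order = [s.value for s in Situation]
    return max(
        fence.situation_counts,
        key=lambda s: (fence.situation_counts[s], -order.index(s)),
    )


def dominant_context(fence: Geofence) -> str:
    """Modal context tag over the fence's reports; ties broken by the fixed
    priority order urge > stress > mood > others > generic."""
    if not fence.context_counts:
        return "generic"
    return max(
        fence.context_counts,
        key=lambda t: (fence.context_counts[t], -_CONTEXT_PRIORITY[t]),
    )


def select_gts_message(
    library: MessageLibrary,
    fence: Geofence,
    context: str,
    stage: Stage,
    history: Sequence[str],
    seed: int,
) -> SupportMessage:
    """Pick a message for a fired geofence trigger.

    Eligibility: matches the stage and the fence's modal situation; among
    eligible messages those matching the dominant context are preferred,
    then unsent messages (the cycle resets when all eligible ids have been
    sent).  Deterministic given (library, inputs, history, seed).
    """
    situation = modal_situation(fence)
    stage_name = stage.value if isinstance(stage, Stage) else str(stage)

    pool = [
        m
        for m in library.messages
        if m.phase_tag is None
        and stage_name in m.stage_tags
        and (situation is None or situation in m.situation_tags)
    ]
    if not pool:
        pool = [m for m in library.messages if "generic" in m.context_tags and m.phase_tag is None]
    if not pool:
        raise ValueError("no eligible message and no generic fallback in library")

    sent = set(history)
    unsent = [m for m in pool if m.id not in sent]
    cycle = unsent or pool  # exhausted -> reset the cycle
    # context match is a preference within the cycle, never a hard filter
    matching = [m for m in cycle if context in m.context_tags]
    cycle = sorted(matching or cycle, key=lambda m: m.id)
    rng = np.random.default_rng([int(seed), len(history)])
    return cycle[int(rng.integers(len(cycle)))]


def post_report_feedback(
    report: SmokingReport, state: EngineState, library: Optional[MessageLibrary] = None
) -> SupportMessage:
    """On-screen feedback after a smoking report, keyed to elevated context."""
    library = library or default_library()
    if report.urge_strength >= 4:
        want = "strong_urge"
    elif report.stress >= 4:
        want = "stress"
    elif report.mood <= 1:
        want = "low_mood"
    elif report.others_present:
        want = "others_present"
    else:
        want = "generic"
    stage_name = state.stage.value if state.stage.value != "stopped" else "maintenance"
    for m in library.messages:
        if (
            m.phase_tag is None
            and stage_name in m.stage_tags
            and report.situation.value in m.situation_tags
            and want in m.context_tags
        ):
            return m
    raise ValueError(f"library lacks a message for ({stage_name}, {report.situation}, {want})")


def morning_message(library: MessageLibrary, on: date, quit_date: date) -> SupportMessage:
    """The scheduled daily morning message; keyed to the signed day offset
    from the quit date, one fixed message per local day."""
    offset = (on - quit_date).days
    phase = "pre_quit" if offset < 0 else ("quit_day" if offset == 0 else "post_quit")
    pool = sorted((m for m in library.messages if m.phase_tag == phase), key=lambda m: m.id)
    if not pool:
        raise ValueError(f"library has no morning messages for phase {phase}")
    return pool[abs(offset) % len(pool)]


@dataclass(frozen=True)
class ProfileStats:
    days_quit: int
    money_saved: float


def profile_stats(
    quit_date: date, now: date, cigarettes_per_day: int, price_per_cigarette: float
) -> ProfileStats:
    """Days quit and money saved (days x cigarettes/day x price)."""
    days = max(0, (now - quit_date).days)
    return ProfileStats(days_quit=days, money_saved=days * cigarettes_per_day * price_per_cigarette)


_CRAVING_EMOJI = {0: "calm", 1: "calm", 2: "ok", 3: "ok", 4: "craving", 5: "craving"}


@dataclass(frozen=True)
class EndOfDayEntry:
    date: date
    smoked: bool
    craving_level: int
    self_efficacy: int
    emoji_code: str = field(init=False)

    def __post_init__(self) -> None:
        if self.craving_level not in range(6) or self.self_efficacy not in range(6):
            raise ValueError("ordinal fields must be in 0-5")
        smoke = "smoked" if self.smoked else "smokefree"
        crave = _CRAVING_EMOJI[self.craving_level]
        conf = "confident" if self.self_efficacy >= 3 else "shaky"
        object.__setattr__(self, "emoji_code", f"{smoke}/{crave}/{conf}")


def smoking_pattern_summary(reports: Iterable[SmokingReport]) -> dict:
    """Counts and proportions of reported smoking triggers.

    Breakdowns: situation, presence of other smokers, and high-urge /
    high-stress flags (ordinal >= 4).  Proportions within each breakdown
    sum to 1; an empty input yields an empty summary.
    """
    reports = list(reports)
    if not reports:
        return {}
    n = len(reports)

    def breakdown(counts: dict[str, int]) -> dict:
        return {
            "counts": counts,
            "proportions": {k: v / n for k, v in counts.items()},
        }

    situations: dict[str, int] = {}
    others: dict[str, int] = {"with_others": 0, "alone": 0}
    urge: dict[str, int] = {"high_urge": 0, "low_urge": 0}
    stress: dict[str, int] = {"high_stress": 0, "low_stress": 0}
    for r in reports:
        situations[r.situation.value] = situations.get(r.situation.value, 0) + 1
        others["with_others" if r.others_present else "alone"] += 1
        urge["high_urge" if r.urge_strength >= 4 else "low_urge"] += 1
        stress["high_stress" if r.stress >= 4 else "low_stress"] += 1
    return {
        "n": n,
        "situation": breakdown(situations),
        "others_present": breakdown(others),
        "urge": breakdown(urge),
        "stress": breakdown(stress),
    }
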