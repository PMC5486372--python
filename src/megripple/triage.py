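"""Ripple-time grouping, capped random review sets, and review decisions.

Automatic HFO detectors run with a deliberately high false-positive rate, so
every detection is triaged: detections that overlap in time across channels
are grouped into *ripple-times* (the unit of review and counting), at most
three member events per ripple-time are sampled for visual review, and the
reviewer's verdicts on the sample decide the whole group — a ripple-time is
accepted when strictly more than half of its reviewed events are judged true
(with a sample capped at three, that is the > 2/3 rule), and the decision
propagates to all member events including the unsampled ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .detector import RippleEvent

__all__ = [
    "RippleTime",
    "group_ripple_times",
    "build_review_set",
    "apply_review_decisions",
]

MAX_REVIEW_PER_RIPPLE_TIME = 3


@dataclass
class RippleTime:
    """A maximal set of temporally overlapping events across channels."""

    start_s: float
    end_s: float
    member_ids: list[int]  # indices into the event list passed at grouping
    review_ids: list[int] = field(default_factory=list)
    decision: str = "pending"  # accepted | rejected | pending

    @property
    def n_members(self) -> int:
        return len(self.member_ids)


def group_ripple_times(
    events: Sequence[RippleEvent], bridge_gap_s: float = 0.0
) -> list[RippleTime]:
    """Group events into ripple-times by transitive temporal overlap.

    Events on any channels whose [start_s, end_s) intervals overlap (share at
    least one instant; optionally bridged by ``bridge_gap_s``) belong to the
    same ripple-time, whose interval is the union span of its members.
    Returned sorted by start time; ``member_ids`` index into ``events``.
    """
    if not events:
        return []
    order = sorted(range(len(events)), key=lambda i: (events[i].start_s, events[i].end_s))
    groups: list[RippleTime] = []
    current_ids = [order[0]]
    cur_start = events[order[0]].start_s
    cur_end = events[order[0]].end_s
    for idx in order[1:]:
        ev = events[idx]
        if ev.start_s < cur_end + bridge_gap_s:
            current_ids.append(idx)
            cur_end = max(cur_end, ev.end_s)
        else:
            groups.append(
                RippleTime(start_s=cur_start, end_s=cur_end, member_ids=current_ids)
            )
            current_ids = [idx]
            cur_start, cur_end = ev.start_s, ev.end_s
    groups.append(RippleTime(start_s=cur_start, end_s=cur_end, member_ids=current_ids))
    return groups


def build_review_set(
    ripple_times: Sequence[RippleTime],
    rng: Union[int, np.random.Generator, None] = 0,
    max_per_time: int = MAX_REVIEW_PER_RIPPLE_TIME,
) -> list[RippleTime]:
    """Sample at most ``max_per_time`` member events per ripple-time for
    review, uniformly without replacement; deterministic given the seed."""
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    for rt in ripple_times:
        k = min(max_per_time, rt.n_members)
        chosen = rng.choice(len(rt.member_ids), size=k, replace=False)
        rt.review_ids = [rt.member_ids[i] for i in sorted(chosen)]
    return list(ripple_times)


def apply_review_decisions(
    ripple_times: Sequence[RippleTime],
    decisions: dict[int, bool],
    events: Optional[Sequence[RippleEvent]] = None,
) -> tuple[list[int], list[int]]:
    """Propagate reviewer verdicts from the sampled events to whole groups.

    A ripple-time is accepted iff strictly more than half of its reviewed
    events were judged true; the decision applies to every member event.
    Returns (accepted_event_ids, rejected_event_ids). If ``events`` is given,
    each event's ``accepted`` flag is updated in place.
    """
    missing = [
        ev_id
        for rt in ripple_times
        for ev_id in rt.review_ids
        if ev_id not in decisions
    ]
    if missing:
        raise ValueError(f"missing review verdicts for event ids: {sorted(set(missing))}")
    accepted: list[int] = []
    rejected: list[int] = []
    for rt in ripple_times:
        if not rt.review_ids:
            rt.decision = "pending"
            continue
        verdicts = [decisions[i] for i in rt.review_ids]
        ok = sum(verdicts) > len(verdicts) / 2.0  # strictly more than half
        rt.decision = "accepted" if ok else "rejected"
        (accepted if ok else rejected).extend(rt.member_ids)
    if events is not None:
        for i in accepted:
            events[i].accepted = True
        for i in rejected:
            events[i].accepted = False
    return accepted, rejected
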