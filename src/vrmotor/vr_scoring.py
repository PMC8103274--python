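"""Scoring of the two non-tremor VR tasks.

VR Time: seconds to slice three food items (bread, carrot, cucumber) with a
virtual knife, recorded per hand over two attempts — a bradykinesia proxy.

VR ADL Score: a virtual mug holding ten liquid cylinders is carried across a
table; tilting the mug past a threshold spills cylinders.  The score is the
number of cylinders (0-10) remaining when the mug is set down, averaged over
five attempts per hand.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .errors import AnalysisError, MalformedLogError

FOOD_ITEMS = ("bread", "carrot", "cucumber")

#: default tilt-from-vertical threshold beyond which liquid spills, degrees
DEFAULT_TILT_THRESHOLD_DEG = 30.0

N_CYLINDERS = 10
N_ADL_ATTEMPTS = 5
N_SLICE_ATTEMPTS = 2


@dataclass(frozen=True)
class SliceEvent:
    t: float
    kind: str  # session_start | item_cut | session_end
    item: str | None = None  # set for item_cut events


@dataclass(frozen=True)
class SliceSessionLog:
    """Ordered event log of one food-slicing attempt for one hand."""

    hand: str
    attempt_index: int
    events: tuple[SliceEvent, ...]

    def __post_init__(self):
        object.__setattr__(self, "events", tuple(self.events))
        ts = [e.t for e in self.events]
        if any(b < a for a, b in zip(ts, ts[1:])):
            raise MalformedLogError("slice log events are out of time order")
        for e in self.events:
            if e.kind not in ("session_start", "item_cut", "session_end"):
                raise MalformedLogError(f"unknown event kind {e.kind!r}")
            if e.kind == "item_cut" and e.item not in FOOD_ITEMS:
                raise MalformedLogError(f"unknown food item {e.item!r}")


@dataclass(frozen=True)
class SpillRule:
    """Drain dynamics: one cylinder lost per ``drain_s`` seconds of cumulative
    time spent beyond the tilt threshold (quantised; the remainder carries
    across exceedance episodes)."""

    drain_s: float = 0.25

    def __post_init__(self):
        if self.drain_s <= 0:
            raise AnalysisError("SpillRule.drain_s must be positive")


@dataclass(frozen=True)
class ADLAttempt:
    """One mug-carry attempt: the tilt trajectory and its resulting score."""

    hand: str
    attempt_index: int  # 1..5
    mug_index: int  # 1..5
    t: np.ndarray
    tilt_deg: np.ndarray
    cylinders_remaining: int | None = None

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        tilt = np.asarray(self.tilt_deg, dtype=float)
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "tilt_deg", tilt)
        if t.size != tilt.size or t.size == 0:
            raise AnalysisError("tilt series must be nonempty and aligned with t")
        if np.any(np.diff(t) < 0):
            raise AnalysisError("tilt timestamps must be nondecreasing")
        if np.any((tilt < 0) | (tilt > 180)):
            raise AnalysisError("tilt angles must lie in [0, 180] degrees")
        if self.cylinders_remaining is not None and not (
            0 <= self.cylinders_remaining <= N_CYLINDERS
        ):
            raise AnalysisError("cylinders_remaining must lie in [0, 10]")


@dataclass(frozen=True)
class VRHandSummary:
    """Per-hand summary of the two non-tremor VR measures."""

    hand: str
    vr_time: float  # seconds
    vr_adl_score: float  # mean of 5 attempt scores, in [0, 10]


def compute_vr_time(log: SliceSessionLog) -> float:
    """Elapsed seconds from session_start to session_end of one attempt."""
    starts = [e.t for e in log.events if e.kind == "session_start"]
    ends = [e.t for e in log.events if e.kind == "session_end"]
    if not starts or not ends:
        raise MalformedLogError("slice log is missing session_start/session_end")
    span = ends[-1] - starts[0]
    if span < 0:
        raise MalformedLogError("session_end precedes session_start")
    if span == 0:
        warnings.warn("zero-duration slicing session", stacklevel=2)
    return float(span)


def aggregate_vr_time(durations, mode: str = "mean") -> float:
    """Reduce per-attempt slicing durations to one per-hand VR Time.

    ``mode``: ``mean`` (default), ``best`` (shortest) or ``sum``.
    """
    durations = list(durations)
    if not durations:
        raise AnalysisError("no slicing durations to aggregate")
    if mode == "mean":
        return float(np.mean(durations))
    if mode == "best":
        return float(np.min(durations))
    if mode == "sum":
        return float(np.sum(durations))
    raise AnalysisError(f"unknown VR Time aggregate mode {mode!r}")


def exceedance_time(t, tilt_deg, threshold_deg: float) -> float:
    """Total seconds spent above the tilt threshold.

    Sample-and-hold convention: the interval [t_i, t_{i+1}) counts as
    exceedance iff sample i is above threshold; the final sample carries no
    duration.
    """
    t = np.asarray(t, dtype=float)
    tilt = np.asarray(tilt_deg, dtype=float)
    if t.size == 0:
        raise AnalysisError("empty tilt series")
    if threshold_deg <= 0:
        raise AnalysisError("threshold_deg must be positive")
    if t.size == 1:
        return 0.0
    dt = np.diff(t)
    return float(np.sum(dt[tilt[:-1] > threshold_deg]))


def score_adl_attempt(
    t,
    tilt_deg,
    threshold_deg: float = DEFAULT_TILT_THRESHOLD_DEG,
    spill_rule: SpillRule = SpillRule(),
) -> int:
    """Cylinders (0-10) left in the mug after one carry attempt.

    The mug starts with 10 cylinders; one cylinder drains per ``drain_s``
    seconds of cumulative threshold exceedance (partial quanta carry across
    episodes but never drain a cylinder on their own).
    """
    total = exceedance_time(t, tilt_deg, threshold_deg)
    lost = min(N_CYLINDERS, int(math.floor(total / spill_rule.drain_s + 1e-12)))
    return N_CYLINDERS - lost


def aggregate_adl(scores, hand: str) -> VRHandSummary:
    """Mean of exactly five per-attempt ADL scores for one hand.

    The VR Time slot of the returned summary is nan; use
    :func:`make_hand_summary` to fill both measures.
    """
    scores = list(scores)
    if len(scores) != N_ADL_ATTEMPTS:
        raise AnalysisError(
            f"expected exactly {N_ADL_ATTEMPTS} ADL scores, got {len(scores)}"
        )
    for s in scores:
        if not 0 <= s <= N_CYLINDERS:
            raise AnalysisError(f"ADL score {s} outside [0, {N_CYLINDERS}]")
    return VRHandSummary(hand=hand, vr_time=math.nan, vr_adl_score=float(np.mean(scores)))


def make_hand_summary(
    hand: str,
    slice_logs,
    adl_attempts,
    time_mode: str = "mean",
    threshold_deg: float = DEFAULT_TILT_THRESHOLD_DEG,
    spill_rule: SpillRule = SpillRule(),
) -> VRHandSummary:
    """Score a hand's full VR session: slicing logs + ADL attempts."""
    durations = [compute_vr_time(log) for log in slice_logs]
    scores = [
        score_adl_attempt(a.t, a.tilt_deg, threshold_deg, spill_rule)
        for a in adl_attempts
    ]
    adl = aggregate_adl(scores, hand)
    return VRHandSummary(
        hand=hand,
        vr_time=aggregate_vr_time(durations, time_mode),
        vr_adl_score=adl.vr_adl_score,
    )
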