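"""Bout segmentation and per-session behavioral metrics.

A *bout* is a stretch of work between lever availability and the next
reset-lever press — the operant analog of a patch residence.  PRR sessions
are split into bouts at reset presses; in PR sessions the reset lever has no
programmed consequence, so the whole session is a single (incomplete) bout.

Press counting follows the task contingency: the reward light is lit from
reward delivery until the magazine entry that collects it, and active
presses made while it is lit are logged but do not advance the ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Optional

import numpy as np

from .session import EventLog

__all__ = [
    "Bout",
    "SessionMetrics",
    "CumulativeRecord",
    "SegmentationError",
    "segment_bouts",
    "compute_session_metrics",
    "cumulative_record",
]


class SegmentationError(Exception):
    """Event stream inconsistent with the task contingency."""


@dataclass(frozen=True)
class Bout:
    """One bout of work.

    ``rewards`` equals the highest ratio completed within the bout (the
    requirement starts at 1 and increments by 1 per reward, so the k-th
    reward completes ratio k).
    """

    index: int
    start_t: float
    end_t: float
    rewards: int
    active_presses: int
    complete: bool


@dataclass
class SessionMetrics:
    """Per-session summary of counts, rates and latencies.

    ``press_rate`` is the active-lever work tempo in presses/s; see
    :func:`compute_session_metrics` for the estimator.  Medians are ``None``
    when no qualifying observations exist (e.g. a session with no rewards).
    ``breakpoint`` — the highest successfully completed ratio — is defined
    for PR sessions only.
    """

    active_presses: int
    reset_presses: int
    pellets: int
    press_rate: Optional[float]
    median_reward_latency_s: Optional[float]
    median_work_latency_s: Optional[float]
    median_bout_length: Optional[float]
    n_bouts_complete: int
    breakpoint: Optional[int]
    reset_latencies_s: list[float] = field(default_factory=list)


@dataclass
class CumulativeRecord:
    """Step series of cumulative active presses with reward marks."""

    start_t: float
    press_times: np.ndarray
    counts: np.ndarray
    reward_times: np.ndarray


def _counting_flags(log: EventLog) -> list[bool]:
    """For each active_press (in order), whether it counts toward the ratio.

    A press is non-counting while the reward light is on, i.e. between a
    reward delivery and the magazine entry that collects it.
    """
    flags: list[bool] = []
    light_on = False
    for e in log.events:
        if e.kind == "reward_delivered":
            light_on = True
        elif e.kind == "magazine_entry":
            light_on = False
        elif e.kind == "active_press":
            flags.append(not light_on)
    return flags


def segment_bouts(log: EventLog) -> list[Bout]:
    """Split a session into bouts of work.

    PRR: one bout per ``levers_extended`` episode, running to the next
    reset press (complete) or to session end (incomplete).  PR: exactly one
    bout spanning the session; reset presses are inconsequential and do not
    split it.
    """
    ev = log.events
    end_time = log.meta.duration_s
    is_prr = log.meta.task == "PRR"

    if is_prr:
        # Each reset press triggers retraction; the retraction is logged at
        # the same timestamp (canonically sorted before the press) or as the
        # next event.
        retract_t = {e.t for e in ev if e.kind == "levers_retracted"}
        for i, e in enumerate(ev):
            if e.kind == "reset_press":
                nxt = next((x for x in ev[i + 1:] if x.kind != "reset_press"), None)
                ok = e.t in retract_t or (nxt is not None and nxt.kind == "levers_retracted")
                if not ok:
                    raise SegmentationError(
                        f"PRR reset_press@{e.t} not followed by levers_retracted"
                    )

    # Bout boundaries as (start_t, end_t, complete).
    bounds: list[tuple[float, float, bool]] = []
    if not is_prr:
        start = next((e.t for e in ev if e.kind == "levers_extended"), 0.0)
        bounds.append((start, end_time, False))
    else:
        start_t: Optional[float] = None
        for e in ev:
            if e.kind == "levers_extended":
                start_t = e.t
            elif e.kind == "reset_press" and start_t is not None:
                bounds.append((start_t, e.t, True))
                start_t = None
        if start_t is not None:
            bounds.append((start_t, end_time, False))

    bouts: list[Bout] = []
    for idx, (s, t_end, complete) in enumerate(bounds):
        rewards = sum(1 for e in ev if e.kind == "reward_delivered" and s < e.t <= t_end)
        presses = sum(1 for e in ev if e.kind == "active_press" and s < e.t <= t_end)
        bouts.append(Bout(index=idx, start_t=s, end_t=t_end,
                          rewards=rewards, active_presses=presses, complete=complete))
    return bouts


def _within_ratio_ipis(log: EventLog) -> list[float]:
    """Intervals between consecutive counting presses with no intervening
    reward — pure inter-press intervals during ratio work."""
    ipis: list[float] = []
    flags = iter(_counting_flags(log))
    prev_press_t: Optional[float] = None
    for e in log.events:
        if e.kind in ("reward_delivered", "levers_extended", "levers_retracted"):
            prev_press_t = None
        elif e.kind == "active_press":
            counting = next(flags)
            if counting:
                if prev_press_t is not None:
                    ipis.append(e.t - prev_press_t)
                prev_press_t = e.t
            # Non-counting presses interrupt nothing: light-on pauses are
            # already excluded by the reward_delivered reset above.
        elif e.kind == "magazine_entry":
            prev_press_t = None
    return ipis


def _lever_available_time(log: EventLog) -> float:
    """Session duration minus time the levers were retracted."""
    retracted = 0.0
    t_retract: Optional[float] = None
    for e in log.events:
        if e.kind == "levers_retracted":
            t_retract = e.t
        elif e.kind == "levers_extended" and t_retract is not None:
            retracted += e.t - t_retract
            t_retract = None
    if t_retract is not None:
        retracted += log.meta.duration_s - t_retract
    return log.meta.duration_s - retracted


def compute_session_metrics(
    log: EventLog,
    bouts: Optional[list[Bout]] = None,
    rate_mode: str = "ipi",
) -> SessionMetrics:
    """Compute the per-session behavioral summary.

    Latencies: reward-collection latency is magazine entry minus reward
    delivery, one value per collected reward; return-to-work latency is the
    first counting press after a magazine entry minus that entry, computed
    only when pressing resumes within the same bout.  Session values are
    medians (midpoint convention for even counts).

    ``rate_mode`` selects the press-rate estimator:

    - ``"ipi"`` (default): reciprocal of the mean within-ratio inter-press
      interval.  Excludes post-reward handling pauses and reset delays, so
      it estimates the chosen work tempo rather than throughput.
    - ``"lever_available"``: counting presses divided by lever-available
      time (session duration minus retraction time).
    - ``"session"``: counting presses divided by session duration.

    When ``"ipi"`` is requested but the session has no within-ratio
    intervals (fewer than two counting presses per ratio throughout), the
    lever-available estimator is used as a fallback.
    """
    if bouts is None:
        bouts = segment_bouts(log)
    ev = log.events
    if rate_mode not in ("ipi", "lever_available", "session"):
        raise ValueError(f"unknown rate_mode {rate_mode!r}")

    active_presses = sum(1 for e in ev if e.kind == "active_press")
    reset_presses = sum(1 for e in ev if e.kind == "reset_press")
    pellets = sum(1 for e in ev if e.kind == "reward_delivered")
    n_counting = sum(_counting_flags(log))

    # Reward-collection latencies: match each reward to the single magazine
    # entry before the next reward (if any).
    reward_lat: list[float] = []
    t_reward: Optional[float] = None
    for e in ev:
        if e.kind == "reward_delivered":
            t_reward = e.t
        elif e.kind == "magazine_entry" and t_reward is not None:
            reward_lat.append(e.t - t_reward)
            t_reward = None

    # Return-to-work latencies: magazine entry → next counting press, same bout.
    bout_end = {b.start_t: b.end_t for b in bouts}
    work_lat: list[float] = []
    flags = iter(_counting_flags(log))
    pending_mag: Optional[float] = None
    current_end: float = bouts[0].end_t if bouts else log.meta.duration_s
    for e in ev:
        if e.kind == "levers_extended" and e.t in bout_end:
            current_end = bout_end[e.t]
            pending_mag = None
        elif e.kind == "magazine_entry":
            pending_mag = e.t
        elif e.kind == "active_press":
            counting = next(flags)
            if counting and pending_mag is not None and e.t <= current_end:
                work_lat.append(e.t - pending_mag)
                pending_mag = None
        elif e.kind == "reset_press":
            pending_mag = None

    press_rate: Optional[float] = None
    if n_counting > 0:
        ipis = _within_ratio_ipis(log) if rate_mode == "ipi" else []
        if ipis:
            press_rate = len(ipis) / sum(ipis)
        elif rate_mode == "session":
            press_rate = n_counting / log.meta.duration_s
        else:
            avail = _lever_available_time(log)
            press_rate = n_counting / avail if avail > 0 else None

    complete = [b for b in bouts if b.complete]
    reset_latencies = [b.end_t - b.start_t for b in complete]
    median_bout = median([b.rewards for b in complete]) if complete else None

    return SessionMetrics(
        active_presses=active_presses,
        reset_presses=reset_presses,
        pellets=pellets,
        press_rate=press_rate,
        median_reward_latency_s=median(reward_lat) if reward_lat else None,
        median_work_latency_s=median(work_lat) if work_lat else None,
        median_bout_length=float(median_bout) if median_bout is not None else None,
        n_bouts_complete=len(complete),
        breakpoint=pellets if log.meta.task == "PR" else None,
        reset_latencies_s=reset_latencies,
    )


def cumulative_record(log: EventLog, per_bout: bool = False) -> list[CumulativeRecord]:
    """Cumulative active-press step series, whole-session or restarting per bout.

    Every logged active press advances the counter (the cumulative record
    reflects the raw behavioral stream, counting and non-counting alike).
    """
    press_t = np.array([e.t for e in log.events if e.kind == "active_press"])
    reward_t = np.array([e.t for e in log.events if e.kind == "reward_delivered"])
    if not per_bout:
        return [CumulativeRecord(
            start_t=0.0,
            press_times=press_t,
            counts=np.arange(1, len(press_t) + 1),
            reward_times=reward_t,
        )]
    out = []
    for b in segment_bouts(log):
        sel = (press_t > b.start_t) & (press_t <= b.end_t)
        rsel = (reward_t > b.start_t) & (reward_t <= b.end_t)
        pts = press_t[sel]
        out.append(CumulativeRecord(
            start_t=b.start_t,
            press_times=pts,
            counts=np.arange(1, len(pts) + 1),
            reward_times=reward_t[rsel],
        ))
    return out
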