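"""Generative simulator for PR and PRR sessions.

Couples a task state machine (progressive ratio, reward light, reset lever,
lever retraction during the reset delay) to a stochastic rat agent with
trait parameters: a work tempo (gamma-renewal inter-press intervals), a
reward-collection latency and a return-to-work latency (lognormal, specified
by median and dispersion), and a bout policy deciding how many rewards to
earn before pressing the reset lever.

The generative process per bout: the first press occurs one inter-press
interval after lever extension; each subsequent press of a ratio follows one
inter-press interval; a completed ratio delivers a reward immediately, the
magazine entry follows one reward latency later, and the next press — or the
reset press, if the bout policy's target is reached — follows one
return-to-work latency after the magazine entry.

All draws come from a single RNG stream derived from ``(seed, session_id)``,
so a session is reproducible independent of anything else generated in the
same run.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .optimality import OptimalityParams, optimal_bout_length
from .session import Event, EventLog, SessionMeta, canonical_sort

__all__ = [
    "LatencySpec",
    "BoutPolicy",
    "AgentParams",
    "SubjectRanges",
    "simulate_session",
    "simulate_cohort",
]


@dataclass(frozen=True)
class LatencySpec:
    """Lognormal latency: ``median_s`` seconds, ``dispersion`` = sigma of
    log-latency.  dispersion = 0 degenerates to the constant ``median_s``."""

    median_s: float
    dispersion: float = 0.4

    def __post_init__(self) -> None:
        if self.median_s <= 0:
            raise ValueError("median_s must be > 0")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")

    def draw(self, rng: np.random.Generator) -> float:
        if self.dispersion == 0:
            return self.median_s
        return float(rng.lognormal(math.log(self.median_s), self.dispersion))


@dataclass(frozen=True)
class BoutPolicy:
    """How many rewards to earn before pressing the reset lever.

    kinds
        ``fixed``: always ``N`` rewards.
        ``jittered``: ``N`` plus a uniform integer in [-jitter, +jitter],
        drawn per bout.
        ``optimal_plus_bias``: the rate-maximizing bout length for the
        agent's own generative press rate and the session's reset delay
        (handling time ``handling_time_s``), plus ``bias``, plus optional
        per-bout jitter.  Positive bias produces overharvesting by
        construction.
    Targets are clipped below at 1.
    """

    kind: str = "fixed"
    N: Optional[int] = None
    bias: int = 0
    jitter: int = 0
    handling_time_s: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "jittered", "optimal_plus_bias"):
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.kind in ("fixed", "jittered"):
            if self.N is None or self.N < 1:
                raise ValueError(f"{self.kind} policy requires N >= 1")
        if self.jitter < 0:
            raise ValueError("jitter must be >= 0")

    def base_target(self, press_rate: float, reset_delay_s: Optional[float]) -> int:
        """Per-session deterministic part of the target (before jitter)."""
        if self.kind in ("fixed", "jittered"):
            return int(self.N)  # type: ignore[arg-type]
        if reset_delay_s is None:
            raise ValueError("optimal_plus_bias policy requires a reset delay")
        n_opt = optimal_bout_length(OptimalityParams(
            press_rate=press_rate, reset_delay_s=reset_delay_s,
            handling_time_s=self.handling_time_s)).n_opt
        return max(1, n_opt + self.bias)

    def draw_target(self, rng: np.random.Generator, press_rate: float,
                    reset_delay_s: Optional[float]) -> int:
        base = self.base_target(press_rate, reset_delay_s)
        if self.kind == "fixed" or self.jitter == 0:
            return base
        return max(1, base + int(rng.integers(-self.jitter, self.jitter + 1)))


@dataclass(frozen=True)
class AgentParams:
    """Generative trait parameters of one simulated rat.

    ``press_rate`` is the mean pressing tempo (presses/s); inter-press
    intervals are gamma with shape ``ipi_shape`` and mean ``1/press_rate``
    (``ipi_shape = inf`` degenerates to constant intervals, used for
    hand-checkable traces).  ``nonfunctional_press_rate`` is the rate of
    inconsequential reset presses emitted during PR sessions, per minute.
    ``pr_stop_ratio``: in PR sessions the agent quiesces once the ratio
    requirement exceeds this value (None = work until session end).
    """

    press_rate: float
    ipi_shape: float = 3.0
    reward_latency: LatencySpec = field(default_factory=lambda: LatencySpec(0.7))
    work_latency: LatencySpec = field(default_factory=lambda: LatencySpec(2.4))
    bout_policy: BoutPolicy = field(default_factory=lambda: BoutPolicy(kind="fixed", N=4))
    nonfunctional_press_rate: float = 1.8
    pr_stop_ratio: Optional[int] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.press_rate <= 0:
            raise ValueError("press_rate must be > 0")
        if not (self.ipi_shape > 0):
            raise ValueError("ipi_shape must be > 0 (inf allowed)")
        if self.nonfunctional_press_rate < 0:
            raise ValueError("nonfunctional_press_rate must be >= 0")

    def draw_ipi(self, rng: np.random.Generator) -> float:
        if math.isinf(self.ipi_shape):
            return 1.0 / self.press_rate
        return float(rng.gamma(self.ipi_shape,
                               1.0 / (self.press_rate * self.ipi_shape)))


def _session_rng(seed: int, session_id: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                zlib.crc32(session_id.encode("utf-8"))]))


def simulate_session(meta: SessionMeta, agent: AgentParams) -> EventLog:
    """Simulate one session event-by-event; deterministic under fixed seed.

    The returned log always passes :func:`prrforage.session.validate`.
    Activity in progress when the clock reaches ``meta.duration_s`` is
    truncated: no event is emitted past session end.
    """
    rng = _session_rng(agent.seed, meta.session_id)
    dur = meta.duration_s
    functional = meta.task == "PRR"
    events: list[Event] = [Event(0.0, "session_start"), Event(0.0, "levers_extended")]

    def emit(t: float, kind: str) -> bool:
        if t > dur:
            return False
        events.append(Event(t, kind))
        return True

    # PR: inconsequential reset presses as a Poisson process over the session,
    # drawn up front so the main loop's draw order is unaffected.
    if not functional and agent.nonfunctional_press_rate > 0:
        rate_per_s = agent.nonfunctional_press_rate / 60.0
        t = 0.0
        while True:
            t += float(rng.exponential(1.0 / rate_per_s))
            if t > dur:
                break
            events.append(Event(t, "reset_press"))

    t_ext = 0.0
    stopped = False
    while not stopped:
        ratio, presses, rewards_in_bout = 1, 0, 0
        target = (agent.bout_policy.draw_target(rng, agent.press_rate, meta.reset_delay_s)
                  if functional else None)
        t_next = t_ext + agent.draw_ipi(rng)
        bout_over = False
        while not bout_over:
            if not emit(t_next, "active_press"):
                stopped = True
                break
            presses += 1
            if presses < ratio:
                t_next += agent.draw_ipi(rng)
                continue
            emit(t_next, "reward_delivered")
            rewards_in_bout += 1
            t_mag = t_next + agent.reward_latency.draw(rng)
            if not emit(t_mag, "magazine_entry"):
                stopped = True
                break
            t_resume = t_mag + agent.work_latency.draw(rng)
            if functional and rewards_in_bout == target:
                if not emit(t_resume, "reset_press"):
                    stopped = True
                    break
                events.append(Event(t_resume, "levers_retracted"))
                t_ext = t_resume + float(meta.reset_delay_s)
                if not emit(t_ext, "levers_extended"):
                    stopped = True
                    break
                bout_over = True
            else:
                ratio += 1
                presses = 0
                if (not functional and agent.pr_stop_ratio is not None
                        and ratio > agent.pr_stop_ratio):
                    stopped = True
                    break
                t_next = t_resume

    events.append(Event(dur, "session_end"))
    return EventLog(meta=meta, events=canonical_sort(events))


@dataclass(frozen=True)
class SubjectRanges:
    """Uniform ranges from which per-subject trait parameters are drawn.

    Defaults emulate the study conditions: press rates spanning ~0.4–1.6
    presses/s across rats, reward-collection latency medians near 0.7 s,
    PRR return-to-work latency medians near 2.4 s, with PR return-to-work
    latencies slower by ``pr_work_latency_extra_s`` (PR medians ~3.5–5.8 s).
    """

    press_rate: tuple[float, float] = (0.4, 1.6)
    reward_latency_median_s: tuple[float, float] = (0.5, 0.9)
    work_latency_median_s: tuple[float, float] = (1.8, 3.0)
    pr_work_latency_extra_s: float = 2.7
    ipi_shape: float = 3.0
    latency_dispersion: float = 0.4

    def __post_init__(self) -> None:
        for name in ("press_rate", "reward_latency_median_s", "work_latency_median_s"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")


_DEFAULT_TASKS: tuple[tuple[str, Optional[float]], ...] = (
    ("PR", None), ("PRR", 10.0), ("PRR", 60.0))


def simulate_cohort(
    n_subjects: int,
    tasks=_DEFAULT_TASKS,
    sessions_per_task: int = 1,
    duration_s: float = 2700.0,
    ranges: SubjectRanges = SubjectRanges(),
    bout_policy: BoutPolicy = BoutPolicy(kind="fixed", N=4),
    pr_stop_ratio: Optional[int | str] = None,
    seed: int = 0,
) -> tuple[list[EventLog], pd.DataFrame]:
    """Simulate a cohort: per-subject traits drawn once, reused across tasks.

    Trait persistence across tasks is what makes cross-task correlations of
    bout length recoverable.  ``pr_stop_ratio`` controls PR quiescence: an
    integer applies to every subject, ``None`` lets agents work to session
    end, and ``"trait"`` derives each subject's stopping ratio from the bout
    policy evaluated at the subject's own press rate with a 60 s reference
    delay — tying the PR breakpoint to the same trait that drives PRR bout
    lengths.  Returns the logs plus a ground-truth table
    (one row per session) with the generative press rate, latency medians,
    the bout policy's per-session base target, and — for PRR sessions — the
    rate-maximizing bout length implied by the generative press rate.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    master = np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC04057]))
    logs: list[EventLog] = []
    rows: list[dict] = []
    for s in range(n_subjects):
        subject_id = f"rat{s:03d}"
        sex = "male" if master.random() < 0.5 else "female"
        p = float(master.uniform(*ranges.press_rate))
        rew_m = float(master.uniform(*ranges.reward_latency_median_s))
        work_m = float(master.uniform(*ranges.work_latency_median_s))
        for task, delay in tasks:
            for k in range(sessions_per_task):
                session_id = f"{subject_id}_{task}" + (f"-{delay:g}" if delay else "") + f"_s{k}"
                meta = SessionMeta(subject_id=subject_id, sex=sex, task=task,
                                   session_id=session_id, reset_delay_s=delay,
                                   duration_s=duration_s)
                wl = work_m + (ranges.pr_work_latency_extra_s if task == "PR" else 0.0)
                if pr_stop_ratio == "trait":
                    stop = bout_policy.base_target(p, 60.0) if task == "PR" else None
                else:
                    stop = pr_stop_ratio if task == "PR" else None
                agent = AgentParams(
                    press_rate=p,
                    ipi_shape=ranges.ipi_shape,
                    reward_latency=LatencySpec(rew_m, ranges.latency_dispersion),
                    work_latency=LatencySpec(wl, ranges.latency_dispersion),
                    bout_policy=bout_policy,
                    pr_stop_ratio=stop,
                    seed=int(master.integers(0, 2**31 - 1)),
                )
                logs.append(simulate_session(meta, agent))
                if task == "PRR":
                    n_opt = optimal_bout_length(OptimalityParams(
                        press_rate=p, reset_delay_s=float(delay),
                        handling_time_s=bout_policy.handling_time_s)).n_opt
                    target = bout_policy.base_target(p, delay)
                else:
                    n_opt, target = None, None
                rows.append(dict(subject_id=subject_id, session_id=session_id,
                                 sex=sex, task=task, reset_delay_s=delay,
                                 press_rate=p, reward_latency_median_s=rew_m,
                                 work_latency_median_s=wl,
                                 policy_kind=bout_policy.kind,
                                 policy_target=target, bias=bout_policy.bias,
                                 n_opt=n_opt))
    return logs, pd.DataFrame(rows)
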