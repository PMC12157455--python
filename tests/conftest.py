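"""Shared fixtures: hand-built toy sessions and degenerate-agent simulations."""

import math

import pytest

from prrforage import (
    AgentParams, BoutPolicy, Event, EventLog, LatencySpec, SessionMeta,
)


def make_log(meta: SessionMeta, rows) -> EventLog:
    """Build an EventLog from (t, kind) tuples."""
    return EventLog(meta=meta, events=[Event(t, k) for t, k in rows])


@pytest.fixture
def toy_prr_log() -> EventLog:
    """Hand-constructed two-bout PRR-10 session.

    Bout 1: ratio 1 (press@1 → reward), ratio 2 (presses@3,4 → reward),
    reset@6; levers back at 16.  Bout 2: one reward@17, runs to session
    end (incomplete).  All latencies hand-computable.
    """
    meta = SessionMeta(subject_id="toy", task="PRR", session_id="toy-1",
                       reset_delay_s=10.0, duration_s=300.0)
    return make_log(meta, [
        (0.0, "session_start"),
        (0.0, "levers_extended"),
        (1.0, "active_press"),
        (1.0, "reward_delivered"),
        (1.5, "magazine_entry"),
        (3.0, "active_press"),
        (4.0, "active_press"),
        (4.0, "reward_delivered"),
        (4.5, "magazine_entry"),
        (6.0, "levers_retracted"),
        (6.0, "reset_press"),
        (16.0, "levers_extended"),
        (17.0, "active_press"),
        (17.0, "reward_delivered"),
        (300.0, "session_end"),
    ])


@pytest.fixture
def toy_pr_log() -> EventLog:
    """PR session completing ratios 1..5 then quiescing; five
    inconsequential reset presses sprinkled through."""
    meta = SessionMeta(subject_id="toy", task="PR", session_id="toy-pr",
                       duration_s=2700.0)
    rows = [(0.0, "session_start"), (0.0, "levers_extended")]
    t = 0.0
    for ratio in range(1, 6):
        for _ in range(ratio):
            t += 1.0
            rows.append((t, "active_press"))
        rows.append((t, "reward_delivered"))
        rows.append((t + 0.5, "magazine_entry"))
        t += 2.0
    for tr in (100.0, 200.0, 300.0, 400.0, 500.0):
        rows.append((tr, "reset_press"))
    rows.append((2700.0, "session_end"))
    return make_log(meta, rows)


@pytest.fixture
def degenerate_agent() -> AgentParams:
    """Zero-variance agent: IPI 1 s, reward latency 0.5 s, work latency 1 s,
    two rewards per bout — every event time is closed-form computable."""
    return AgentParams(
        press_rate=1.0,
        ipi_shape=math.inf,
        reward_latency=LatencySpec(0.5, 0.0),
        work_latency=LatencySpec(1.0, 0.0),
        bout_policy=BoutPolicy(kind="fixed", N=2),
        seed=1,
    )


@pytest.fixture
def prr10_meta() -> SessionMeta:
    return SessionMeta(subject_id="r1", task="PRR", session_id="sim-1",
                       reset_delay_s=10.0, duration_s=100.0)
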