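"""Task/agent simulator: hand-checkable traces, determinism, ground truth."""

import math

import numpy as np
import pytest

from prrforage import (
    AgentParams, BoutPolicy, LatencySpec, SessionMeta, SubjectRanges,
    compute_session_metrics, segment_bouts, simulate_cohort, simulate_session,
    validate,
)


class TestDegenerateTrace:
    def test_first_bout_event_times_match_hand_simulation(self, prr10_meta,
                                                          degenerate_agent):
        log = simulate_session(prr10_meta, degenerate_agent)
        expected = [
            (0.0, "session_start"),
            (0.0, "levers_extended"),
            (1.0, "active_press"),     # first press one IPI after extension
            (1.0, "reward_delivered"),
            (1.5, "magazine_entry"),
            (2.5, "active_press"),     # work latency after collection
            (3.5, "active_press"),     # one IPI later completes ratio 2
            (3.5, "reward_delivered"),
            (4.0, "magazine_entry"),
            (5.0, "levers_retracted"),
            (5.0, "reset_press"),      # work latency after final collection
            (15.0, "levers_extended"),  # 10 s reset delay
        ]
        got = [(e.t, e.kind) for e in log.events[:len(expected)]]
        assert got == expected

    @pytest.mark.parametrize("N", [1, 2, 3, 5])
    def test_degenerate_reset_latency_closed_form(self, N):
        """With constant IPI, reward and work latencies, the reset latency of
        an N-reward bout is IPI·(1 + N(N−1)/2) + N·(reward + work latency):
        one IPI for the bout's first press, an IPI for every further press,
        and one collection + return interval per reward (the last return
        interval precedes the reset press itself)."""
        ipi, rew, work = 1.0, 0.5, 1.0
        meta = SessionMeta(subject_id="r", task="PRR", session_id=f"n{N}",
                           reset_delay_s=10.0, duration_s=600.0)
        agent = AgentParams(press_rate=1.0 / ipi, ipi_shape=math.inf,
                            reward_latency=LatencySpec(rew, 0.0),
                            work_latency=LatencySpec(work, 0.0),
                            bout_policy=BoutPolicy(kind="fixed", N=N), seed=0)
        m = compute_session_metrics(simulate_session(meta, agent))
        expected = ipi * (1 + N * (N - 1) / 2) + N * (rew + work)
        assert m.reset_latencies_s
        assert all(lat == pytest.approx(expected) for lat in m.reset_latencies_s)


class TestContracts:
    def test_same_seed_same_log(self, prr10_meta):
        agent = AgentParams(press_rate=0.9, seed=42)
        assert simulate_session(prr10_meta, agent) == \
            simulate_session(prr10_meta, agent)

    def test_different_seed_differs(self, prr10_meta):
        a = AgentParams(press_rate=0.9, seed=1)
        b = AgentParams(press_rate=0.9, seed=2)
        assert simulate_session(prr10_meta, a) != simulate_session(prr10_meta, b)

    @pytest.mark.parametrize("seed", range(10))
    @pytest.mark.parametrize("task,delay", [("PRR", 10.0), ("PRR", 60.0),
                                            ("PR", None)])
    def test_every_simulated_log_is_valid(self, seed, task, delay):
        meta = SessionMeta(subject_id="r", task=task, session_id=f"v{seed}",
                           reset_delay_s=delay, duration_s=300.0)
        agent = AgentParams(press_rate=0.4 + 0.15 * seed,
                            bout_policy=BoutPolicy(kind="fixed", N=2 + seed % 4),
                            seed=seed)
        log = simulate_session(meta, agent)
        assert validate(log) == []
        assert all(0.0 <= e.t <= meta.duration_s for e in log.events)

    def test_reset_delay_gaps_are_exact(self):
        meta = SessionMeta(subject_id="r", task="PRR", session_id="gap",
                           reset_delay_s=10.0, duration_s=700.0)
        log = simulate_session(meta, AgentParams(press_rate=1.0, seed=3))
        gaps, t_ret = [], None
        for e in log.events:
            if e.kind == "levers_retracted":
                t_ret = e.t
            elif e.kind == "levers_extended" and t_ret is not None:
                gaps.append(e.t - t_ret)
                t_ret = None
        resets = sum(1 for e in log.events if e.kind == "reset_press")
        assert gaps and all(g == pytest.approx(10.0) for g in gaps)
        assert len(gaps) in (resets, resets - 1)  # final delay may be truncated

    def test_too_short_session_yields_valid_empty_log(self):
        meta = SessionMeta(subject_id="r", task="PRR", session_id="short",
                           reset_delay_s=10.0, duration_s=0.05)
        log = simulate_session(meta, AgentParams(press_rate=0.5, seed=0))
        assert validate(log) == []
        assert log.counts()["active_press"] == 0

    def test_pr_agent_quiesces_at_stop_ratio(self):
        meta = SessionMeta(subject_id="r", task="PR", session_id="stop",
                           duration_s=2700.0)
        agent = AgentParams(press_rate=1.5, pr_stop_ratio=6,
                            nonfunctional_press_rate=0.0, seed=4)
        log = simulate_session(meta, agent)
        m = compute_session_metrics(log)
        assert m.breakpoint == 6

    def test_pr_nonfunctional_reset_presses_present(self):
        meta = SessionMeta(subject_id="r", task="PR", session_id="np",
                           duration_s=2700.0)
        log = simulate_session(meta, AgentParams(press_rate=1.0, seed=8))
        # ~1.8/min over 45 min -> ~81 expected; loose band.
        assert 40 <= log.counts()["reset_press"] <= 140

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            AgentParams(press_rate=0.0)
        with pytest.raises(ValueError):
            LatencySpec(-1.0)
        with pytest.raises(ValueError):
            BoutPolicy(kind="fixed")         # missing N
        with pytest.raises(ValueError):
            BoutPolicy(kind="telepathic", N=2)
        with pytest.raises(ValueError):
            SubjectRanges(press_rate=(0.0, 1.0))


class TestCohort:
    def test_single_subject_three_logs_share_identity(self):
        logs, truth = simulate_cohort(1, sessions_per_task=1, duration_s=300.0,
                                      seed=2)
        assert len(logs) == 3
        assert len({log.meta.subject_id for log in logs}) == 1
        assert set(truth["task"]) == {"PR", "PRR"}

    def test_press_rate_recovery_correlates_with_truth(self):
        logs, truth = simulate_cohort(
            10, tasks=[("PRR", 10.0)], duration_s=2700.0,
            bout_policy=BoutPolicy(kind="fixed", N=4), seed=6)
        recovered = [compute_session_metrics(log).press_rate for log in logs]
        r = np.corrcoef(truth["press_rate"], recovered)[0, 1]
        assert r > 0.95

    def test_optimal_plus_bias_targets_recoverable(self):
        logs, truth = simulate_cohort(
            6, tasks=[("PRR", 60.0)], duration_s=2700.0,
            bout_policy=BoutPolicy(kind="optimal_plus_bias", bias=3), seed=13)
        for log, (_, row) in zip(logs, truth.iterrows()):
            complete = [b.rewards for b in segment_bouts(log) if b.complete]
            assert complete
            # Without jitter every complete bout hits n_opt + bias exactly.
            assert set(complete) == {row["n_opt"] + 3}
            assert row["policy_target"] == row["n_opt"] + 3
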