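"""Event-log format, validation and round-trip I/O."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from prrforage import (
    AgentParams, BoutPolicy, Event, EventLog, FormatError, LatencySpec,
    MetadataError, SessionMeta, read_event_log, simulate_session, validate,
    write_event_log,
)
from conftest import make_log


def minimal_meta(task="PRR", delay=10.0, duration=2700.0):
    return SessionMeta(subject_id="s", task=task, session_id="x",
                       reset_delay_s=delay if task == "PRR" else None,
                       duration_s=duration)


class TestValidation:
    def test_minimal_empty_session_is_valid(self, tmp_path):
        log = make_log(minimal_meta(), [(0.0, "session_start"),
                                        (0.0, "levers_extended"),
                                        (2700.0, "session_end")])
        assert validate(log) == []
        p = tmp_path / "s.csv"
        write_event_log(log, p)
        back = read_event_log(p)
        assert back == log
        assert len(back.events) == 3
        assert back.counts()["active_press"] == 0

    def test_unknown_event_kind_rejected(self):
        with pytest.raises(FormatError):
            Event(1.0, "lever_sniffed")

    def test_negative_time_is_violation(self):
        log = make_log(minimal_meta(), [(-1.0, "active_press"),
                                        (0.0, "session_start"),
                                        (2700.0, "session_end")])
        names = {v.invariant for v in validate(log)}
        assert "time_in_session" in names

    def test_duplicate_session_start_is_one_violation(self):
        log = make_log(minimal_meta(), [(0.0, "session_start"),
                                        (5.0, "session_start"),
                                        (2700.0, "session_end")])
        hits = [v for v in validate(log) if v.invariant == "single_session_start"]
        assert len(hits) == 1

    def test_press_during_reset_delay_names_lever_absence(self, toy_prr_log):
        assert validate(toy_prr_log) == []
        bad = EventLog(meta=toy_prr_log.meta,
                       events=toy_prr_log.events[:11]
                       + [Event(10.0, "active_press")]
                       + toy_prr_log.events[11:])
        hits = [v for v in validate(bad)
                if v.invariant == "no_press_during_reset_delay"]
        assert len(hits) == 1
        assert bad.events[hits[0].index].t == 10.0

    def test_reset_press_at_retraction_instant_is_not_a_violation(self, toy_prr_log):
        # The reset press that causes the retraction shares its timestamp.
        assert all(v.invariant != "no_press_during_reset_delay"
                   for v in validate(toy_prr_log))

    def test_unsorted_timestamps_rejected_on_read(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("t,kind\n0.000,session_start\n5.000,active_press\n"
                     "1.000,active_press\n10.000,session_end\n")
        (tmp_path / "bad.meta.json").write_text(
            '{"subject_id": "s", "sex": "unknown", "task": "PRR",'
            ' "reset_delay_s": 10, "duration_s": 10, "session_id": "x"}')
        with pytest.raises(FormatError, match="canonical_order"):
            read_event_log(p)

    def test_two_magazine_entries_per_reward_flagged(self):
        log = make_log(minimal_meta(), [(0.0, "session_start"),
                                        (0.0, "levers_extended"),
                                        (1.0, "active_press"),
                                        (1.0, "reward_delivered"),
                                        (1.5, "magazine_entry"),
                                        (2.0, "magazine_entry"),
                                        (2700.0, "session_end")])
        assert any(v.invariant == "one_magazine_entry_per_reward"
                   for v in validate(log))


class TestMetadata:
    def test_prr_requires_positive_reset_delay(self):
        with pytest.raises(MetadataError):
            SessionMeta(subject_id="s", task="PRR", session_id="x",
                        reset_delay_s=None)

    def test_pr_forbids_reset_delay(self):
        with pytest.raises(MetadataError):
            SessionMeta(subject_id="s", task="PR", session_id="x",
                        reset_delay_s=10.0)

    def test_missing_sidecar_is_metadata_error(self, tmp_path):
        p = tmp_path / "orphan.csv"
        p.write_text("t,kind\n0.000,session_start\n10.000,session_end\n")
        with pytest.raises(MetadataError):
            read_event_log(p)


class TestRoundTrip:
    def test_noncanonical_order_written_canonically(self, tmp_path):
        # Same-timestamp events supplied out of precedence order.
        meta = minimal_meta(duration=20.0)
        log = make_log(meta, [(0.0, "levers_extended"),
                              (0.0, "session_start"),
                              (5.0, "reward_delivered"),
                              (5.0, "active_press"),
                              (20.0, "session_end")])
        p = tmp_path / "c.csv"
        write_event_log(log, p)
        lines = p.read_text().splitlines()
        assert lines[1] == "0.000,session_start"
        assert lines[2] == "0.000,levers_extended"
        assert lines[3] == "5.000,active_press"
        assert lines[4] == "5.000,reward_delivered"

    def test_written_file_is_byte_stable(self, tmp_path, degenerate_agent, prr10_meta):
        log = simulate_session(prr10_meta, degenerate_agent)
        a, b = tmp_path / "a.csv", tmp_path / "b.csv"
        write_event_log(log, a)
        write_event_log(read_event_log(a), b)
        assert a.read_bytes() == b.read_bytes()

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000),
           press_rate=st.floats(0.3, 2.0),
           n=st.integers(1, 6),
           task=st.sampled_from(["PR", "PRR"]))
    def test_simulated_logs_round_trip_exactly(self, tmp_path_factory, seed,
                                               press_rate, n, task):
        """read(write(x)) == x and validate(x) == [] for simulator output."""
        meta = SessionMeta(subject_id="h", task=task, session_id=f"h-{seed}",
                           reset_delay_s=10.0 if task == "PRR" else None,
                           duration_s=400.0)
        agent = AgentParams(press_rate=press_rate,
                            bout_policy=BoutPolicy(kind="fixed", N=n),
                            reward_latency=LatencySpec(0.7, 0.4),
                            work_latency=LatencySpec(2.4, 0.4),
                            seed=seed)
        log = simulate_session(meta, agent)
        assert validate(log) == []
        d = tmp_path_factory.mktemp("rt")
        write_event_log(log, d / "s.csv")
        assert read_event_log(d / "s.csv") == log

    def test_arbitrary_precision_times_survive(self, tmp_path):
        # Timestamps are arbitrary reals; the canonical rendering is exact.
        t = 1.0 + math.pi / 10
        log = make_log(minimal_meta(duration=20.0),
                       [(0.0, "session_start"), (0.0, "levers_extended"),
                        (t, "active_press"), (20.0, "session_end")])
        p = tmp_path / "pi.csv"
        write_event_log(log, p)
        assert read_event_log(p).events[2].t == t
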