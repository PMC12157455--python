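"""Event-log data model for operant PR / PRR sessions.

A session is recorded as a time-ordered stream of discrete events (lever
extensions/retractions, active-lever presses, reset-lever presses, reward
deliveries, magazine entries) plus metadata describing the subject and task.
Times are seconds from session start (t = 0 at ``session_start``).

On disk a session is one CSV of events (``t,kind``) with a JSON metadata
sidecar ``<name>.meta.json``; a directory of such pairs is a dataset.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "EVENT_KINDS",
    "Event",
    "SessionMeta",
    "EventLog",
    "Violation",
    "EventLogError",
    "FormatError",
    "MetadataError",
    "read_event_log",
    "write_event_log",
    "validate",
    "canonical_sort",
]

#: Canonical tie-breaking precedence for events logged at the same timestamp.
#: Retraction precedes extension, presses precede their consequences
#: (reward, then magazine entry); the session boundary events bracket all.
EVENT_KINDS: tuple[str, ...] = (
    "session_start",
    "levers_retracted",
    "levers_extended",
    "active_press",
    "reset_press",
    "reward_delivered",
    "magazine_entry",
    "session_end",
)

_PRECEDENCE = {kind: i for i, kind in enumerate(EVENT_KINDS)}

_SEXES = ("male", "female", "unknown")
_TASKS = ("PR", "PRR")


class EventLogError(Exception):
    """Base class for event-log problems."""


class FormatError(EventLogError):
    """Malformed event file: bad kinds, times, ordering or structure."""


class MetadataError(EventLogError):
    """Inconsistent or missing session metadata."""


@dataclass(frozen=True)
class Event:
    """A single timestamped event."""

    t: float
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in _PRECEDENCE:
            raise FormatError(f"unknown event kind: {self.kind!r}")


@dataclass(frozen=True)
class SessionMeta:
    """Session-level metadata.

    ``reset_delay_s`` is the enforced lever-retraction period after a reset
    press; it must be positive for PRR sessions and ``None`` for PR sessions
    (where the reset lever has no programmed consequence).
    """

    subject_id: str
    task: str
    session_id: str
    sex: str = "unknown"
    reset_delay_s: Optional[float] = None
    duration_s: float = 2700.0

    def __post_init__(self) -> None:
        if self.task not in _TASKS:
            raise MetadataError(f"task must be one of {_TASKS}, got {self.task!r}")
        if self.sex not in _SEXES:
            raise MetadataError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.duration_s <= 0:
            raise MetadataError("duration_s must be positive")
        if self.task == "PRR":
            if self.reset_delay_s is None or self.reset_delay_s <= 0:
                raise MetadataError("PRR sessions require reset_delay_s > 0")
        elif self.reset_delay_s is not None:
            raise MetadataError("PR sessions must have reset_delay_s = null")


@dataclass
class EventLog:
    """One session: metadata plus its time-ordered event stream."""

    meta: SessionMeta
    events: list[Event] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {k: 0 for k in EVENT_KINDS}
        for e in self.events:
            out[e.kind] += 1
        return out


@dataclass(frozen=True)
class Violation:
    """One broken invariant; ``index`` points at the offending event."""

    invariant: str
    index: Optional[int]
    message: str


def canonical_sort(events: Iterable[Event]) -> list[Event]:
    """Sort events by time, breaking ties by the canonical kind precedence."""
    return sorted(events, key=lambda e: (e.t, _PRECEDENCE[e.kind]))


def validate(log: EventLog) -> list[Violation]:
    """Check every event-log invariant; violations are data, not exceptions.

    Returns an empty list iff the log is well formed: single start/end
    events bracketing the session, times within [0, duration], canonical
    ordering, no presses while the levers are retracted (PRR), and at most
    one magazine entry per delivered reward.
    """
    v: list[Violation] = []
    ev = log.events
    dur = log.meta.duration_s

    starts = [i for i, e in enumerate(ev) if e.kind == "session_start"]
    ends = [i for i, e in enumerate(ev) if e.kind == "session_end"]
    if len(starts) != 1:
        v.append(Violation("single_session_start", starts[1] if len(starts) > 1 else None,
                           f"expected exactly one session_start, found {len(starts)}"))
    elif ev[starts[0]].t != 0.0:
        v.append(Violation("session_start_at_zero", starts[0],
                           f"session_start at t={ev[starts[0]].t}, expected 0"))
    if len(ends) != 1:
        v.append(Violation("single_session_end", ends[1] if len(ends) > 1 else None,
                           f"expected exactly one session_end, found {len(ends)}"))

    for i, e in enumerate(ev):
        if e.t < 0 or e.t > dur:
            v.append(Violation("time_in_session", i,
                               f"event {e.kind} at t={e.t} outside [0, {dur}]"))

    for i in range(1, len(ev)):
        a, b = ev[i - 1], ev[i]
        if (b.t, _PRECEDENCE[b.kind]) < (a.t, _PRECEDENCE[a.kind]):
            v.append(Violation("canonical_order", i,
                               f"{b.kind}@{b.t} out of order after {a.kind}@{a.t}"))

    # Lever absence: in PRR, no press may fall strictly inside a
    # retracted→extended window.  A reset press logged at the retraction
    # instant is the cause of the retraction, so the comparison is on time,
    # not sequence position.
    if log.meta.task == "PRR":
        t_retract: Optional[float] = None
        for i, e in enumerate(ev):
            if e.kind == "levers_retracted":
                t_retract = e.t
            elif e.kind == "levers_extended":
                t_retract = None
            elif e.kind in ("active_press", "reset_press") and t_retract is not None:
                if e.t > t_retract:
                    v.append(Violation("no_press_during_reset_delay", i,
                                       f"{e.kind}@{e.t} while levers retracted since t={t_retract}"))

    # At most one magazine entry per delivered reward.
    mag_since_reward = 0
    seen_reward = False
    for i, e in enumerate(ev):
        if e.kind == "reward_delivered":
            mag_since_reward = 0
            seen_reward = True
        elif e.kind == "magazine_entry" and seen_reward:
            mag_since_reward += 1
            if mag_since_reward > 1:
                v.append(Violation("one_magazine_entry_per_reward", i,
                                   f"extra magazine_entry@{e.t} with no intervening reward"))
    return v


def _format_time(t: float) -> str:
    """Canonical decimal rendering: exact float round-trip, ≥3 fractional digits."""
    s = repr(float(t))
    if "e" in s or "E" in s:
        s = format(t, ".17f").rstrip("0")
        if s.endswith("."):
            s += "0"
    if "." not in s:
        s += ".000"
    else:
        whole, frac = s.split(".")
        s = f"{whole}.{frac.ljust(3, '0')}"
    return s


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix("").with_suffix(".meta.json") if path.suffix == ".csv" \
        else Path(str(path) + ".meta.json")


def write_event_log(log: EventLog, path: str | Path) -> None:
    """Write a session as canonical CSV plus a JSON metadata sidecar.

    Events are written in canonical order; ``read_event_log`` inverts the
    result exactly.
    """
    path = Path(path)
    events = canonical_sort(log.events)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        fh.write("t,kind\n")
        for e in events:
            fh.write(f"{_format_time(e.t)},{e.kind}\n")
    meta = log.meta
    sidecar = {
        "subject_id": meta.subject_id,
        "sex": meta.sex,
        "task": meta.task,
        "reset_delay_s": meta.reset_delay_s,
        "duration_s": meta.duration_s,
        "session_id": meta.session_id,
    }
    with open(_sidecar_path(path), "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")


def read_event_log(path: str | Path) -> EventLog:
    """Read and validate a session from a CSV event file and its sidecar.

    Raises :class:`FormatError` for structural problems (unknown kinds,
    unsorted or out-of-range timestamps, missing session boundaries) and
    :class:`MetadataError` for a bad or missing sidecar.
    """
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise MetadataError(f"metadata sidecar not found: {sidecar}")
    with open(sidecar, encoding="utf-8") as fh:
        raw = json.load(fh)
    try:
        meta = SessionMeta(
            subject_id=str(raw["subject_id"]),
            sex=raw.get("sex", "unknown"),
            task=raw["task"],
            reset_delay_s=raw.get("reset_delay_s"),
            duration_s=float(raw.get("duration_s", 2700.0)),
            session_id=str(raw["session_id"]),
        )
    except KeyError as exc:
        raise MetadataError(f"sidecar {sidecar} missing key {exc}") from exc

    events: list[Event] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header != ["t", "kind"]:
            raise FormatError(f"{path}: expected header 't,kind', got {header}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != 2:
                raise FormatError(f"{path}:{lineno}: expected two fields, got {row}")
            try:
                t = float(row[0])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad timestamp {row[0]!r}") from exc
            events.append(Event(t=t, kind=row[1]))

    log = EventLog(meta=meta, events=events)
    violations = validate(log)
    if violations:
        first = violations[0]
        raise FormatError(
            f"{path}: {len(violations)} invariant violation(s); first: "
            f"[{first.invariant}] {first.message}"
        )
    return log


def canonicalize(log: EventLog) -> EventLog:
    """Return a copy with events in canonical order."""
    return replace(log, events=canonical_sort(log.events))
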