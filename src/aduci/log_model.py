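"""Domain model and file I/O for smartphone-app usage logs.

A *usage log* records, for each login (session) of an app, who logged in,
when, how long the tracker recorded the login as lasting, and the ordered
sequence of page visits ("navigation events") within that login.  Each page
visit carries the section label, its offset in seconds from the start of the
session, and its own recorded duration.

The on-disk format is a flat UTF-8 CSV with one row per navigation event
(and one row with empty event columns for a login with no navigation):

    user_id,session_id,login_time,recorded_login_duration_s,page_label,enter_offset_s,page_duration_s

Timestamps are ISO-8601; durations and offsets are seconds, written to three
decimal places.  Offsets are relative to ``login_time`` so the cleaning rules
never do timezone arithmetic.  Page-visit intervals are half-open
``[enter_offset, enter_offset + duration)``.  Page labels are compared
case-insensitively after whitespace trimming, because tracking exports are
inconsistent about casing.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import IO, Iterable, Sequence, Union

__all__ = [
    "CSV_HEADER",
    "LogParseError",
    "NavigationEvent",
    "Session",
    "UsageLog",
    "canonical_label",
    "read_event_log",
    "write_event_log",
    "validate_log",
]

CSV_HEADER = [
    "user_id",
    "session_id",
    "login_time",
    "recorded_login_duration_s",
    "page_label",
    "enter_offset_s",
    "page_duration_s",
]

#: Decimal places used when writing numeric fields; the round-trip guarantee
#: (read(write(log)) == log) holds at this precision.
NUMERIC_PRECISION = 3


class LogParseError(ValueError):
    """Malformed usage-log input; carries the 1-based line number if known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def canonical_label(label: str) -> str:
    """Canonical form of a page label: trimmed and casefolded.

    All label comparisons (menu membership, run collapsing, per-page
    aggregation) go through this form; display output keeps the first-seen
    original spelling.
    """
    return label.strip().casefold()


@dataclass(frozen=True)
class NavigationEvent:
    """One page visit within a session."""

    page_label: str
    enter_offset: float  # seconds from session start, >= 0
    recorded_duration: float  # seconds on the page, >= 0

    def violations(self) -> list[str]:
        out = []
        if not self.page_label.strip():
            out.append("page_label empty after trimming")
        if self.enter_offset < 0:
            out.append(f"enter_offset {self.enter_offset} < 0")
        if self.recorded_duration < 0:
            out.append(f"recorded_duration {self.recorded_duration} < 0")
        return out

    @property
    def key(self) -> str:
        return canonical_label(self.page_label)


@dataclass(frozen=True)
class Session:
    """One login: identity, login time, recorded duration and its page visits.

    ``events`` is ordered by ``enter_offset`` (non-decreasing); a login with
    no page visits has an empty tuple.
    """

    user_id: str
    session_id: str
    login_time: datetime
    recorded_login_duration: float
    events: tuple[NavigationEvent, ...] = ()

    def violations(self) -> list[str]:
        out = []
        if self.recorded_login_duration < 0:
            out.append(
                f"session {self.session_id}: recorded_login_duration "
                f"{self.recorded_login_duration} < 0"
            )
        offsets = [e.enter_offset for e in self.events]
        if any(b < a for a, b in zip(offsets, offsets[1:])):
            out.append(f"session {self.session_id}: events not sorted by enter_offset")
        seen: set[tuple[float, str]] = set()
        for e in self.events:
            pair = (e.enter_offset, e.key)
            if pair in seen:
                out.append(
                    f"session {self.session_id}: duplicate event {pair!r}"
                )
            seen.add(pair)
        for e in self.events:
            out.extend(f"session {self.session_id}: {v}" for v in e.violations())
        return out


@dataclass(frozen=True)
class UsageLog:
    """A collection of sessions with distinct session ids."""

    sessions: tuple[Session, ...] = ()
    source: str = ""

    def __len__(self) -> int:
        return len(self.sessions)


def validate_log(log: UsageLog) -> list[str]:
    """Return invariant violations (empty list means the log is valid).

    Violations are data, not exceptions: each entry names the offending
    session and the broken invariant.
    """
    out: list[str] = []
    seen: set[str] = set()
    for s in log.sessions:
        if s.session_id in seen:
            out.append(f"session {s.session_id}: duplicate session_id")
        seen.add(s.session_id)
        out.extend(s.violations())
    return out


def _parse_float(text: str, what: str, line: int) -> float:
    try:
        value = float(text)
    except ValueError:
        raise LogParseError(f"non-numeric {what}: {text!r}", line) from None
    if value < 0:
        raise LogParseError(f"negative {what}: {text}", line)
    if value != value:  # NaN
        raise LogParseError(f"non-finite {what}: {text}", line)
    return value


def _open_source(source: Union[str, Path, IO[str]]):
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def read_event_log(source: Union[str, Path, IO[str]]) -> UsageLog:
    """Parse a usage-log CSV into a :class:`UsageLog`.

    Rows are grouped into sessions by ``session_id``; sessions are ordered by
    ``(user_id, login_time)`` and events within a session by ``enter_offset``,
    so parsing is insensitive to the row order of the input.

    Raises
    ------
    LogParseError
        On a wrong header, wrong column count, non-numeric or negative
        duration/offset, inconsistent session-level fields, or a duplicated
        ``(session_id, enter_offset, page_label)`` triple.  The error names
        the offending 1-based line number.
    """
    handle, owned = _open_source(source)
    name = getattr(handle, "name", str(source))
    try:
        reader = csv.reader(handle)
        try:
            header = next(reader)
        except StopIteration:
            raise LogParseError("empty file: missing header") from None
        if [h.strip() for h in header] != CSV_HEADER:
            raise LogParseError(
                f"bad header {header!r}; expected {','.join(CSV_HEADER)}", 1
            )

        # session_id -> (user_id, login_time, recorded_duration, [events])
        groups: dict[str, tuple[str, datetime, float, list[NavigationEvent]]] = {}
        triples: set[tuple[str, float, str]] = set()
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != len(CSV_HEADER):
                raise LogParseError(
                    f"expected {len(CSV_HEADER)} columns, got {len(row)}", lineno
                )
            user_id, session_id, login_text, login_dur_text, label, off_text, dur_text = (
                c.strip() for c in row
            )
            if not session_id:
                raise LogParseError("empty session_id", lineno)
            try:
                login_time = datetime.fromisoformat(login_text)
            except ValueError:
                raise LogParseError(
                    f"bad ISO-8601 login_time: {login_text!r}", lineno
                ) from None
            login_dur = _parse_float(login_dur_text, "recorded_login_duration_s", lineno)

            no_event = not label and not off_text and not dur_text
            event = None
            if not no_event:
                if not label:
                    raise LogParseError("empty page_label on an event row", lineno)
                offset = _parse_float(off_text, "enter_offset_s", lineno)
                duration = _parse_float(dur_text, "page_duration_s", lineno)
                event = NavigationEvent(label, offset, duration)
                triple = (session_id, offset, canonical_label(label))
                if triple in triples:
                    raise LogParseError(
                        f"duplicate event {triple!r} within session", lineno
                    )
                triples.add(triple)

            if session_id in groups:
                prev_user, prev_time, prev_dur, events = groups[session_id]
                if (prev_user, prev_time, prev_dur) != (user_id, login_time, login_dur):
                    raise LogParseError(
                        f"session {session_id!r}: inconsistent session-level fields",
                        lineno,
                    )
            else:
                events = []
                groups[session_id] = (user_id, login_time, login_dur, events)
            if event is not None:
                events.append(event)

        sessions = [
            Session(
                user_id=u,
                session_id=sid,
                login_time=t,
                recorded_login_duration=d,
                events=tuple(sorted(ev, key=lambda e: e.enter_offset)),
            )
            for sid, (u, t, d, ev) in groups.items()
        ]
        sessions.sort(key=lambda s: (s.user_id, s.login_time, s.session_id))
        return UsageLog(sessions=tuple(sessions), source=name)
    finally:
        if owned:
            handle.close()


def _fmt(value: float) -> str:
    return f"{value:.{NUMERIC_PRECISION}f}"


def write_event_log(log: UsageLog, sink: Union[str, Path, IO[str]]) -> None:
    """Write a usage log as CSV; inverse of :func:`read_event_log`.

    Numeric fields are written to three decimal places, so a log whose values
    are already rounded at that precision round-trips field-for-field.
    """
    if isinstance(sink, (str, Path)):
        with open(sink, "w", encoding="utf-8", newline="") as handle:
            _write(log, handle)
    else:
        _write(log, sink)


def _write(log: UsageLog, handle: IO[str]) -> None:
    writer = csv.writer(handle, lineterminator="\n")
    writer.writerow(CSV_HEADER)
    for s in log.sessions:
        base = [s.user_id, s.session_id, s.login_time.isoformat(),
                _fmt(s.recorded_login_duration)]
        if not s.events:
            writer.writerow(base + ["", "", ""])
            continue
        for e in s.events:
            writer.writerow(base + [e.page_label, _fmt(e.enter_offset),
                                    _fmt(e.recorded_duration)])


def round_log(log: UsageLog) -> UsageLog:
    """Round all numeric fields to the on-disk precision (3 decimals)."""
    sessions = []
    for s in log.sessions:
        events = tuple(
            replace(e, enter_offset=round(e.enter_offset, NUMERIC_PRECISION),
                    recorded_duration=round(e.recorded_duration, NUMERIC_PRECISION))
            for e in s.events
        )
        sessions.append(
            replace(s, recorded_login_duration=round(
                s.recorded_login_duration, NUMERIC_PRECISION), events=events)
        )
    return replace(log, sessions=tuple(sessions))
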