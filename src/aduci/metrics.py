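"""Engagement metrics: deduplicated frequency tallies, usage summaries,
naive-vs-cleaned comparison tables, and the user-testing task flag.

The frequency rule distinguishes two navigation patterns.  Returning to the
same content page via the main menu (``Cancer Information, Main Menu,
Cancer Information``) counts as **one** view — there is no evidence the
repeat was intentional.  Returning after visiting a *different* content page
(``Cancer Information, Main Menu, Wellbeing, Main Menu, Cancer
Information``) counts as **two** views of Cancer Information, because the
intervening visit shows deliberate navigation.  Formally: a content page is
counted once per maximal run of visits to it, where menu visits do not break
a run but a different content page does.  Menu visits themselves are
reported as their own feature (one count per maximal consecutive menu run),
so the menu row of a report is meaningful rather than discarded.

Duration and frequency rules are independent: per-page durations sum the
effective (post-cleaning) durations of *all* events on that page, including
visits that the frequency rule collapsed.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence, Union

import pandas as pd

from .cleaning import CleanedSession, CleaningConfig
from .log_model import NavigationEvent, canonical_label

__all__ = [
    "FrequencyTable",
    "PageStats",
    "UsageSummary",
    "ComparisonRow",
    "ComparisonTable",
    "UserTestTask",
    "tally_frequencies",
    "naive_tally",
    "summarize",
    "compare_summaries",
    "flag_user_test_tasks",
]

#: page label -> positive view count; pages never visited are absent.
FrequencyTable = dict[str, int]


def _canon_set(labels: Iterable[str]) -> frozenset[str]:
    return frozenset(canonical_label(m) for m in labels)


def tally_frequencies(
    events: Sequence[NavigationEvent], menu_labels: Iterable[str]
) -> FrequencyTable:
    """Deduplicated per-page view counts for one retained session.

    Single left-to-right pass: a content event increments its page's count
    only if the previous *content* event was a different page (menu visits
    in between are transparent); a menu event increments the menu count only
    at the start of a maximal consecutive menu run.  Immediate same-page
    repeats therefore collapse to one view.
    """
    menu = _canon_set(menu_labels)
    counts: Counter[str] = Counter()
    display: dict[str, str] = {}
    prev_content: str | None = None
    in_menu_run = False
    for e in events:
        key = e.key
        display.setdefault(key, e.page_label.strip())
        if key in menu:
            if not in_menu_run:
                counts[key] += 1
            in_menu_run = True
        else:
            if key != prev_content:
                counts[key] += 1
            prev_content = key
            in_menu_run = False
    return {display[k]: n for k, n in counts.items()}


def naive_tally(events: Sequence[NavigationEvent]) -> FrequencyTable:
    """Raw per-page view counts: every event counts once under its label."""
    counts: Counter[str] = Counter()
    display: dict[str, str] = {}
    for e in events:
        display.setdefault(e.key, e.page_label.strip())
        counts[e.key] += 1
    return {display[k]: n for k, n in counts.items()}


@dataclass(frozen=True)
class PageStats:
    frequency: int
    total_duration: float
    mean_duration: float  # total / frequency, or 0 when never visited


@dataclass(frozen=True)
class UsageSummary:
    """Per-page and overall frequency/duration aggregates for one log."""

    per_page: dict[str, PageStats]
    n_logins: int
    total_duration: float
    mean_duration_per_login: float
    mode: str = "aduci"

    def page_universe(self) -> set[str]:
        return set(self.per_page)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "feature": label,
                "frequency": st.frequency,
                "total_duration_s": round(st.total_duration, 3),
                "mean_duration_s": round(st.mean_duration, 3),
            }
            for label, st in sorted(self.per_page.items())
        ]
        rows.append(
            {
                "feature": "All uses",
                "frequency": self.n_logins,
                "total_duration_s": round(self.total_duration, 3),
                "mean_duration_s": round(self.mean_duration_per_login, 3),
            }
        )
        return pd.DataFrame(rows, columns=["feature", "frequency",
                                           "total_duration_s", "mean_duration_s"])


def _mean(total: float, n: int) -> float:
    return total / n if n > 0 else 0.0


def summarize(
    cleaned: Sequence[CleanedSession],
    mode: str = "aduci",
    config: CleaningConfig | None = None,
    page_universe: Iterable[str] | None = None,
) -> UsageSummary:
    """Aggregate cleaned sessions into a usage summary.

    ``mode="aduci"`` uses effective durations and the deduplicated tally on
    retained sessions only (excluded sessions contribute nothing even if
    passed).  ``mode="naive"`` reproduces what a manual extraction of the raw
    export would report: recorded durations and raw counts over *all*
    sessions.  ``page_universe`` optionally forces named pages to appear with
    zero counts (so a report can show every app feature, visited or not).
    """
    if mode not in ("aduci", "naive"):
        raise ValueError(f"mode must be 'aduci' or 'naive', got {mode!r}")
    config = config or CleaningConfig()

    freq: Counter[str] = Counter()
    dur: Counter[str] = Counter()
    display: dict[str, str] = {}
    n_logins = 0
    total = 0.0
    for c in cleaned:
        if mode == "aduci":
            if c.excluded:
                continue
            events = c.effective_events
            login_duration = c.effective_login_duration
            table = tally_frequencies(events, config.menu_labels)
        else:
            events = c.source.events
            login_duration = c.source.recorded_login_duration
            table = naive_tally(events)
        n_logins += 1
        total += login_duration
        for label, n in table.items():
            key = canonical_label(label)
            display.setdefault(key, label)
            freq[key] += n
        for e in events:
            display.setdefault(e.key, e.page_label.strip())
            dur[e.key] += e.recorded_duration

    keys = set(freq) | set(dur)
    if page_universe is not None:
        for label in page_universe:
            key = canonical_label(label)
            display.setdefault(key, label.strip())
            keys.add(key)
    per_page = {
        display[k]: PageStats(
            frequency=freq.get(k, 0),
            total_duration=dur.get(k, 0.0),
            mean_duration=_mean(dur.get(k, 0.0), freq.get(k, 0)),
        )
        for k in keys
    }
    return UsageSummary(
        per_page=per_page,
        n_logins=n_logins,
        total_duration=total,
        mean_duration_per_login=_mean(total, n_logins),
        mode=mode,
    )


@dataclass(frozen=True)
class ComparisonRow:
    feature: str
    naive_frequency: int
    aduci_frequency: int
    frequency_difference: int
    naive_total_duration: float
    aduci_total_duration: float
    duration_difference: float


@dataclass(frozen=True)
class ComparisonTable:
    """Naive-vs-cleaned differences, per page and overall.

    Every ``*_difference`` field is ``naive - cleaned``: positive values are
    the inflation removed by cleaning.
    """

    rows: tuple[ComparisonRow, ...]
    naive_n_logins: int
    aduci_n_logins: int
    login_difference: int
    naive_total_duration: float
    aduci_total_duration: float
    total_duration_difference: float
    notes: tuple[str, ...] = ()

    def to_frame(self) -> pd.DataFrame:
        records = [
            {
                "feature": r.feature,
                "naive_frequency": r.naive_frequency,
                "aduci_frequency": r.aduci_frequency,
                "frequency_difference": r.frequency_difference,
                "naive_total_duration_s": round(r.naive_total_duration, 3),
                "aduci_total_duration_s": round(r.aduci_total_duration, 3),
                "duration_difference_s": round(r.duration_difference, 3),
            }
            for r in self.rows
        ]
        records.append(
            {
                "feature": "All uses",
                "naive_frequency": self.naive_n_logins,
                "aduci_frequency": self.aduci_n_logins,
                "frequency_difference": self.login_difference,
                "naive_total_duration_s": round(self.naive_total_duration, 3),
                "aduci_total_duration_s": round(self.aduci_total_duration, 3),
                "duration_difference_s": round(self.total_duration_difference, 3),
            }
        )
        return pd.DataFrame(records)


def compare_summaries(naive: UsageSummary, aduci: UsageSummary) -> ComparisonTable:
    """Tabulate ``naive - cleaned`` differences cell by cell.

    Mismatched page universes are unioned, absent pages counting as zero;
    a note records which side was missing each such page.
    """
    notes: list[str] = []
    zero = PageStats(0, 0.0, 0.0)
    by_key_naive = {canonical_label(k): (k, v) for k, v in naive.per_page.items()}
    by_key_aduci = {canonical_label(k): (k, v) for k, v in aduci.per_page.items()}
    rows = []
    for key in sorted(set(by_key_naive) | set(by_key_aduci)):
        label_n, st_n = by_key_naive.get(key, (None, zero))
        label_a, st_a = by_key_aduci.get(key, (None, zero))
        if label_n is None:
            notes.append(f"page {label_a!r} absent from naive summary; counted as 0")
        if label_a is None:
            notes.append(f"page {label_n!r} absent from cleaned summary; counted as 0")
        rows.append(
            ComparisonRow(
                feature=label_n or label_a,
                naive_frequency=st_n.frequency,
                aduci_frequency=st_a.frequency,
                frequency_difference=st_n.frequency - st_a.frequency,
                naive_total_duration=st_n.total_duration,
                aduci_total_duration=st_a.total_duration,
                duration_difference=st_n.total_duration - st_a.total_duration,
            )
        )
    return ComparisonTable(
        rows=tuple(rows),
        naive_n_logins=naive.n_logins,
        aduci_n_logins=aduci.n_logins,
        login_difference=naive.n_logins - aduci.n_logins,
        naive_total_duration=naive.total_duration,
        aduci_total_duration=aduci.total_duration,
        total_duration_difference=naive.total_duration - aduci.total_duration,
        notes=tuple(notes),
    )


@dataclass(frozen=True)
class UserTestTask:
    """One timed scenario from pre-release user acceptance testing."""

    task_id: str
    completed: bool
    completion_seconds: float | None = None

    def __post_init__(self):
        if self.completed and self.completion_seconds is None:
            raise ValueError(f"task {self.task_id}: completed but no time recorded")
        if not self.completed and self.completion_seconds is not None:
            raise ValueError(f"task {self.task_id}: time recorded for incomplete task")
        if self.completion_seconds is not None and self.completion_seconds < 0:
            raise ValueError(f"task {self.task_id}: negative completion time")


def flag_user_test_tasks(
    tasks: Sequence[UserTestTask], cutoff_seconds: float = 20.0
) -> list[str]:
    """Task ids needing content/design revision: incomplete, or slower than
    the cutoff (default 20 s, a usability guide adjusted for older adults)."""
    if cutoff_seconds <= 0:
        raise ValueError("cutoff_seconds must be > 0")
    return [
        t.task_id
        for t in tasks
        if not t.completed or t.completion_seconds > cutoff_seconds
    ]


def render_text_table(frame: pd.DataFrame) -> str:
    """Aligned human-readable rendering of a summary/comparison frame."""
    return frame.to_string(index=False)
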