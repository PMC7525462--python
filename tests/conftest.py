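from datetime import datetime

import pytest
from hypothesis import strategies as st

from aduci.log_model import NavigationEvent, Session, UsageLog

LOGIN_TIME = datetime(2023, 3, 1, 9, 30, 0)

MENU = "Main Menu"
LABELS = ["Cancer Information", "Wellbeing", MENU]


def make_events(labels, dwell=5.0, gap=10.0):
    """Events visiting `labels` in order at evenly spaced offsets."""
    return tuple(
        NavigationEvent(label, round(i * gap, 3), dwell)
        for i, label in enumerate(labels)
    )


def make_session(duration, labels=(), session_id="s1", user_id="u1",
                 events=None, login_time=LOGIN_TIME):
    if events is None:
        events = make_events(labels)
    return Session(
        user_id=user_id,
        session_id=session_id,
        login_time=login_time,
        recorded_login_duration=duration,
        events=tuple(events),
    )


def make_log(*sessions):
    return UsageLog(sessions=tuple(sessions), source="test")


@st.composite
def session_strategy(draw, max_events=6):
    """Random session with sorted offsets and 3-decimal numeric fields."""
    n = draw(st.integers(min_value=0, max_value=max_events))
    offsets = sorted(
        draw(
            st.lists(
                st.floats(min_value=0, max_value=2000).map(lambda x: round(x, 3)),
                min_size=n,
                max_size=n,
                unique=True,
            )
        )
    )
    events = tuple(
        NavigationEvent(
            draw(st.sampled_from(LABELS)),
            off,
            round(draw(st.floats(min_value=0, max_value=20000)), 3),
        )
        for off in offsets
    )
    duration = round(draw(st.floats(min_value=0, max_value=50000)), 3)
    return make_session(duration, events=events)


@st.composite
def log_strategy(draw, max_sessions=5):
    n = draw(st.integers(min_value=0, max_value=max_sessions))
    sessions = tuple(
        Session(
            user_id=s.user_id,
            session_id=f"s{i}",
            login_time=s.login_time,
            recorded_login_duration=s.recorded_login_duration,
            events=s.events,
        )
        for i, s in enumerate(draw(st.lists(session_strategy(),
                                            min_size=n, max_size=n)))
    )
    return UsageLog(sessions=sessions, source="hypothesis")
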