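"""Cleaning rules: exclusion, idle capping, discrepancy elimination."""

import numpy as np
import pytest
from hypothesis import given, settings

from aduci.cleaning import (
    CleanedSession,
    CleaningConfig,
    FlagLabel,
    LogValidationError,
    apply_duration_cap,
    classify_exclusion,
    clean_log,
    clean_session,
    resolve_discrepancies,
)
from aduci.log_model import NavigationEvent, UsageLog

from conftest import MENU, make_events, make_log, make_session, session_strategy

CONFIG = CleaningConfig()


class TestClassifyExclusion:
    @pytest.mark.parametrize(
        "duration, labels, expected",
        [
            (0.5, ["Wellbeing"], FlagLabel.EXCLUDED_SUBSECOND),
            (0.5, [MENU], FlagLabel.EXCLUDED_SUBSECOND),  # sub-second wins
            (10.0, [MENU], FlagLabel.EXCLUDED_NO_NAVIGATION),
            (10.0, [MENU, MENU, MENU], FlagLabel.EXCLUDED_NO_NAVIGATION),
            (10.0, [], FlagLabel.EXCLUDED_NO_NAVIGATION),  # login, zero events
            (10.0, [MENU, "Cancer Information"], None),
            (1.0, ["Wellbeing"], None),  # exactly at the 1-second floor
        ],
    )
    def test_rules(self, duration, labels, expected):
        flag = classify_exclusion(make_session(duration, labels), CONFIG)
        assert (flag.label if flag else None) == expected

    def test_menu_labels_matched_case_insensitively(self):
        session = make_session(10.0, ["  main menu  "])
        flag = classify_exclusion(session, CONFIG)
        assert flag.label is FlagLabel.EXCLUDED_NO_NAVIGATION


class TestDurationCap:
    def test_idle_tail_capped_22_minutes_after_last_navigation(self):
        events = (NavigationEvent("Wellbeing", 100.0, 4900.0),)
        session = make_session(5000.0, events=events)
        cleaned = apply_duration_cap(session, CONFIG)
        assert cleaned.effective_login_duration == pytest.approx(1420.0)
        assert cleaned.has_flag(FlagLabel.DURATION_CAPPED)
        # final event cannot extend past the effective end
        assert cleaned.effective_events[-1].recorded_duration == pytest.approx(1320.0)

    def test_cap_not_binding_leaves_session_unchanged(self):
        session = make_session(300.0, events=(NavigationEvent("Wellbeing", 200.0, 50.0),))
        cleaned = apply_duration_cap(session, CONFIG)
        assert cleaned.effective_login_duration == 300.0
        assert cleaned.flags == ()

    def test_boundary_equality_is_not_capped(self):
        session = make_session(1320.0, events=(NavigationEvent("Wellbeing", 0.0, 1320.0),))
        cleaned = apply_duration_cap(session, CONFIG)
        assert cleaned.effective_login_duration == 1320.0
        assert cleaned.flags == ()

    def test_custom_cap_from_config(self):
        config = CleaningConfig(idle_cap_seconds=600.0)
        session = make_session(5000.0, events=(NavigationEvent("Wellbeing", 100.0, 10.0),))
        cleaned = apply_duration_cap(session, config)
        assert cleaned.effective_login_duration == pytest.approx(700.0)


class TestResolveDiscrepancies:
    def test_page_duration_exceeding_login_is_capped_and_flagged(self):
        # the canonical tracking artifact: a 16,072 s page inside a 4 s login
        session = make_session(4.0, events=(NavigationEvent("Cancer Information", 0.0, 16072.0),))
        cleaned = CleanedSession(session, 4.0, session.events)
        resolved = resolve_discrepancies(cleaned)
        assert resolved.effective_events[0].recorded_duration == 4.0
        (flag,) = resolved.flags
        assert flag.label is FlagLabel.PAGE_DURATION_DISCREPANCY
        assert "16072" in flag.detail  # original value preserved for audit

    def test_consistent_durations_untouched(self):
        session = make_session(10.0, events=(NavigationEvent("Wellbeing", 0.0, 3.0),))
        cleaned = CleanedSession(session, 10.0, session.events)
        resolved = resolve_discrepancies(cleaned)
        assert resolved == cleaned

    def test_matches_elementwise_min_oracle_on_random_sessions(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n = int(rng.integers(1, 6))
            events = tuple(
                NavigationEvent("Wellbeing", float(i * 10), float(rng.uniform(0, 500)))
                for i in range(n)
            )
            login = float(rng.uniform(0, 300))
            cleaned = resolve_discrepancies(
                CleanedSession(make_session(login, events=events), login, events)
            )
            expected = [min(e.recorded_duration, login) for e in events]
            got = [e.recorded_duration for e in cleaned.effective_events]
            assert got == pytest.approx(expected)
            n_flags = sum(
                1 for f in cleaned.flags
                if f.label is FlagLabel.PAGE_DURATION_DISCREPANCY
            )
            assert n_flags == sum(
                1 for e in events if e.recorded_duration > login + 1e-6
            )


class TestCleanLog:
    def test_three_session_composition(self):
        log = make_log(
            make_session(0.4, ["Wellbeing"], session_id="bounce"),
            make_session(10.0, [MENU], session_id="menu"),
            make_session(60.0, [MENU, "Wellbeing"], session_id="ok"),
        )
        retained, excluded = clean_log(log, CONFIG)
        assert [c.source.session_id for c in retained] == ["ok"]
        flags = {c.source.session_id: c.flags[0].label for c in excluded}
        assert flags == {
            "bounce": FlagLabel.EXCLUDED_SUBSECOND,
            "menu": FlagLabel.EXCLUDED_NO_NAVIGATION,
        }

    def test_empty_log(self):
        assert clean_log(UsageLog(), CONFIG) == ([], [])

    def test_invalid_log_raises_with_violations(self):
        log = make_log(make_session(-1.0, [], session_id="neg"))
        with pytest.raises(LogValidationError, match="neg"):
            clean_log(log, CONFIG)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(session=session_strategy())
    def test_monotonic_idempotent_and_sound(self, session):
        cleaned = clean_session(session, CONFIG)
        # monotonicity
        assert cleaned.effective_login_duration <= session.recorded_login_duration
        # discrepancy elimination
        for e in cleaned.effective_events:
            assert e.recorded_duration <= cleaned.effective_login_duration + 1e-6
        # exclusion completeness: one-line oracle over the raw session
        should_exclude = session.recorded_login_duration < 1.0 - 1e-6 or not any(
            not CONFIG.is_menu(e.page_label) for e in session.events
        )
        assert cleaned.excluded == should_exclude
        # idempotence on retained output
        if not cleaned.excluded:
            again = clean_session(cleaned.to_session(), CONFIG)
            assert not again.excluded
            assert again.effective_login_duration == cleaned.effective_login_duration
            assert again.effective_events == cleaned.effective_events
            assert again.flags == ()

    def test_partition_counts(self):
        from aduci.synthgen import SynthConfig, generate_log

        log, _ = generate_log(SynthConfig(n_users=15, seed=2))
        retained, excluded = clean_log(log, CONFIG)
        assert len(retained) + len(excluded) == len(log)
        assert {c.source.session_id for c in retained}.isdisjoint(
            c.source.session_id for c in excluded
        )


class TestCleaningConfig:
    def test_defaults(self):
        assert CONFIG.idle_cap_seconds == 1320.0
        assert CONFIG.min_session_seconds == 1.0
        assert CONFIG.menu_labels == frozenset({"Main Menu"})

    def test_from_yaml_file_with_partial_keys(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("idle_cap_seconds: 600\nmenu_labels: [Home, Hub]\n")
        config = CleaningConfig.from_file(path)
        assert config.idle_cap_seconds == 600
        assert config.min_session_seconds == 1.0
        assert config.menu_labels == frozenset({"Home", "Hub"})

    def test_from_json_file(self, tmp_path):
        path = tmp_path / "config.json"
        path.write_text('{"min_session_seconds": 2.5}')
        assert CleaningConfig.from_file(path).min_session_seconds == 2.5

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"idle_cap_seconds": 0},
            {"min_session_seconds": -1},
            {"menu_labels": frozenset()},
        ],
    )
    def test_invalid_values_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CleaningConfig(**kwargs)

    def test_unknown_file_keys_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("idle_cap: 10\n")
        with pytest.raises(ValueError, match="unknown"):
            CleaningConfig.from_file(path)
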