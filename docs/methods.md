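# Methods

## The cleaning model

A usage log is a set of *sessions* (logins). A session has a recorded
duration $D \ge 0$ and an ordered sequence of navigation events
$(\ell_i, t_i, d_i)_{i=1..n}$ — page label, offset from session start in
seconds, recorded page duration in seconds. Offsets are relative to the
login timestamp, so cleaning never performs timezone arithmetic; page-visit
intervals are half-open $[t_i, t_i + d_i)$. Labels are compared
case-insensitively after whitespace trimming, because tracking exports are
inconsistent about casing; display output keeps the first-seen spelling.

Cleaning runs three stages in a fixed order:

1. **Exclusion.** A session is excluded as a *bounce* if $D < m$ (default
   $m = 1$ s), otherwise as *no-navigation* if no event's label lies outside
   the configured menu-label set. Precedence matters only for reporting: a
   0.5-second menu-only login is flagged once, as a bounce, since a mis-tap
   is the more parsimonious explanation. A login with zero events is treated
   as the degenerate no-navigation case. Excluded sessions keep their raw
   record but contribute nothing to any downstream metric.
2. **Idle cap.** $D^\* = \min(D, t_n + c)$ with $c = 1320$ s by default
   ($t_n = 0$ for a hypothetical event-free retained session). The cap runs
   from the *start* of the final navigation event. Two alternative readings
   exist — cap the whole session at $c$, or run $c$ from the final event's
   *end* — but anchoring at the last navigation start is the most
   conservative interpretation that still removes background-idle time
   while preserving long, genuinely active sessions; the final event's end
   is itself often inflated by the same idle artifact, which would make it
   a circular anchor. When the cap binds, the final event's duration is
   truncated to $D^\* - t_n$ and the session is flagged `DURATION_CAPPED`.
3. **Discrepancy elimination.** Any $d_i > D^\*$ is set to $D^\*$ and
   flagged `PAGE_DURATION_DISCREPANCY` with the original value preserved in
   the flag detail. Capping rather than dropping keeps the session's other,
   plausible measurements; the artifact is in one field, not the session.

The composition is idempotent on its retained output (re-cleaning a
cleaned session changes nothing), monotone (effective durations never
exceed recorded ones), and complete (retained + excluded partitions the
input). These are tested as properties, not examples.

### Frequency deduplication

View counting is independent of duration cleaning. For a retained session
the content label sequence (menu visits removed) is run-length collapsed —
consecutive duplicates count once — and tallied per label; menu visits are
tallied separately, one count per maximal consecutive menu run in the full
sequence. This reproduces the two defining scenarios: a menu detour back to
the same page is one view, a detour through a different content page makes
the return a second view. Immediate same-page repeats (no menu between)
also collapse to one view, by the same rationale: there is no evidence the
repeat was intentional. Menu visits are reported as their own feature
rather than discarded so that a navigation row can appear in summary
tables; how a cleaned menu count "should" be defined is genuinely open, and
per-maximal-run is the choice consistent with the content rule.

The single-pass tally is verified exhaustively against an independent
groupby-based oracle on all sequences of length ≤ 8 over a three-label
alphabet (9,841 sequences).

## Parameters

| parameter | default | units | meaning |
|---|---|---|---|
| `idle_cap_seconds` | 1320 | s | counted time ends this long after the last navigation starts; 22 min is the mean per-login use observed in a pilot caregiver cohort |
| `min_session_seconds` | 1 | s | logins shorter than this are bounces |
| `menu_labels` | {"Main Menu"} | — | labels treated as the hub page |

All three are config-level (YAML/JSON, omitted keys keep defaults): the
22-minute value came from one cohort and other apps and populations should
recalibrate it. The user-testing helper flags tasks slower than a separate
`cutoff_seconds` (default 20 s, a usability guideline adjusted for older
adults) or left incomplete.

## Numerical conventions

* Durations and offsets are seconds as floats; files store three decimal
  places, and the read/write round-trip is exact for values already at that
  precision.
* All duration comparisons at rule boundaries use a $10^{-6}$-second
  tolerance, so a value representing "exactly 22 minutes" is never capped
  by a last-bit float artifact. A login of exactly `min_session_seconds` is
  retained.
* Summary means are `total / frequency` with the convention `0` when the
  frequency is zero.
* Ground-truth recovery compares counts and frequencies exactly and summed
  durations within $10^{-6}$ s, since the two routes may associate float
  additions differently.
* Idempotence of cleaning is guaranteed when `idle_cap_seconds ≥
  min_session_seconds`; a pathological config with a sub-second idle cap
  could cap a retained session below the bounce floor.

## The synthetic generator

Real trial exports are rarely shareable, so `aduci.synthgen` generates
seeded logs that emulate the four pathologies. Session types are chosen by
labeled construction — the generator decides up front whether a session is
a bounce, menu-only, or normal, and remembers which events it corrupted —
so the `GroundTruth` sidecar carries *realized* pathology counts and exact
expected summaries, making recovery tests non-flaky. Truth summaries are
computed with independent arithmetic (a groupby run counter, elementwise
min rules), never by calling the cleaner, so recovery tests compare two
genuinely separate routes.

Default conditions describe a small trial cohort: 40 users averaging five
logins each (≈200 sessions; shifted-Poisson counts), six content-page
visits per active session, log-normal page dwell with median ≈18 s,
a heavy-tailed log-normal idle tail with mean 600 s (so roughly a tenth of
active sessions exceed the 22-minute cap), 5% bounces, 10% menu-only
logins, and a 5% chance per active session that one non-final page duration
is inflated past the login duration. None of these distributions is fitted
to a real cohort — the published aggregate tables of any one trial are
population-specific — and the generator deliberately does not model
features of real usage such as within-user habit correlation, diurnal
rhythm, content-specific dwell differences, or simultaneous multi-device
logins. Passing recovery tests therefore demonstrates that the rules are
implemented exactly as specified, not that the rules are the right ones for
any particular real population.

Corrupted durations are injected only on non-final events: inflating the
final event is indistinguishable from an idle tail, which the cap stage
(not the discrepancy stage) rightly absorbs, and conflating the two would
make injected counts unrecoverable in principle.

## Scale of the shipped checks

The test suite and the acceptance script run at desk scale by design: logs
of a few hundred sessions across multiple seeds, exhaustive sequence
enumeration to length 8, and property tests with 60–150 examples each. The
rules are $O(\text{events})$ per session, so behavior at these sizes is
representative; nothing in the implementation is size-dependent.

## Known limitations

* One published summary table shows a section *gaining* time after manual
  cleaning; no stated rule produces increases, so that behavior is not
  implemented — this package's cleaning is monotone by construction.
* The cleaner repairs only the four modeled pathologies. Structural damage
  (negative durations, unordered events, duplicated event rows) is a
  validation failure, not a cleaning case; missing durations are not
  imputed.
* No inferential statistics on naive-vs-cleaned differences, and no
  navigation-pathway (Markov) modeling of user behavior.
* There is no standard export schema for in-app tracking; the CSV layout
  here is this package's own, and adapters for analytics-platform exports
  are out of scope.
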