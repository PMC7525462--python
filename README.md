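# aduci

Cleaning and engagement metrics for smartphone-app usage logs.

Trials of mHealth apps — for example supportive-care apps for people with
cancer and their caregivers — routinely report engagement from raw tracking
exports: number of logins, time per login, and page views per app section.
Taken at face value those exports overstate engagement, for four recurring
reasons:

* **bounce logins** — sub-second sessions, most plausibly a mis-tap on the
  app icon;
* **no-navigation logins** — sessions that never go beyond the main menu,
  so no content was used;
* **idle tails** — session time recorded long after the last navigation,
  i.e. the app left running in the background;
* **duration discrepancies** — tracker artifacts where a single page's
  recorded duration exceeds the duration of the login that contained it.

`aduci` implements a rule-based cleaning framework for such logs, aimed at
researchers evaluating e-intervention feasibility and engagement. Every
intervention the cleaner makes is recorded as an audit flag, so the cleaned
dataset stays defensible.

## The rules

For a session with recorded login duration $D$, navigation events at
offsets $t_1 \le \dots \le t_n$ with recorded page durations $d_1, \dots,
d_n$, and cleaning thresholds $(c, m)$ — idle cap $c = 1320$ s (22 min) and
minimum session duration $m = 1$ s by default:

1. **Exclusion.** Drop the session if $D < m$ (bounce), or else if no event
   is on a content page (nothing beyond the main menu, including zero-event
   logins). Sub-second takes precedence.
2. **Idle cap.** Effective login duration $D^\* = \min(D,\; t_n + c)$:
   counted time ends at most $c$ seconds after the *start* of the final
   navigation. If the cap binds, the final page duration is truncated so it
   does not extend past $D^\*$, and the session is flagged.
3. **Discrepancy elimination.** Every page duration is capped at the
   effective login duration: $d_i^\* = \min(d_i, D^\*)$, flagged with the
   original value whenever reduced. After cleaning, no page can have been
   open longer than its login.
4. **View deduplication.** A content page is counted once per *maximal run*
   of visits to it, where main-menu visits do not break a run but a visit
   to a different content page does. So `Cancer Information, Main Menu,
   Cancer Information` is **1** view of Cancer Information (the return may
   be accidental), while `Cancer Information, Main Menu, Wellbeing, Main
   Menu, Cancer Information` is **2** views (the detour shows intent).
   Menu visits are reported as their own feature, one count per maximal
   consecutive menu run.

Frequency and duration rules are independent: per-page time sums the
effective durations of all events on that page, including visits collapsed
for counting.

## Worked example

```python
from datetime import datetime
from aduci import (CleaningConfig, NavigationEvent, Session,
                   clean_session, tally_frequencies)

session = Session(
    "u1", "s1", datetime(2023, 3, 1, 9, 0),
    recorded_login_duration=5000.0,
    events=(NavigationEvent("Main Menu", 0.0, 8.0),
            NavigationEvent("Cancer Information", 10.0, 16072.0),
            NavigationEvent("Main Menu", 140.0, 5.0),
            NavigationEvent("Wellbeing", 150.0, 60.0)))

cleaned = clean_session(session, CleaningConfig())
print("effective_login_duration:", cleaned.effective_login_duration)
for f in cleaned.flags:
    print(f.label.value, "|", f.detail)
print("views:", tally_frequencies(cleaned.effective_events, {"Main Menu"}))
```

prints

```
effective_login_duration: 1470.0
DURATION_CAPPED | recorded 5000.0s -> 1470.0s (last navigation at 150.0s + cap 1320.0s)
PAGE_DURATION_DISCREPANCY | page 'Cancer Information' at 10.0s: duration 16072.0s > login 1470.0s; capped
views: {'Main Menu': 2, 'Cancer Information': 1, 'Wellbeing': 1}
```

The login is counted for 1470 s rather than 5000 s (last navigation started
at 150 s, plus the 22-minute cap), the corrupted 16,072-second page visit —
impossible inside any login this short — is capped at the session's
effective duration, and the four raw events reduce to one content view
each of Cancer Information and Wellbeing plus two menu runs.

## Command line

```sh
aduci simulate --seed 7 --out sim          # synthetic log + ground truth
aduci clean   sim.log.csv --out run        # cleaned/excluded CSVs + manifest
aduci summarize sim.log.csv --mode aduci   # per-feature table
aduci compare sim.log.csv --out cmp        # naive-vs-cleaned differences
```

`compare` prints a table like

```
           feature  naive_frequency  aduci_frequency  frequency_difference  naive_total_duration_s  aduci_total_duration_s  duration_difference_s
Cancer Information              169              129                    40                5478.868                5478.868                  0.000
         Main Menu              710              599                   111               10609.858                5264.680               5345.178
          All uses              206              175                    31              157371.855              103362.902              54008.953
```

— here a naive reading of the simulated export would report 206 logins and
157,372 s of use; after cleaning, 175 logins and 103,363 s. The difference
columns are the inflation the cleaning removed. Every run writes a
`*.manifest.json` recording the resolved thresholds and session counts.

The log file format is a flat CSV, one row per navigation event (see
`aduci.log_model`); `aduci simulate` generates seeded synthetic logs with
known injected pathologies and a ground-truth JSON sidecar, which the test
suite uses to verify that the pipeline recovers every injected pathology
exactly.

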