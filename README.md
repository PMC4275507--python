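# heartcoach

A rule-based **education and coaching engine for heart-failure self-care**,
with a synthetic-cohort simulator and journey reporting.

Patients with heart failure are asked to manage much of their own care —
take medication as prescribed, stay physically active, eat a low-salt diet,
restrict fluid intake — yet adherence to these behaviors is notoriously
poor. Automated tele-coaching programs address this by assessing each
patient's behavior and knowledge, tailoring education to the gaps, and then
coaching behavior change through weekly personal goals, a daily diary, and
tailored feedback, escalating to a heart-failure nurse only when a patient
keeps struggling. `heartcoach` implements such a program as a testable
engine: every interaction is a timestamped event, every decision rule is
explicit and configurable, and entire patient cohorts can be replayed,
simulated, and tabulated. It is aimed at researchers in digital health and
behavior change who want to study, extend, or re-analyze goal-setting
coaching protocols without the original delivery hardware.

## The model

Per behavior, each patient occupies a cell of a 2×2 **knowledge × behavior
matrix**: *does* the patient perform the behavior, and does the patient
*know* why it matters? Neither → education, then coaching (area 1); does
but doesn't know → education only (area 2); knows but doesn't do →
coaching only (area 3); both → nothing (area 4). Behavior flags come from
a 5-point agree-scale questionnaire (any item under the cutoff, default 4,
flags the behavior as not performed); knowledge flags from multiple-choice
items where "I don't know" is always scored incorrect.

Nonadherent patients rate the behavior's perceived **importance** and their
**confidence** in adopting it on 0–10 motivational-interviewing rulers
(threshold 7, importance first): low importance triggers myth/truth
messages, low confidence barrier tips, otherwise encouragement.

**Coaching** then runs a per-behavior state machine:

    nonadherent → ic_assessed → coaching → adherent
        adherent → continued_coaching (new goals, new prompt after the
                                       next 2 achieved weeks)
        adherent → stopped_after_adherent → follow-up every 60 days →
                   maintained | relapsed (re-coach or stop)

A weekly goal (e.g. *3 days of 15–30 min activity*, or *2 g sodium/day*)
is evaluated against the daily diary when its 7-day window closes:
activity weeks are achieved when at least the planned number of days
reached the planned minutes band; diet/fluid weeks when the target was met
every reported day of the week; medication weeks when the planned doses
were taken daily. **Adherence** = achieving the personal goal for 2
consecutive weeks. Three consecutive missed weeks raise a nurse alert.
Feedback after each week is a deterministic table lookup on outcome,
day/band shortfall, and the modal effort rating (ties resolve toward
harder): a missed, shorter, too-hard week advises a less ambitious goal; a
too-easy achieved week suggests raising it.

The package also ships a trial **eligibility screener** (NT-proBNP ≥ 1000
pg/mL in sinus rhythm or ≥ 2000 otherwise; ≥ 40 mg/day furosemide
equivalent, with 1 mg bumetanide ≡ 10 mg torasemide ≡ 40 mg furosemide;
recent admission or NYHA ≥ III; standard exclusions), a **cohort
simulator** driven by per-behavior transition probabilities, and a
deterministic **123-patient fixture cohort** whose replay reproduces the
journey tables of the observational study the program was evaluated in.

## Worked example

```python
import heartcoach as hc

events = hc.fixture_study_cohort()            # 123 patients, ~10,700 events
result = hc.replay_events(events)             # journey per patient-behavior
table = hc.transition_table(result)
print(table.formatted().iloc[:, :2].to_string())
```

```
                                   Physical activity  Low-salt diet
Were nonadherent                       50/123 (40.7)  56/123 (45.5)
Started coaching                        35/50 (70.0)   47/56 (83.9)
Became adherent                         28/35 (80.0)   36/47 (76.6)
Stopped coaching immediately            11/28 (39.3)   23/36 (63.9)
Continued coaching                      17/28 (60.7)   13/36 (36.1)
Stopped coaching later on                9/17 (52.9)    6/13 (46.2)
Continued coaching until study end       8/17 (47.1)    7/13 (53.8)
```

Each cell is *entered-state count / parent-state count (percent)*: 50 of
123 patients scored nonadherent for physical activity, 70% of them started
coaching, 80% of starters reached their goal for 2 consecutive weeks, and
so on down the journey. Aggregating the goals reached at adherence:

```python
matrix = hc.goal_distribution(result, hc.BehaviorId.PHYSICAL_ACTIVITY)
count, total, pct = hc.aggregate_goal_share(matrix, lambda days, band: days >= 4)
print(f"active on >=4 days/week: {count} of {total} ({pct:.0f}%)")
# active on >=4 days/week: 17 of 28 (61%)
```

The same pipeline is available from the shell:

```bash
heartcoach fixture --out cohort.jsonl
heartcoach report --log cohort.jsonl --table transitions
heartcoach simulate -n 500 --seed 7 --out sim.jsonl   # stochastic cohort
heartcoach screen --records candidates.yaml           # trial eligibility
```

## Layout

- `src/heartcoach/assessment.py` — questionnaire scoring, matrix placement,
  importance/confidence feedback, eligibility screening
- `src/heartcoach/coaching.py` — goals, diary, weekly evaluation, feedback
  selection, adherence/relapse state machine, event-log replay
- `src/heartcoach/catalog.py` + `data/catalog.yaml` — education videos/tips,
  myth/truth and barrier messages, feedback templates (identifier stubs)
- `src/heartcoach/simulate.py` — stochastic cohort simulator and the
  deterministic 123-patient fixture
- `src/heartcoach/reporting.py` — transition, follow-up, goal, and
  non-start tables
- `src/heartcoach/eventlog.py`, `cli.py`, `config.py` — JSONL event logs,
  command-line interface, thresholds

See `docs/methods.md` for the full account of the rules, defaults, and the
fixture's construction.
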