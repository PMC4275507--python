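# Methods

This note documents the rules the engine implements, the defaults and why
they were chosen, what the synthetic cohorts do and do not emulate, and the
numerical/design choices made where the underlying program description left
the design open.

## Assessment

**Behavior scoring.** The default item bank carries 12 behavior items
(three per coachable behavior) on a 5-point agree scale, in the style of
the European Heart Failure Self-Care Behaviour Scale extended with extra
behavior probes such as reading food-package labels for sodium content. A
behavior counts as *performed* only if every one of its items is answered
at or above the cutoff (default 4 of 5). The any-item rule is deliberately
conservative: coaching a patient who is in fact adherent is low-harm,
whereas missing a nonadherent patient forfeits the intervention. Scoring is
therefore monotone — improving any single answer can never turn a
performed behavior into a not-performed one (property-tested).

**Knowledge scoring.** 15 knowledge items (three per coachable behavior,
one per education-only topic) offer three substantive options plus
"I don't know", which is always scored incorrect — the option exists
precisely so that guessing is not rewarded. Knowledge is *sufficient* when
at most `knowledge_tolerance` answers are wrong or "don't know"; the
default tolerance is 0 because no published cutoff exists for
"insufficient knowledge" and a single gap is enough to justify offering a
short video. Both instruments are configuration, not claims of fidelity:
the original scales are not public item-by-item, so deployments swap in
their own bank through the same YAML schema.

**Matrix placement** maps the two flags to areas 1–4 bijectively; the
prescribed path (education→coaching / education / coaching / none) is a
pure function of the area. Area 1 *gates* coaching: the engine rejects a
first goal until the behavior's required education content has been viewed.

**Importance/confidence.** Ratings use 0–10 rulers with threshold 7 — the
standard motivational-interviewing ruler convention; the program
description gives no scale. When both ratings are low only the importance
feedback is delivered (importance is listed first in the source protocol,
and stacking both message sets in one session dilutes each).

**Eligibility.** Loop-diuretic equivalence is 40 mg furosemide ≡ 1 mg
bumetanide ≡ 10 mg torasemide; an unknown diuretic name is an error, never
a silent pass. "Advanced or unstable disease" is operationalized as an HF
admission within 60 days OR NYHA ≥ III, mirroring the two protocol
bullets. The verdict is the conjunction of independent predicates and the
reason list enumerates every failed criterion (tested against a brute-force
conjunction on randomized records).

## Coaching

**Weeks.** A week is a fixed 7-day window opening on the goal-set date.
Evaluation fires when the window has closed — triggered by the first event
after it or by study end. Diary entries are unique per patient-behavior-day
and must fall inside the open window, so weeks partition days and no entry
is ever counted twice.

**Achievement predicates.** Activity: a diary entry on a day counts as
activity; the week is achieved when the number of days *at or above the
planned minutes band* reaches the planned day count (being active longer
than planned counts; shorter does not — "days" and "minutes" both matter).
Diet and fluid goals use a daily met-target flag rather than grams/liters
(the source system's diary fields for these are not described; a boolean
keeps the entry burden model simple); the week is achieved when the target
was met on the configured fraction of week days, default all 7, with
unreported days counting as not met. Medication weeks require the planned
doses on every day. A missed diary day counts as no activity/unmet — a
choice, not a documented rule.

**Feedback** is a total, deterministic table over (outcome, fewer days than
planned?, sessions below planned band?, dominant effort). Dominant effort
is the modal rating over active days with ties resolved toward the harder
rating, so borderline weeks err toward gentler goals. All key combinations
map to one of five templates (totality is enumerated in tests).

**Adherence** is two consecutive achieved weeks (the source program's
definition). After each adherence the outcome streak resets: a continuing
patient must achieve two fresh consecutive weeks before the next
continue/stop prompt, consistent with patients repeatedly confirming
continuation every time they re-achieved their goal.

**Struggle alerts.** "Continually experiencing difficulties" is
operationalized as 3 consecutive missed weeks (no number is published; 3
balances alert fatigue against delay). Exactly one alert per missed streak,
fired when the streak reaches 3, from the coaching state only.

**Relapse follow-up.** "Two months" is 60 days exactly. Follow-ups recur
every 60 days while the patient remains stopped-and-maintained; a relapsed
patient either re-enters coaching (a fresh goal is required; the next
follow-up is scheduled only after the next stop) or leaves the program.

**State machine.** The eleven journey states and their edges are encoded as
an explicit legality table; any (state, event) pair off the graph raises an
error naming both. Journeys are independent across behaviors, and replaying
a log is deterministic — same states, evaluations, feedback ids, alerts.
Medication and fluid goals run through the identical loop even though few
patients in the source study used them; the engine is behavior-generic.

## Synthetic cohorts

**The fixture** is hand-scripted data, not a sample: 123 patients whose
questionnaire answers score to the published nonadherence counts
(50/56/6/6) and whose event logs replay to the published transition counts,
follow-up tallies, reached-goal distributions, and non-start reasons. Key
scripting choices:

- Calendar: study day 0 = 2012-03-01; an explicit study-end event at day
  210 censors open journeys. The 210-day horizon stages follow-up receipt:
  patients scripted to stop more than 60 days before study end receive the
  questionnaire, later stoppers do not, reproducing the published
  received-counts (13/15/1/2) without any dedicated "no follow-up" flag.
- Adherent journeys are two achieved weeks per continue/stop cycle, with
  prompts every 14 days; "until study end" patients answer continue at
  every prompt and end in a censored partial week.
- Starters who never became adherent (7 activity, 11 salt, 2 fluid) are
  not a printed table row; their count is forced by arithmetic
  (starters − adherent) and they are scripted as censored in coaching,
  reported in a separate censored column.
- The goal reached at first adherence is scripted per patient to populate
  the published activity days×minutes matrix (total 28) and sodium-goal
  distribution (total 36) cell-exactly.
- 20 non-start reason records cover 17 distinct patients (some patients
  gave reasons for more than one behavior); the per-reason tally matches
  the published table.
- Even-numbered patients lack knowledge for their nonadherent behaviors
  (area 1, education-gated); odd-numbered know but do not do (area 3).
- Demographics (97 men, mean age 66.2, 49 over 70, 81 NYHA III) are
  deterministic per-patient values for report headers only.

**The simulator** draws per-behavior journeys from configurable transition
probabilities (nonadherence, coaching start, weekly achievement, first
continue choice, later stop-per-prompt, relapse at follow-up, retry after
relapse), emitting engine-legal raw events — including questionnaire
answers that *score to* the drawn nonadherence flag, so simulated logs
exercise the same pipeline as real ones. Weekly outcomes are independent
Bernoulli draws, so empirical frequencies recover the parameters (verified
within three binomial standard errors at n=5000). `study_calibrated_params`
packages the observed study shares as a configuration.

What the synthetic data does **not** emulate: real diary noise (partial
weeks, erratic entry timing), correlated behaviors within a patient,
importance/confidence heterogeneity among starters, vital signs,
hospitalization, or mortality. Passing tests show the engine's rules and
bookkeeping are correct and that the published tables are consistent with
the program's state machine — not that the behavioral findings would
replicate in a new cohort.

## Numerical and I/O choices

- Percentages round half-up to one decimal in exact decimal arithmetic
  (matching the published 40.7 = 50/123; float rounding would be
  banker's).
- Event logs are line-delimited JSON with canonical key order — greppable,
  streamable, append-only, and byte-stable on rewrite; dates are ISO-8601
  days because the program logic is day-granular.
- All thresholds (cutoffs, tolerance, ruler thresholds, week length,
  struggle streak, follow-up interval) live in one YAML-loadable config
  with the defaults above.
- Content is identifiers plus title stubs; media assets are out of scope.
  Referential closure — every id the engine can emit resolves in the
  catalog — is tested.

## Problem sizes

The fixture replay handles ~10,700 events for 123 patients in about a
second. Stochastic checks use cohorts of 3,000–5,000 patients over a
120–150-day horizon (tens of thousands of events, a few seconds), which
keeps binomial standard errors small enough for 3-SE parameter-recovery
assertions to be meaningful.

## Known limitations

- The questionnaire banks are plausible stand-ins, not the validated
  instruments; psychometric properties are out of scope.
- Adherence is self-reported by construction; the engine has no notion of
  objective measurement (accelerometry, urinary sodium, dispensers).
- The continue/stop and relapse semantics follow the published narrative;
  where the narrative is silent (streak reset, missed-diary handling,
  struggle threshold) the choices above apply and are configurable where
  reasonable.
- Scheduling is logical, not real-time: the engine evaluates weeks when
  events arrive, and emits alerts and follow-up due-dates as records only.
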