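# Methods

This note documents the models, rules and numerical choices behind
`hftitrate`, and what the simulator does and does not emulate.

## The monitoring model

Each patient transmits at most one accepted sample per parameter per day.
Alarm bounds (defaults): weight ≥ baseline + 2 kg; heart rate < 60 or
> 100 bpm; systolic < 90 or > 160 mm Hg; diastolic < 60 or > 95 mm Hg.
Bound semantics differ on purpose: HR/BP bounds are strict inequalities
(a reading exactly on the bound is normal), while the weight rule is
inclusive because "baseline + 2 kg" names the alarm level itself. The
baseline weight is the enrollment-day weight and is never recomputed;
drift in "true" weight therefore shows up as crossings, which is the
intended clinical behavior.

A sustained alert requires the *same* parameter to cross on `run_length`
(default 3) consecutive calendar days, each day carrying a valid
measurement. Two deliberate readings of an ambiguous rule: different
parameters crossing on successive days never jointly alert, and a missing
day breaks the run — the conservative interpretation that avoids alerting
on sparse or mixed evidence. One alert is emitted per maximal run (it fires
on day `run_length`; days 4, 5, … of a longer run do not re-alert until the
run is broken). Equivalence with a brute-force scan over all contiguous
3-day windows is property-tested on random streams.

Weekend handling is date-level: a review task whose run ends Saturday or
Sunday becomes visible the next working day.

## The engagement model

Window geometry is fixed: open = ideal − 1 h, reminder = ideal + 2 h,
close = ideal + 4 h (a 5-hour window). The first in-window app response is
terminal; later responses are ignored. Escalation for an unresolved window:
no-registration tag at close, then a phone call due within 12 h of close,
placed at the first working instant ≥ close (working hours default
Mon–Fri 08:00–17:00, configurable). This composes correctly with weekends:
a Saturday-morning miss is called Monday 08:00.

Outcome vocabulary and accounting: `confirmed_app`, `confirmed_callcenter`,
`declined_app`, `declined_callcenter`, `no_recording` (the last only for
vitals/questionnaires — an intake call always yields a confirm/decline, so
an unreachable patient's intake is booked as `declined_callcenter`).
Adherence = (confirmed_app + confirmed_callcenter) / total, reported at two
decimals with half-up rounding; frequency tables use half-up at the
precision of the corresponding summary (0 dp for proposal/nurse tables).
Call-center quartiles use linear-interpolation percentiles so the toy
example (per-patient counts 2, 4, 6 → median 4, IQR 3–5) is exactly
reproducible.

## The titration model

Schedule: ⌊active_phase_days / interval⌋ slots at enrollment + 14, 28, …
days, alternating β-blocker first; ACE-I slots carry a blood request 7 days
ahead; every slot carries a questionnaire due the day before (the protocol
only requires it "before" the proposal; one day gives the patient the whole
previous day to answer). Proposals are generated at 08:00 on the due date.
After the active phase the engine generates nothing automatically; a manual
slot hook (`manual_proposal_event`) exists for nurse-initiated proposals in
the less-intensive phase.

The classification cascade (first match wins) is a reconstruction of a
three-family outcome scheme — conclusive uptitrate / conclusive hold /
nurse evaluation for incomplete, aberrant-vitals or aberrant-blood reasons —
with thresholds the protocol leaves unquantified fixed as explicit
parameters:

- completeness cutoff 0.8 over the 14-day window (completeness = measured
  days / window days);
- renal aberrance: eGFR < 30 mL/min/1.73 m², or a drop > 25 % from the
  enrollment baseline; blood older than 14 days counts as missing rather
  than aberrant;
- any symptom red flag routes to the nurse rather than auto-refusing —
  the design favors a large safety margin over algorithmic autonomy.

Safety invariants are structural, not statistical: dose changes go through
`apply_review` only, move exactly one ladder step, and raise
`SafetyViolationError` at the top step; `UPTITRATE` cannot be produced when
the evidence window contains a crossing because the aberrant branch
precedes it in the cascade. Both are re-checked empirically over 100 seeded
cohorts in the acceptance suite.

Default ladders end at the guideline maxima (validated at construction);
intermediate steps follow common titration practice, e.g. bisoprolol
1.25/2.5/3.75/5/7.5/10 mg. Ladders are configurable; the engine only
requires strictly increasing steps ending at the stated maximum.

## The cohort simulator

The simulator emulates the *study conditions*: 14 patients followed 182
days (91-day active phase), daily vitals plus three intake confirmations
(β-blocker and diuretic 08:00, ACE-I 20:00), pre-proposal questionnaires
and biweekly blood draws (2-day lab turnaround, 90 % completion).

Baselines are truncated normals — heart rate 73 (13) bpm, systolic 112 (14)
and diastolic 75 (12) mm Hg, eGFR 50 (28) mL/min/1.73 m², weight 81 (14) kg
(a cohort BMI of ~28 at 1.70 m; the source population reports BMI, not
weight). Behavior probabilities are calibrated so the expected ledger
composition matches the observed accounting: in-app confirm 0.7681, in-app
decline 0.0324, phone confirm 0.7885 conditional on a missed registration
(unconditional share ≈ 0.157); device technical-failure rate 0.18 with
phone recovery 0.7033 conditional (so ≈ 12.7 % of vitals arrive by phone
and ≈ 5.3 % are never recorded). Daily symptom-flag probability 0.05 —
a value chosen once as a plausible red-flag rate; nothing in the pipeline
is sensitive to it except the proposal-outcome mix.

Vital generation is `baseline + step_index × per-step shift + N(0, sd)`
per parameter (noise SDs 0.4 kg, 4 bpm, 7/5 mm Hg), with default per-step
shifts of −2 bpm and −1.5/−1 mm Hg for the β-blocker and −3/−2 mm Hg for
the ACE-I. Dose response is linear in ladder step and immediate — enough
to close the loop (doses shift vitals, vitals gate proposals) and to be
recovered by regression in tests, but explicitly non-physiological: no
pharmacokinetics, no lag, no tolerance, no inter-day correlation beyond
the dose term.

The titration loop runs inside the simulation with a pluggable nurse
policy; the default confirms conclusive proposals, phones the patient for
nurse-evaluation outcomes (uptitrating only when nothing aberrant was
seen), and marks the dose optimal at the ladder top.

Determinism: each patient's stream comes from `SeedSequence([seed, index])`,
so a fixed config reproduces the JSONL log byte-for-byte; this is asserted
in tests and required of any refactor.

### What passing tests do and do not show

The simulator shares its event vocabulary and rule set with the engine, so
green tests demonstrate internal consistency (conservation of actions into
ledger entries, calendar correctness, safety caps, probability recovery) —
not fidelity to real patients. Real cohorts have correlated missingness,
weekday effects, dropout, device swaps, and congestion-driven weight gain,
none of which are modelled. Call counts in simulated runs are
also higher than a real service would log: every missed action generates
its own call record, with no per-day batching of calls to the same patient.

## Numerical / degenerate-input choices

- Percentages: decimal half-up, never float rounding; zero denominators
  yield 0.0 and empty reports rather than exceptions.
- Truncated-normal sampling by rejection (≤ 1000 draws) — adequate for
  physiologic ranges ≥ ~2 SD wide; a range excluding essentially all mass
  raises a configuration error. `sd = 0` degenerates to the mean exactly.
- Vitals are floored at 20 (units of the parameter) so additive noise can
  never produce a non-positive, hence invalid, sample.
- Phone-recovered vital samples keep their measurement date but are
  recorded at the call instant, which may be a later working day; device
  samples must be recorded on their measurement date.
- Quantiles: `numpy.percentile(..., method="linear")`.
- Ties/ordering in the event log: per-patient emission sequence numbers and
  a (date, patient, seq) sort make logs fully ordered and reruns
  byte-identical.

## Known limitations

- The classification cascade is a faithful reconstruction of a published
  outcome taxonomy, not a copied decision tree; branch thresholds
  (0.8 completeness, eGFR rules) are explicit parameters precisely because
  they are choices.
- The symptom questionnaire is reduced to generic red-flag booleans; no
  scoring model exists.
- One nurse action per proposal: real reviews can combine responses
  (contact *and* change another drug); the accounting layer therefore
  accepts externally supplied count tables with an explicit denominator.
- The simulator's adherence process is i.i.d. per action; real adherence
  is patient- and drug-correlated (per-drug behavior parameters exist but
  ship symmetric).
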