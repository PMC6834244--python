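# hftitrate

A rules engine and synthetic-cohort simulator for **remote heart-failure
medication uptitration**. Heart-failure guidelines call for stepping
β-blockers and ACE inhibitors up to the maximum tolerated, evidence-based
daily dose, but in routine practice many patients stay on suboptimal doses.
Telemonitoring platforms attack this by transmitting daily weight, blood
pressure and heart rate from home, prompting patients to confirm each
medication intake, and generating semiautomatic dose-increase proposals that
a heart-failure nurse reviews. `hftitrate` implements that workflow as a
testable library plus CLI, for people who design, stress-test or audit such
remote-titration protocols. No patient data is required: a built-in cohort
simulator generates realistic daily event streams.

## What it implements

**Telemetry monitoring** (`hftitrate.telemetry`). Each daily sample is
checked against alarm bounds — weight ≥ baseline + 2 kg, HR < 60 or
> 100 bpm, SBP < 90 or > 160 mm Hg, DBP < 60 or > 95 mm Hg (HR/BP bounds
strict, weight inclusive). When the *same* parameter crosses on 3 consecutive
measured days, one sustained alert fires per maximal run: a symptom
questionnaire is pushed to the patient and the clinical call center gets a
review task (deferred to Monday for weekend alerts).

**Engagement & adherence** (`hftitrate.engagement`). Every scheduled action
(intake confirmation, measurement, questionnaire) has a 5-hour window opening
1 h before and closing 4 h after the ideal time, with a reminder at +2 h. An
unresolved window produces a *no-registration* tag and a technical-call-center
phone call due within 12 h, shifted into working hours (Mon–Fri 08:00–17:00
by default). Each action ends in exactly one ledger outcome —
`confirmed_app`, `confirmed_callcenter`, `declined_app`,
`declined_callcenter`, or `no_recording` — and adherence is
(confirmed\_app + confirmed\_callcenter) / total.

**Titration engine** (`hftitrate.titration`). Proposal slots every 14 days,
alternating β-blocker → ACE-I starting at enrollment + 14 days, for a 91-day
active phase (hence ⌊91/14⌋ = 6 slots); a blood-withdrawal request precedes
each ACE-I slot by 7 days and a short questionnaire precedes every slot.
A fixed first-match cascade classifies each slot:

1. at ladder top / flagged optimal → `NO_UPTITRATION`
2. window completeness < 0.8 or questionnaire missing → `NURSE_EVAL_INCOMPLETE`
3. any threshold crossing in the 14-day window → `NURSE_EVAL_ABERRANT_VITALS`
4. ACE-I only: blood missing/stale (> 14 d) → `NURSE_EVAL_INCOMPLETE`;
   eGFR < 30 or > 25 % below baseline → `NURSE_EVAL_ABERRANT_BLOOD`
5. any symptom red flag → `NURSE_EVAL_ABERRANT_VITALS`
6. otherwise → `UPTITRATE`

Only a nurse review changes the plan: one ladder step at a time, never past
the guideline maximum (bisoprolol 10, nebivolol 5, enalapril/ramipril/
perindopril 10, lisinopril 20, candesartan 16, losartan 100 mg/day — exceeding
it raises `SafetyViolationError`). Diuretics are adherence-monitored, never
titrated. Every review lands in an append-only audit log.

**Cohort simulator** (`hftitrate.simulate`) and **reporting**
(`hftitrate.reporting`, `hftitrate.cli`): deterministic day-by-day cohorts
(vitals respond linearly to dose step; device failures are phone-recoverable;
behavior is governed by per-patient probabilities) and pure-function reports
of adherence, proposal/nurse-response frequencies, call-center statistics and
titration trajectories.

## Worked example

```bash
hftitrate run --patients 14 --days 182 --seed 7 --out-dir out
```

writes `events.jsonl` (the full event stream), `ledger.csv`,
`ground_truth.yaml` and `report.json`. With seed 7 the log holds 10,276
scheduled actions and the report reads:

```
adherence overall : 93.30 %
  medication      : 92.79 %   vitals: 94.94 %
proposals         : 84 total  (14 patients x 6 biweekly slots)
  NURSE_EVAL_ABERRANT_VITALS 72 (86%)   NURSE_EVAL_INCOMPLETE 10 (12%)
  UPTITRATE 2 (2%)            conclusive share 2%
nurse reviews     : CONFIRM 2, CONTACT_PATIENT_THEN_DECIDE 82
```

Read it as: with the default engagement probabilities roughly 93 % of all
scheduled actions end confirmed (in-app or by phone); every patient gets
exactly 6 proposals in the 91-day active phase; and because the cascade is
deliberately conservative, most proposals route to the nurse — here mostly
for aberrant vitals, since simulated baselines near the alarm bounds cross
them regularly. `hftitrate report --events out/events.jsonl` recomputes the
identical report from the log alone.

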