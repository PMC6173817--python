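# Methods

## The alert model

A reading is a triple (SBP, DBP, pulse) with SBP > DBP and each component
inside a plausibility window (SBP 40–300, DBP 20–200 mm Hg, pulse 20–250
beats/min); anything outside is rejected with a reason code rather than
classified. Two independent pathways score each reading:

- **Hypertension**: tier(SBP against 140/160) ∨ tier(DBP against 90/110),
  i.e. the worse of the two components. Pulse never enters.
- **Shock**: tier(SI against 0.9/1.7) where SI = pulse/SBP. The tier is
  computed on the exact ratio; rounding (2 decimals, half-to-even) exists
  only for display, so a reading can never change tier because of how its
  SI is printed.

The overall colour is the maximum severity of the two tiers. The reported
*condition* is shock whenever the shock tier is at least yellow, even when
hypertension supplies the colour: shock, particularly haemorrhagic,
usually needs the more urgent response, and the display follows the
condition (flashing down arrow for shock, constant up arrow for
hypertension-only alerts). Both pathway tiers are kept on the result, so
a shock-yellow + hypertension-red reading loses no information: it shows
red with the shock display. Utility states (low battery, error) are
display-map entries only and never participate in logic.

Boundary convention defaults to inclusive (≥), matching the usual reading
of "140/90 defines hypertension"; a strict mode is exposed because
conventions differ between chart systems. All six thresholds live in
`ThresholdConfig` (YAML-loadable), not in code, so a revision of the
published cut-offs is a configuration change.

## Device-validation statistics

Validation sequences alternate reference and device measurements on the
same arm, starting and ending with the reference (default seven
measurements → three device readings). The default pairing scheme,
`flanking_mean`, compares each device reading with the mean of its two
flanking reference readings — the convention of sequential same-arm BHS
validation, which cancels slow drift in the subject's true pressure;
`same_index` (device vs immediately preceding reference) is offered for
sensitivity analysis. On a constant reference sequence the two schemes
coincide.

Differences are device − reference. Summaries are the arithmetic mean and
sample SD (n−1); the ISO criterion passes a component iff |mean| ≤ 5 and
SD ≤ 8 mm Hg (boundary inclusive, sign-symmetric on the mean — the
protocol's "≤5±8" is read as a bound on the magnitude of the bias). BHS
grades come from cumulative percentages of |differences| within 5/10/15
mm Hg against the grade table (A: 60/85/95, B: 50/75/90, C: 40/65/85; D
otherwise); the table is configuration with these standard defaults, and a
grade requires all three of its percentages. Reports are produced overall
and within arm-circumference strata, default closed bands [22, 32] and
[33, 42] cm.

## Cohort evaluation

Each cohort row is classified by the alert engine and tabulated per colour
against a named binary outcome. Per-tier risk is events/(events+total);
tiers with no subjects are *undefined*, never zero. Risk ratios are
relative to green; the trend flag is the non-strict ordering
risk(green) ≤ risk(yellow) ≤ risk(red). Diagnostic metrics dichotomise at
yellow-or-worse by default (red-only available) and flag undefined ratios
explicitly.

Odds ratios are crude: OR = ad/bc with the Woolf (log-normal) 95% CI
exp(ln OR ± 1.96·SE), SE = √(1/a+1/b+1/c+1/d), and a two-sided p-value
from the normal approximation on ln OR. The Haldane–Anscombe 0.5
correction is opt-in and applied to all four cells only when some cell is
zero. Adjusted or cluster-aware estimators are deliberately out of scope;
published adjusted estimates will therefore not be reproduced exactly by
this crude estimator (the reconstructed surveillance table gives 0.6043
where an adjusted analysis reported 0.58 — the package does not force
agreement). The pre/post analysis treats the post phase as exposed, so an
OR < 1 means the indicator became rarer after the intervention.

## Synthetic data

A single integer seed feeds a `numpy` `SeedSequence` tree, so every
generator is independently reproducible and byte-identical across runs.

**Population.** A three-class mixture (normotensive 115/72 ± 10/8,
pulse 82 ± 10; hypertensive 152/98 ± 12/8, pulse 86 ± 12; shocked
92/56 ± 12/10, pulse 124 ± 18; SBP–DBP correlation 0.5) truncated by
rejection to the plausibility windows with SBP > DBP. Default weights
0.70/0.20/0.10. The shocked class emulates haemodynamic compromise from
haemorrhage or sepsis; its parameters (like all class defaults) are
illustrative choices of plausible obstetric values, not fits to any
clinical dataset.

**Paired study.** Per subject, a true pressure is drawn (SBP 120 ± 15,
DBP 75 ± 10, DBP capped 15 mm Hg below SBP); reference readings equal the
truth plus optional within-subject noise, device readings add an
arm-circumference-dependent bias (default 0 below 33 cm, +10 mm Hg at or
above — a cuff that overestimates on large arms) plus Normal(0, 3²)
measurement error. Default design: 52 subjects split evenly across the
22–32 and 33–42 cm bands, seven measurements each. `within_subject_sd`
defaults to 0 so that device-minus-reference differences are *exactly*
Normal(bias, error_sd²) under either pairing scheme; reference drift is a
separate, explicit knob rather than an implicit property of every
simulation.

**Outcome cohort.** Tier-targeted generation uses rejection sampling: a
broad candidate mixture is drawn, each candidate is classified against the
supplied threshold config (via a vectorised mirror of the rule table,
cross-checked against the scalar engine in tests), and tiers are filled to
quotas obtained by largest-remainder rounding of the designed proportions
(default 0.5/0.3/0.2) — correct under any threshold configuration, at the
cost of discarding draws. Generation aborts with an explicit error if a
quota is unfilled after a bounded number of batches (infeasible designs).
Outcomes are Bernoulli per designed tier risk (default 0.02/0.10/0.30,
non-decreasing enforced unless disabled).

**Pre/post.** Bernoulli indicator draws at the two designed proportions;
defaults mirror a surveillance design with 694 women before and 547 after.

What passing tests on these generators show is *internal* consistency —
the pipeline recovers parameters it planted, at sampling-theory rates.
Real vital signs are longitudinal, autocorrelated, digit-preferenced and
device-rounded, and real outcome risks vary continuously with pressure
rather than jumping at tier boundaries; none of that is emulated, so
passing here does not certify clinical performance.

## Numerical and design notes

- Classification uses exact comparisons on floats; generated vitals are
  rounded to 0.1 and drawn with a >0.2 mm Hg SBP−DBP margin so rounding
  cannot create SBP ≤ DBP.
- `difference_stats` requires ≥ 2 pairs (sample SD) and signals an empty
  stratum with a dedicated exception instead of returning zeros.
- File formats are delimited text with explicit headers; numeric output
  uses shortest-round-trip formatting so write→read is exact. Rejected
  rows are reported with line numbers and counted in the per-run manifest;
  they never abort a run silently.
- The acceptance script simulates the auscultatory-use accuracy study at
  its reported size (255 pairs, differences Normal(2.2, 6.1²) mm Hg) as
  85 seven-measurement sequences → 3 flanking pairs each; the mean and SD
  it reports are measured from the simulated pairs by the validation
  module, then judged against the ISO bounds.
- Known limitations: no time-to-event or multivariable modelling; no
  oscillometric waveform processing; antenatal/postnatal contexts share
  one threshold table (no published basis for separating them); exact or
  conditional CIs for sparse 2×2 tables are not provided.
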