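# vsalert

Traffic-light vital-signs early warning for pregnancy, with the statistics
needed to validate the measuring device and to evaluate the alert
thresholds against clinical outcomes.

Haemorrhage, hypertensive disorders and sepsis drive most preventable
maternal deaths, and each announces itself through blood pressure and
pulse. `vsalert` implements, in library form, the alerting logic of a
low-cost semiautomated BP/pulse device intended for minimally trained
healthcare providers in low-resource maternity care, together with the
analysis pipelines that surround such a device:

- **`vsalert.ews`** — the traffic-light engine. Hypertension tiers trigger
  on SBP/DBP thresholds (defaults: yellow at 140/90, red at 160/110 mm Hg);
  shock tiers trigger on the **Shock Index**, SI = pulse / SBP (defaults:
  yellow at 0.9, red at 1.7). The alert colour is the more severe tier, but
  whenever shock alerts the displayed condition is shock (flashing down
  arrow rather than the constant up arrow of hypertension), because shock
  usually demands the more urgent response.
- **`vsalert.validation`** — adapted BHS/ISO paired-difference device
  validation: pairing of alternating same-arm measurement sequences
  (flanking-mean or same-index), mean ± SD of device-minus-reference
  differences, the ISO criterion (|mean| ≤ 5 and SD ≤ 8 mm Hg), BHS A–D
  grades from cumulative percentages of |differences| within 5/10/15 mm Hg,
  overall and per arm-circumference stratum (22–32 vs 33–42 cm).
- **`vsalert.cohort`** — tier-vs-outcome evaluation (per-tier risk, risk
  ratios, monotone-trend check, sensitivity/specificity/likelihood ratios
  after dichotomising at a tier) and crude 2×2 odds ratios with Woolf 95%
  confidence intervals for before/after surveillance comparisons.
- **`vsalert.synth`** — seed-controlled generators for all of the above:
  mixed obstetric populations (normotensive / hypertensive / shocked),
  paired studies with arm-circumference-dependent device bias, outcome
  cohorts with designed per-tier risks, and pre/post indicator samples.
- **`vsalert.cli`** — a `vsalert` command with `classify`,
  `validate-device`, `evaluate` and `simulate` subcommands; every run
  writes a JSON provenance manifest. A commented threshold-configuration
  template ships in `examples/thresholds.yml`.

## Worked example

```python
from vsalert import ThresholdConfig, validate_reading, alert

cfg = ThresholdConfig()  # 140/90, 160/110, SI 0.9/1.7, inclusive
r = validate_reading({"subject_id": "w1", "sbp": 100, "dbp": 60, "pulse": 95})
res = alert(r, cfg)
print(res.colour, res.condition, res.display, res.shock_index.rounded())
# yellow shock flashing down arrow 0.95
```

A normotensive pressure of 100/60 raises no hypertension flag, but a pulse
of 95 at that systolic pressure gives SI = 0.95 ≥ 0.9: a yellow *shock*
alert with the flashing down arrow.

Simulating a wide-range-cuff validation study in which the device
overestimates by 10 mm Hg on large arms (the generator default), then
running the paired-difference analysis:

```python
from vsalert.synth import PairedStudySpec, generate_paired_study
from vsalert.validation import run_validation

report = run_validation(generate_paired_study(PairedStudySpec(seed=7)))
for s in report.strata:
    print(s.stratum, round(s.stats.mean_sbp, 2), s.iso.overall_pass, s.bhs.grade_sbp)
# (22.0, 32.0) -0.61 True A
# (33.0, 42.0) 10.06 False D
```

The small-arm stratum passes ISO with BHS grade A; the large-arm stratum's
+10 mm Hg bias fails the |mean| ≤ 5 bound and grades D — the pattern that
disqualifies a cuff for use across the whole arm-circumference range.

Crude odds ratio for a surveillance indicator falling from 174/694 (25.1%)
before an intervention to 92/547 (16.9%) after:

```python
from vsalert.cohort import TwoByTwo, odds_ratio
o = odds_ratio(TwoByTwo(92, 455, 174, 520))
print(round(o.odds_ratio, 4), round(o.ci_low, 3), round(o.ci_high, 3))
# 0.6043 0.456 0.801
```

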