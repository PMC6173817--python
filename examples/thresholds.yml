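# Traffic-light threshold configuration template.
#
# Hypertension tiers trigger when either pressure component reaches its
# cut-off; shock tiers trigger on the Shock Index (pulse / systolic BP).
# All pressures are mm Hg; the Shock Index is dimensionless.

# Yellow (caution) hypertension cut-offs — 140/90 is the conventional
# definition of hypertension in pregnancy.
hyp_yellow_sbp: 140
hyp_yellow_dbp: 90

# Red (urgent) hypertension cut-offs — severe hypertension.
hyp_red_sbp: 160
hyp_red_dbp: 110

# Shock Index cut-offs: caution at 0.9, urgent at 1.7.
si_yellow: 0.9
si_red: 1.7

# true: a value exactly at a cut-off triggers the tier (>=, the default);
# false: strictly above only (>).
inclusive_boundaries: true

# Optional. Display symbol per "<colour>:<condition>" key; omit to use the
# defaults shown here.  The low_battery / error entries are device utility
# states and never affect classification.
display_map:
  "green:none": "none"
  "yellow:hypertension": "constant up arrow"
  "red:hypertension": "constant up arrow"
  "yellow:shock": "flashing down arrow"
  "red:shock": "flashing down arrow"
  "low_battery": "battery symbol"
  "error": "error symbol"
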