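"""Independent brute-force oracles used by the test suite.

These deliberately re-derive expected results from first principles —
plain rule tables and two-pass arithmetic — without touching the package's
classification or statistics code paths.
"""

from __future__ import annotations

import math

_SEVERITY = {"green": 0, "yellow": 1, "red": 2}

# The default rule table, hard-coded on purpose: hypertension yellow at
# 140/90, red at 160/110 mm Hg; Shock Index yellow at 0.9, red at 1.7;
# boundaries inclusive.


def brute_force_alert(sbp: float, dbp: float, pulse: float) -> dict:
    if sbp >= 160 or dbp >= 110:
        hyp = "red"
    elif sbp >= 140 or dbp >= 90:
        hyp = "yellow"
    else:
        hyp = "green"

    si = pulse / sbp
    if si >= 1.7:
        shock = "red"
    elif si >= 0.9:
        shock = "yellow"
    else:
        shock = "green"

    colour = hyp if _SEVERITY[hyp] >= _SEVERITY[shock] else shock
    if shock != "green":
        condition = "shock"
        display = "flashing down arrow"
    elif hyp != "green":
        condition = "hypertension"
        display = "constant up arrow"
    else:
        condition = "none"
        display = "none"
    return {
        "colour": colour,
        "condition": condition,
        "hypertension_tier": hyp,
        "shock_tier": shock,
        "display": display,
    }


def two_pass_mean_sd(values) -> tuple[float, float]:
    """Naive two-pass mean and sample SD (n-1), pure Python arithmetic."""
    n = len(values)
    mean = sum(values) / n
    ss = sum((v - mean) ** 2 for v in values)
    sd = math.sqrt(ss / (n - 1)) if n > 1 else float("nan")
    return mean, sd


def cumulative_within(abs_diffs, bounds=(5.0, 10.0, 15.0)) -> tuple[float, ...]:
    """Hand-counted cumulative percentages of |differences| within bounds."""
    n = len(abs_diffs)
    return tuple(100.0 * sum(1 for d in abs_diffs if d <= b) / n for b in bounds)
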