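"""Threshold-vs-outcome evaluation and pre/post intervention comparison.

Links traffic-light alert tiers to binary adverse outcomes (per-tier risk,
risk ratios vs green, monotone-trend check, diagnostic metrics after
dichotomising at a tier) and provides the crude 2x2 odds-ratio machinery
(Woolf log-normal confidence interval, normal-approximation p-value,
optional Haldane-Anscombe correction) used for before/after surveillance
comparisons.  Adjusted or cluster-aware models are deliberately out of
scope: every estimate here is crude and documented as such.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .ews import Condition, ThresholdConfig, Tier, VitalReading, alert

__all__ = [
    "OutcomeCohort",
    "TierOutcomeTable",
    "TierRiskMetrics",
    "DiagnosticMetrics",
    "TwoByTwo",
    "OddsRatioResult",
    "PrePostResult",
    "GROUPS",
    "tier_outcome_table",
    "tier_risk_metrics",
    "diagnostic_metrics",
    "odds_ratio",
    "prepost_analysis",
]

GROUPS = ("hypertension", "haemorrhage", "sepsis")


@dataclass(frozen=True)
class OutcomeCohort:
    """Readings joined to a condition group and binary outcome indicators.

    ``readings`` aligns with the rows of ``outcomes`` (a boolean DataFrame,
    one column per named outcome, e.g. ``icu_admission``); ``groups`` is
    the admitting condition per row.
    """

    readings: tuple[VitalReading, ...]
    groups: tuple[str, ...]
    outcomes: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.readings)
        if len(self.groups) != n or len(self.outcomes) != n:
            raise ValueError("readings, groups and outcomes must align")
        bad = [g for g in self.groups if g not in GROUPS]
        if bad:
            raise ValueError(f"unknown condition groups: {sorted(set(bad))}")
        for col in self.outcomes.columns:
            if self.outcomes[col].dtype != bool:
                raise ValueError(f"outcome column {col!r} must be boolean")

    @property
    def outcome_names(self) -> tuple[str, ...]:
        return tuple(self.outcomes.columns)

    def __len__(self) -> int:
        return len(self.readings)

    def to_frame(self) -> pd.DataFrame:
        base = pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.readings],
                "timestamp": [r.timestamp or "" for r in self.readings],
                "sbp": [r.sbp for r in self.readings],
                "dbp": [r.dbp for r in self.readings],
                "pulse": [r.pulse for r in self.readings],
                "context": [str(r.context) for r in self.readings],
                "group": list(self.groups),
            }
        )
        return pd.concat([base, self.outcomes.reset_index(drop=True)], axis=1)


@dataclass(frozen=True)
class TierOutcomeTable:
    """Event / non-event counts per alert colour for one named outcome."""

    outcome: str
    counts: Mapping[Tier, tuple[int, int]]  # tier -> (events, non-events)

    def __post_init__(self) -> None:
        for tier, (yes, no) in self.counts.items():
            if yes < 0 or no < 0:
                raise ValueError(f"negative count in tier {tier}")

    def total(self) -> int:
        return sum(y + n for y, n in self.counts.values())

    def events(self, tier: Tier) -> int:
        return self.counts[tier][0]

    def nonevents(self, tier: Tier) -> int:
        return self.counts[tier][1]


def tier_outcome_table(
    cohort: OutcomeCohort,
    cfg: ThresholdConfig,
    outcome: str,
) -> TierOutcomeTable:
    """Classify every cohort row and tabulate counts per colour x outcome."""
    if outcome not in cohort.outcomes.columns:
        raise KeyError(
            f"unknown outcome {outcome!r}; available: {list(cohort.outcomes.columns)}"
        )
    flags = cohort.outcomes[outcome].to_numpy()
    counts = {tier: [0, 0] for tier in Tier}
    for reading, event in zip(cohort.readings, flags):
        colour = alert(reading, cfg).colour
        counts[colour][0 if event else 1] += 1
    return TierOutcomeTable(
        outcome=outcome,
        counts={tier: (int(y), int(n)) for tier, (y, n) in counts.items()},
    )


@dataclass(frozen=True)
class TierRiskMetrics:
    """Per-tier outcome risk, risk ratio vs green and monotone-trend flag.

    A tier with no subjects has undefined risk (``None``), never zero; the
    trend flag is ``None`` whenever any risk is undefined.
    """

    risks: Mapping[Tier, Optional[float]]
    risk_ratios: Mapping[Tier, Optional[float]]
    monotone_trend: Optional[bool]


def tier_risk_metrics(table: TierOutcomeTable) -> TierRiskMetrics:
    """Risk = events/(events+non-events) per tier; RR relative to green;
    trend true iff risk_green <= risk_yellow <= risk_red (non-strict)."""
    risks: dict[Tier, Optional[float]] = {}
    for tier in Tier:
        y, n = table.counts[tier]
        risks[tier] = (y / (y + n)) if (y + n) > 0 else None
    green = risks[Tier.GREEN]
    rrs: dict[Tier, Optional[float]] = {}
    for tier in Tier:
        r = risks[tier]
        if r is None or green is None or green == 0:
            rrs[tier] = None
        else:
            rrs[tier] = r / green
    if any(risks[t] is None for t in Tier):
        trend = None
    else:
        trend = risks[Tier.GREEN] <= risks[Tier.YELLOW] <= risks[Tier.RED]  # type: ignore[operator]
    return TierRiskMetrics(risks=risks, risk_ratios=rrs, monotone_trend=trend)


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Standard 2x2 diagnostic metrics after dichotomising at a tier.

    Undefined ratios (zero denominators) are ``None`` and listed in
    ``undefined`` — never silently NaN.
    """

    alert_at: Tier
    a: int  # alert-positive with event
    b: int  # alert-positive without event
    c: int  # alert-negative with event
    d: int  # alert-negative without event
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    lr_positive: Optional[float]
    lr_negative: Optional[float]
    undefined: tuple[str, ...] = ()


def diagnostic_metrics(
    table: TierOutcomeTable,
    alert_at: Tier = Tier.YELLOW,
) -> DiagnosticMetrics:
    """Collapse the tier table to alert-positive (colour >= ``alert_at``)
    vs alert-negative and compute sensitivity, specificity, predictive
    values and likelihood ratios."""
    if alert_at == Tier.GREEN:
        raise ValueError("alert_at must be yellow or red")
    a = sum(table.events(t) for t in Tier if t >= alert_at)
    b = sum(table.nonevents(t) for t in Tier if t >= alert_at)
    c = sum(table.events(t) for t in Tier if t < alert_at)
    d = sum(table.nonevents(t) for t in Tier if t < alert_at)

    undefined: list[str] = []

    def ratio(num: float, den: float, name: str) -> Optional[float]:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sens = ratio(a, a + c, "sensitivity")
    spec = ratio(d, b + d, "specificity")
    ppv = ratio(a, a + b, "ppv")
    npv = ratio(d, c + d, "npv")
    lr_pos = None
    lr_neg = None
    if sens is not None and spec is not None:
        lr_pos = ratio(sens, 1.0 - spec, "lr_positive")
        lr_neg = ratio(1.0 - sens, spec, "lr_negative")
    else:
        undefined.extend(["lr_positive", "lr_negative"])
    return DiagnosticMetrics(
        alert_at=alert_at,
        a=a, b=b, c=c, d=d,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        lr_positive=lr_pos,
        lr_negative=lr_neg,
        undefined=tuple(undefined),
    )


@dataclass(frozen=True)
class TwoByTwo:
    """2x2 table: a,b = exposed event/non-event; c,d = unexposed."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must contain at least one observation")

    def swapped(self) -> "TwoByTwo":
        """Exchange the exposed and unexposed rows (OR -> 1/OR)."""
        return TwoByTwo(self.c, self.d, self.a, self.b)


@dataclass(frozen=True)
class OddsRatioResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    corrected: bool  # Haldane-Anscombe 0.5 applied


def odds_ratio(t: TwoByTwo, correction: str = "none") -> OddsRatioResult:
    """Crude odds ratio ad/bc with Woolf 95% CI and two-sided p-value.

    The CI is ``exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d))``; the
    p-value is the two-sided normal tail of ln(OR)/SE.  With
    ``correction="haldane"``, 0.5 is added to every cell when any cell is
    zero; with ``"none"`` a zero cell is rejected.
    """
    if correction not in ("none", "haldane"):
        raise ValueError(f"unknown correction {correction!r}")
    a, b, c, d = float(t.a), float(t.b), float(t.c), float(t.d)
    corrected = False
    if min(a, b, c, d) == 0:
        if correction == "none":
            raise ValueError(
                "zero cell in 2x2 table; use correction='haldane' or exact methods"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    log_or = math.log(or_)
    z = log_or / se
    return OddsRatioResult(
        odds_ratio=or_,
        ci_low=math.exp(log_or - 1.96 * se),
        ci_high=math.exp(log_or + 1.96 * se),
        p_value=float(2.0 * sps.norm.sf(abs(z))),
        corrected=corrected,
    )


@dataclass(frozen=True)
class PrePostResult:
    """Before/after comparison of a binary indicator proportion.

    The 2x2 treats the post-intervention phase as exposed, so an OR below
    one means the indicator became less frequent after the intervention.
    """

    pre_proportion: float
    post_proportion: float
    absolute_difference: float  # post - pre
    n_pre: int
    n_post: int
    or_result: OddsRatioResult


def prepost_analysis(
    pre_events: int,
    pre_n: int,
    post_events: int,
    post_n: int,
    correction: str = "none",
) -> PrePostResult:
    """Proportions per phase and the crude odds ratio of the indicator in
    the post phase relative to the pre phase."""
    if pre_n <= 0 or post_n <= 0:
        raise ValueError("phase sizes must be positive")
    if not (0 <= pre_events <= pre_n and 0 <= post_events <= post_n):
        raise ValueError("event counts must lie within phase sizes")
    table = TwoByTwo(
        a=post_events,
        b=post_n - post_events,
        c=pre_events,
        d=pre_n - pre_events,
    )
    return PrePostResult(
        pre_proportion=pre_events / pre_n,
        post_proportion=post_events / post_n,
        absolute_difference=post_events / post_n - pre_events / pre_n,
        n_pre=pre_n,
        n_post=post_n,
        or_result=odds_ratio(table, correction=correction),
    )
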