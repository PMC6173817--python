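"""Seed-controlled generators for every input the other modules consume.

Four generators emulate the study designs around the early-warning device:

* :func:`generate_population` — a mixed obstetric population (normotensive,
  hypertensive, shocked) of vital-sign readings drawn from truncated,
  SBP-DBP-correlated normal class distributions.
* :func:`generate_paired_study` — device-vs-reference measurement
  sequences (seven alternating same-arm measurements per subject) with an
  arm-circumference-dependent device bias, emulating a wide-range-cuff
  comparison in which the device overestimates pressure on large arms.
* :func:`generate_outcome_cohort` — readings whose alert colours hit
  designed tier proportions (rejection sampling against an arbitrary
  threshold config) with Bernoulli adverse outcomes at designed per-tier
  risks.
* :func:`generate_prepost` — two Bernoulli indicator samples at designed
  proportions for before/after surveillance comparisons.

A single integer seed drives a hierarchical ``numpy`` seed tree
(:class:`numpy.random.SeedSequence`), so identical specs give
byte-identical output and sub-generators are independently reproducible.
All class-distribution defaults are illustrative: the shocked class in
particular emulates haemodynamic compromise from haemorrhage or sepsis
but is not fitted to any clinical dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import GROUPS, OutcomeCohort
from .ews import Context, DBP_WINDOW, PULSE_WINDOW, SBP_WINDOW, ThresholdConfig, VitalReading
from .validation import Cuff, Measurement, MeasurementSequence, Source

__all__ = [
    "ClassParams",
    "DEFAULT_CLASSES",
    "PopulationSpec",
    "PopulationSample",
    "PairedStudySpec",
    "OutcomeCohortSpec",
    "CohortSample",
    "PrePostData",
    "InfeasibleSpecError",
    "generate_population",
    "generate_paired_study",
    "generate_outcome_cohort",
    "generate_prepost",
]

CLASS_NAMES = ("normotensive", "hypertensive", "shocked")


class InfeasibleSpecError(RuntimeError):
    """Raised when rejection sampling cannot satisfy a spec's targets."""


@dataclass(frozen=True)
class ClassParams:
    """Truncated-normal vital-sign distribution for one population class."""

    sbp_mean: float
    sbp_sd: float
    dbp_mean: float
    dbp_sd: float
    pulse_mean: float
    pulse_sd: float

    def __post_init__(self) -> None:
        if min(self.sbp_sd, self.dbp_sd, self.pulse_sd) <= 0:
            raise ValueError("class SDs must be positive")
        if self.dbp_mean >= self.sbp_mean:
            raise ValueError("class dbp mean must be below sbp mean")


# Illustrative class distributions (mm Hg, beats/min).  The shocked class
# emulates haemodynamic compromise from haemorrhage/sepsis: low pressure,
# high pulse, hence an elevated Shock Index.
DEFAULT_CLASSES: dict[str, ClassParams] = {
    "normotensive": ClassParams(115.0, 10.0, 72.0, 8.0, 82.0, 10.0),
    "hypertensive": ClassParams(152.0, 12.0, 98.0, 8.0, 86.0, 12.0),
    "shocked": ClassParams(92.0, 12.0, 56.0, 10.0, 124.0, 18.0),
}


@dataclass(frozen=True)
class PopulationSpec:
    """Mixture specification for a synthetic obstetric population."""

    n: int = 1000
    weights: tuple[float, float, float] = (0.70, 0.20, 0.10)  # normo, hyper, shocked
    classes: Mapping[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    sbp_dbp_corr: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        w = np.asarray(self.weights, dtype=float)
        if w.size != 3 or np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be 3 non-negative values summing to 1")
        if not -1.0 < self.sbp_dbp_corr < 1.0:
            raise ValueError("sbp_dbp_corr must lie in (-1, 1)")
        missing = [c for c in CLASS_NAMES if c not in self.classes]
        if missing:
            raise ValueError(f"missing class parameters: {missing}")


@dataclass(frozen=True)
class PopulationSample:
    """Generated readings with their hidden class labels."""

    readings: tuple[VitalReading, ...]
    labels: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject_id": [r.subject_id for r in self.readings],
                "timestamp": ["" for _ in self.readings],
                "sbp": [r.sbp for r in self.readings],
                "dbp": [r.dbp for r in self.readings],
                "pulse": [r.pulse for r in self.readings],
                "context": [str(r.context) for r in self.readings],
            }
        )


def _draw_vitals(
    rng: np.random.Generator,
    params: ClassParams,
    corr: float,
    size: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Correlated SBP/DBP plus pulse, truncated by rejection to the
    plausibility windows with SBP > DBP."""
    sbp = np.empty(size)
    dbp = np.empty(size)
    pulse = np.empty(size)
    pending = np.arange(size)
    while pending.size:
        k = pending.size
        z1 = rng.standard_normal(k)
        z2 = corr * z1 + np.sqrt(1.0 - corr**2) * rng.standard_normal(k)
        s = params.sbp_mean + params.sbp_sd * z1
        d = params.dbp_mean + params.dbp_sd * z2
        p = params.pulse_mean + params.pulse_sd * rng.standard_normal(k)
        ok = (
            (s >= SBP_WINDOW[0]) & (s <= SBP_WINDOW[1])
            & (d >= DBP_WINDOW[0]) & (d <= DBP_WINDOW[1])
            & (p >= PULSE_WINDOW[0]) & (p <= PULSE_WINDOW[1])
            & (s - d > 0.2)  # margin survives rounding to 0.1 mm Hg
        )
        idx = pending[ok]
        sbp[idx], dbp[idx], pulse[idx] = s[ok], d[ok], p[ok]
        pending = pending[~ok]
    return sbp, dbp, pulse


def generate_population(spec: PopulationSpec) -> PopulationSample:
    """Draw ``spec.n`` readings from the class mixture; reproducible given
    the seed, and every row passes the reading validators by construction."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    if spec.n == 0:
        return PopulationSample(readings=(), labels=())
    labels_idx = rng.choice(3, size=spec.n, p=np.asarray(spec.weights, dtype=float))
    sbp = np.empty(spec.n)
    dbp = np.empty(spec.n)
    pulse = np.empty(spec.n)
    for ci, cname in enumerate(CLASS_NAMES):
        mask = labels_idx == ci
        k = int(mask.sum())
        if k:
            s, d, p = _draw_vitals(rng, spec.classes[cname], spec.sbp_dbp_corr, k)
            sbp[mask], dbp[mask], pulse[mask] = s, d, p
    readings = tuple(
        VitalReading(
            subject_id=f"P{i:06d}",
            sbp=round(float(sbp[i]), 1),
            dbp=round(float(dbp[i]), 1),
            pulse=round(float(pulse[i]), 1),
            context=Context.UNKNOWN,
        )
        for i in range(spec.n)
    )
    labels = tuple(CLASS_NAMES[i] for i in labels_idx)
    return PopulationSample(readings=readings, labels=labels)


@dataclass(frozen=True)
class PairedStudySpec:
    """Design of a device-vs-reference comparison study.

    Device readings equal the subject's reference truth plus an arm-band
    bias (``bias_small_arm`` below ``large_arm_threshold`` cm,
    ``bias_large_arm`` at or above) plus Normal(0, ``error_sd``) noise.
    ``within_subject_sd`` adds independent repeat-to-repeat variation to
    the reference observations; at its default of zero the
    device-minus-reference differences are exactly
    Normal(bias, ``error_sd``^2) under either pairing scheme.  With
    ``balanced_strata`` the subjects split evenly between the small- and
    large-arm bands, mirroring the 26 + 26 wide-range-cuff design.
    """

    n_subjects: int = 52
    bias_small_arm: float = 0.0  # mm Hg added to device readings, small arms
    bias_large_arm: float = 10.0  # mm Hg, large arms
    error_sd: float = 3.0  # mm Hg device measurement noise
    within_subject_sd: float = 0.0  # mm Hg reference repeat variability
    arm_range: tuple[float, float] = (22.0, 42.0)  # cm
    large_arm_threshold: float = 33.0  # cm
    balanced_strata: bool = True
    n_measurements: int = 7
    cuff_rule: str = "wide_range"  # or "by_arm"
    ref_sbp_mean: float = 120.0
    ref_sbp_sd: float = 15.0
    ref_dbp_mean: float = 75.0
    ref_dbp_sd: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 0:
            raise ValueError("n_subjects must be non-negative")
        if self.error_sd <= 0:
            raise ValueError("error_sd must be positive")
        if self.within_subject_sd < 0:
            raise ValueError("within_subject_sd must be non-negative")
        if self.n_measurements < 3 or self.n_measurements % 2 == 0:
            raise ValueError("n_measurements must be odd and at least 3")
        if not self.arm_range[0] < self.arm_range[1]:
            raise ValueError("arm_range must be increasing")
        if self.cuff_rule not in ("wide_range", "by_arm"):
            raise ValueError(f"unknown cuff_rule {self.cuff_rule!r}")


def _assign_cuff(arm: float, rule: str, threshold: float) -> Cuff:
    if rule == "wide_range":
        return Cuff.WIDE_RANGE
    return Cuff.LARGE if arm >= threshold else Cuff.MEDIUM


def generate_paired_study(spec: PairedStudySpec) -> list[MeasurementSequence]:
    """Simulate alternating reference/device measurement sequences."""
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    n = spec.n_subjects
    lo, hi = spec.arm_range
    thr = spec.large_arm_threshold
    if spec.balanced_strata:
        half = n // 2
        arms = np.concatenate(
            [
                rng.uniform(lo, min(thr, hi), size=n - half),
                rng.uniform(min(thr, hi), hi, size=half),
            ]
        )
    else:
        arms = rng.uniform(lo, hi, size=n)

    sequences: list[MeasurementSequence] = []
    for i in range(n):
        arm = float(arms[i])
        bias = spec.bias_large_arm if arm >= thr else spec.bias_small_arm
        truth_sbp = rng.normal(spec.ref_sbp_mean, spec.ref_sbp_sd)
        # keep diastolic below systolic by a physiological margin
        truth_dbp = min(
            rng.normal(spec.ref_dbp_mean, spec.ref_dbp_sd), truth_sbp - 15.0
        )
        measurements: list[Measurement] = []
        for pos in range(spec.n_measurements):
            if pos % 2 == 0:
                s = truth_sbp + rng.normal(0.0, spec.within_subject_sd) \
                    if spec.within_subject_sd > 0 else truth_sbp
                d = truth_dbp + rng.normal(0.0, spec.within_subject_sd) \
                    if spec.within_subject_sd > 0 else truth_dbp
                measurements.append(Measurement(Source.REFERENCE, float(s), float(d)))
            else:
                s = truth_sbp + bias + rng.normal(0.0, spec.error_sd)
                d = truth_dbp + bias + rng.normal(0.0, spec.error_sd)
                measurements.append(Measurement(Source.DEVICE, float(s), float(d)))
        sequences.append(
            MeasurementSequence(
                subject_id=f"V{i:04d}",
                arm_circumference=round(arm, 1),
                measurements=tuple(measurements),
                cuff=_assign_cuff(arm, spec.cuff_rule, thr),
            )
        )
    return sequences


@dataclass(frozen=True)
class OutcomeCohortSpec:
    """Design of a cohort whose alert tiers carry designed outcome risks."""

    n: int = 3000
    tier_proportions: tuple[float, float, float] = (0.5, 0.3, 0.2)  # green, yellow, red
    tier_risks: tuple[float, float, float] = (0.02, 0.10, 0.30)
    outcome_name: str = "adverse_outcome"
    enforce_monotone: bool = True
    # mixture used for candidate draws; broad enough to hit all tiers
    candidate_weights: tuple[float, float, float] = (0.40, 0.30, 0.30)
    classes: Mapping[str, ClassParams] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    max_batches: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        props = np.asarray(self.tier_proportions, dtype=float)
        if np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise ValueError("tier_proportions must be non-negative and sum to 1")
        if any(not 0.0 <= r <= 1.0 for r in self.tier_risks):
            raise ValueError("tier_risks must lie in [0, 1]")
        if self.enforce_monotone and list(self.tier_risks) != sorted(self.tier_risks):
            raise ValueError("tier_risks must be non-decreasing green→yellow→red")


@dataclass(frozen=True)
class CohortSample:
    """Generated cohort plus the hidden truth used to build it."""

    cohort: OutcomeCohort
    true_tiers: tuple[int, ...]  # 0 green, 1 yellow, 2 red, by design
    class_labels: tuple[str, ...]


def _tier_codes(
    sbp: np.ndarray, dbp: np.ndarray, pulse: np.ndarray, cfg: ThresholdConfig
) -> np.ndarray:
    """Vectorised overall alert colour (0/1/2) for candidate screening.

    Mirrors the scalar engine's rule table; the scalar path remains the
    reference implementation and the two are cross-checked in tests.
    """
    ge = np.greater_equal if cfg.inclusive_boundaries else np.greater
    hyp = np.where(
        ge(sbp, cfg.hyp_red_sbp) | ge(dbp, cfg.hyp_red_dbp), 2,
        np.where(ge(sbp, cfg.hyp_yellow_sbp) | ge(dbp, cfg.hyp_yellow_dbp), 1, 0),
    )
    si = pulse / sbp
    shock = np.where(ge(si, cfg.si_red), 2, np.where(ge(si, cfg.si_yellow), 1, 0))
    return np.maximum(hyp, shock)


def _quota_counts(n: int, proportions: Sequence[float]) -> list[int]:
    """Largest-remainder rounding of n * proportions to integers summing n."""
    raw = [n * p for p in proportions]
    counts = [int(np.floor(x)) for x in raw]
    short = n - sum(counts)
    remainders = sorted(
        range(len(raw)), key=lambda i: raw[i] - counts[i], reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


_GROUP_FOR_CLASS = {
    "hypertensive": ("hypertension",),
    "shocked": ("haemorrhage", "sepsis"),
    "normotensive": GROUPS,
}


def generate_outcome_cohort(
    spec: OutcomeCohortSpec, cfg: ThresholdConfig
) -> CohortSample:
    """Build a cohort whose alert-colour mix matches the designed tier
    proportions exactly (rejection sampling against ``cfg``) and whose
    outcomes are Bernoulli draws at the designed per-tier risks.

    Raises :class:`InfeasibleSpecError` if a tier's quota cannot be filled
    within ``spec.max_batches`` candidate batches — e.g. proportions that
    demand a tier the candidate mixture essentially never produces.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    quotas = _quota_counts(spec.n, spec.tier_proportions)
    pools_s: list[list[float]] = [[], [], []]
    pools_d: list[list[float]] = [[], [], []]
    pools_p: list[list[float]] = [[], [], []]
    pools_label: list[list[str]] = [[], [], []]

    weights = np.asarray(spec.candidate_weights, dtype=float)
    weights = weights / weights.sum()
    batch = max(4096, 2 * spec.n)
    batches_used = 0
    while any(len(pools_s[t]) < quotas[t] for t in range(3)):
        if batches_used >= spec.max_batches:
            unfilled = [t for t in range(3) if len(pools_s[t]) < quotas[t]]
            raise InfeasibleSpecError(
                f"tier proportions infeasible under this threshold config: "
                f"tiers {unfilled} unfilled after {batches_used} batches"
            )
        batches_used += 1
        labels_idx = rng.choice(3, size=batch, p=weights)
        sbp = np.empty(batch)
        dbp = np.empty(batch)
        pulse = np.empty(batch)
        for ci, cname in enumerate(CLASS_NAMES):
            mask = labels_idx == ci
            k = int(mask.sum())
            if k:
                s, d, p = _draw_vitals(rng, spec.classes[cname], 0.5, k)
                sbp[mask], dbp[mask], pulse[mask] = s, d, p
        sbp, dbp, pulse = np.round(sbp, 1), np.round(dbp, 1), np.round(pulse, 1)
        keep = sbp > dbp  # rounding can collapse the margin
        tiers = _tier_codes(sbp, dbp, pulse, cfg)
        for j in np.flatnonzero(keep):
            t = int(tiers[j])
            if len(pools_s[t]) < quotas[t]:
                pools_s[t].append(float(sbp[j]))
                pools_d[t].append(float(dbp[j]))
                pools_p[t].append(float(pulse[j]))
                pools_label[t].append(CLASS_NAMES[labels_idx[j]])

    rows_s = np.array([v for t in range(3) for v in pools_s[t]])
    rows_d = np.array([v for t in range(3) for v in pools_d[t]])
    rows_p = np.array([v for t in range(3) for v in pools_p[t]])
    rows_label = [v for t in range(3) for v in pools_label[t]]
    rows_tier = np.array([t for t in range(3) for _ in pools_s[t]])

    order = rng.permutation(spec.n)
    risks = np.asarray(spec.tier_risks)[rows_tier[order]]
    events = rng.random(spec.n) < risks

    readings = []
    groups = []
    for i, j in enumerate(order):
        readings.append(
            VitalReading(
                subject_id=f"C{i:06d}",
                sbp=float(rows_s[j]),
                dbp=float(rows_d[j]),
                pulse=float(rows_p[j]),
            )
        )
        choices = _GROUP_FOR_CLASS[rows_label[j]]
        groups.append(choices[int(rng.integers(len(choices)))])

    cohort = OutcomeCohort(
        readings=tuple(readings),
        groups=tuple(groups),
        outcomes=pd.DataFrame({spec.outcome_name: events}),
    )
    return CohortSample(
        cohort=cohort,
        true_tiers=tuple(int(rows_tier[j]) for j in order),
        class_labels=tuple(rows_label[j] for j in order),
    )


@dataclass(frozen=True)
class PrePostData:
    """Two binary indicator samples: before and after an intervention."""

    pre: np.ndarray  # boolean
    post: np.ndarray

    @property
    def pre_events(self) -> int:
        return int(self.pre.sum())

    @property
    def post_events(self) -> int:
        return int(self.post.sum())


def generate_prepost(
    pre_p: float,
    post_p: float,
    n_pre: int = 694,
    n_post: int = 547,
    seed: int = 0,
) -> PrePostData:
    """Bernoulli indicator draws for the two phases; reproducible.

    The default phase sizes mirror a surveillance study with 694 women
    before and 547 after the intervention.
    """
    if not (0.0 <= pre_p <= 1.0 and 0.0 <= post_p <= 1.0):
        raise ValueError("proportions must lie in [0, 1]")
    if n_pre < 0 or n_post < 0:
        raise ValueError("phase sizes must be non-negative")
    ss = np.random.SeedSequence(seed).spawn(2)
    pre = np.random.default_rng(ss[0]).random(n_pre) < pre_p
    post = np.random.default_rng(ss[1]).random(n_post) < post_p
    return PrePostData(pre=pre, post=post)
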