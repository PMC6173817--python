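"""Paired-difference statistics for blood-pressure device validation.

Implements the adapted BHS / ISH / ISO analysis used to validate an
oscillometric device against a reference (mercury sphygmomanometer or
masked auscultation): pairing of alternating same-arm measurement
sequences, mean and SD of device-minus-reference differences, the ISO
accuracy criterion (|mean| <= 5 mm Hg and SD <= 8 mm Hg), and BHS A-D
grading by cumulative percentages of absolute differences within
5 / 10 / 15 mm Hg — overall and per arm-circumference stratum.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

__all__ = [
    "Source",
    "Cuff",
    "Measurement",
    "MeasurementSequence",
    "ComparisonPair",
    "DifferenceStats",
    "IsoAssessment",
    "BhsGrades",
    "ValidationReport",
    "EmptyStratumError",
    "BHS_GRADE_TABLE",
    "DEFAULT_STRATA",
    "build_comparison_pairs",
    "difference_stats",
    "iso_assess",
    "bhs_grade",
    "run_validation",
]


class Source(enum.Enum):
    REFERENCE = "reference"
    DEVICE = "device"

    def __str__(self) -> str:
        return self.value


class Cuff(enum.Enum):
    MEDIUM = "medium"
    LARGE = "large"
    EXTRA_LARGE = "extra_large"
    WIDE_RANGE = "wide_range"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class Measurement:
    source: Source
    sbp: float  # mm Hg
    dbp: float  # mm Hg


@dataclass(frozen=True)
class MeasurementSequence:
    """Sequential same-arm measurements alternating reference / device.

    The validation protocol takes seven measurements per subject starting
    and ending with the reference observer, i.e. R,D,R,D,R,D,R.  Sequences
    that do not alternate, do not start and end with a reference reading,
    or are shorter than three measurements are rejected.
    """

    subject_id: str
    arm_circumference: float  # cm
    measurements: tuple[Measurement, ...]
    cuff: Cuff = Cuff.WIDE_RANGE

    def __post_init__(self) -> None:
        m = self.measurements
        if len(m) < 3:
            raise ValueError("sequence must contain at least 3 measurements")
        if len(m) % 2 == 0:
            raise ValueError("sequence must end with a reference measurement")
        for i, meas in enumerate(m):
            expected = Source.REFERENCE if i % 2 == 0 else Source.DEVICE
            if meas.source is not expected:
                raise ValueError(
                    f"measurement {i} is {meas.source}, expected {expected}: "
                    "sequence must alternate beginning with reference"
                )


@dataclass(frozen=True)
class ComparisonPair:
    """One device observation paired with its reference value.

    Differences are device minus reference; subject covariates are carried
    through so the pairs can be stratified downstream.
    """

    device_sbp: float
    device_dbp: float
    reference_sbp: float
    reference_dbp: float
    subject_id: str = ""
    arm_circumference: float = float("nan")
    cuff: Optional[Cuff] = None

    @property
    def diff_sbp(self) -> float:
        return self.device_sbp - self.reference_sbp

    @property
    def diff_dbp(self) -> float:
        return self.device_dbp - self.reference_dbp


def build_comparison_pairs(
    seq: MeasurementSequence,
    scheme: str = "flanking_mean",
) -> list[ComparisonPair]:
    """Turn an alternating sequence into device-vs-reference pairs.

    ``flanking_mean`` (the BHS convention, default) pairs each device
    measurement with the arithmetic mean of the two surrounding reference
    measurements; a 7-measurement sequence yields 3 pairs.  ``same_index``
    pairs each device measurement with the reference immediately before
    it, for sensitivity analysis.
    """
    if scheme not in ("flanking_mean", "same_index"):
        raise ValueError(f"unknown pairing scheme {scheme!r}")
    m = seq.measurements
    pairs: list[ComparisonPair] = []
    for i in range(1, len(m), 2):  # device positions
        dev = m[i]
        if scheme == "flanking_mean":
            ref_sbp = (m[i - 1].sbp + m[i + 1].sbp) / 2.0
            ref_dbp = (m[i - 1].dbp + m[i + 1].dbp) / 2.0
        else:
            ref_sbp = m[i - 1].sbp
            ref_dbp = m[i - 1].dbp
        pairs.append(
            ComparisonPair(
                device_sbp=dev.sbp,
                device_dbp=dev.dbp,
                reference_sbp=ref_sbp,
                reference_dbp=ref_dbp,
                subject_id=seq.subject_id,
                arm_circumference=seq.arm_circumference,
                cuff=seq.cuff,
            )
        )
    return pairs


class EmptyStratumError(ValueError):
    """Raised when a requested stratum contains no comparison pairs."""


@dataclass(frozen=True)
class DifferenceStats:
    """Mean and sample SD (n-1) of device-minus-reference differences."""

    n_pairs: int
    mean_sbp: float
    sd_sbp: float
    mean_dbp: float
    sd_dbp: float


def _in_stratum(pair: ComparisonPair, stratum: tuple[float, float]) -> bool:
    lo, hi = stratum
    return lo <= pair.arm_circumference <= hi


def difference_stats(
    pairs: Sequence[ComparisonPair],
    stratum: Optional[tuple[float, float]] = None,
) -> DifferenceStats:
    """Arithmetic mean and sample SD of the paired differences.

    ``stratum`` restricts to pairs whose arm circumference lies in the
    closed interval ``(lo, hi)`` cm.  An empty selection raises
    :class:`EmptyStratumError` rather than returning zeros; fewer than two
    pairs leaves the SD undefined and is rejected.
    """
    if stratum is not None:
        pairs = [p for p in pairs if _in_stratum(p, stratum)]
    if len(pairs) == 0:
        raise EmptyStratumError("no comparison pairs in the requested stratum")
    if len(pairs) < 2:
        raise ValueError("at least 2 pairs are required for a sample SD")
    ds = np.array([p.diff_sbp for p in pairs], dtype=float)
    dd = np.array([p.diff_dbp for p in pairs], dtype=float)
    return DifferenceStats(
        n_pairs=len(pairs),
        mean_sbp=float(ds.mean()),
        sd_sbp=float(ds.std(ddof=1)),
        mean_dbp=float(dd.mean()),
        sd_dbp=float(dd.std(ddof=1)),
    )


@dataclass(frozen=True)
class IsoAssessment:
    """ISO accuracy verdict: |mean| <= mean_bound and SD <= sd_bound."""

    sbp_pass: bool
    dbp_pass: bool
    overall_pass: bool
    mean_bound: float
    sd_bound: float


def iso_assess(
    stats: DifferenceStats,
    mean_bound: float = 5.0,
    sd_bound: float = 8.0,
) -> IsoAssessment:
    """Apply the ISO criterion (boundary inclusive, sign-symmetric on the
    mean) to each pressure component and overall."""
    sbp_ok = abs(stats.mean_sbp) <= mean_bound and stats.sd_sbp <= sd_bound
    dbp_ok = abs(stats.mean_dbp) <= mean_bound and stats.sd_dbp <= sd_bound
    return IsoAssessment(
        sbp_pass=sbp_ok,
        dbp_pass=dbp_ok,
        overall_pass=sbp_ok and dbp_ok,
        mean_bound=mean_bound,
        sd_bound=sd_bound,
    )


# BHS grading: required cumulative % of |differences| within 5/10/15 mm Hg.
# Grade D is the fall-through when no row is satisfied.
BHS_GRADE_TABLE: dict[str, tuple[float, float, float]] = {
    "A": (60.0, 85.0, 95.0),
    "B": (50.0, 75.0, 90.0),
    "C": (40.0, 65.0, 85.0),
}


@dataclass(frozen=True)
class BhsGrades:
    grade_sbp: str
    grade_dbp: str
    # cumulative % of |diff| within 5, 10, 15 mm Hg
    pct_sbp: tuple[float, float, float]
    pct_dbp: tuple[float, float, float]


def _cumulative_pct(abs_diffs: np.ndarray) -> tuple[float, float, float]:
    n = abs_diffs.size
    return tuple(float(100.0 * np.count_nonzero(abs_diffs <= b) / n)
                 for b in (5.0, 10.0, 15.0))  # type: ignore[return-value]


def _grade_from_pct(
    pct: tuple[float, float, float],
    table: Mapping[str, tuple[float, float, float]],
) -> str:
    for grade in sorted(table):  # A before B before C
        req = table[grade]
        if all(p >= r for p, r in zip(pct, req)):
            return grade
    return "D"


def bhs_grade(
    pairs: Sequence[ComparisonPair],
    grade_table: Optional[Mapping[str, tuple[float, float, float]]] = None,
) -> BhsGrades:
    """BHS grade per pressure component.

    The grade is the best (alphabetically first) row of ``grade_table``
    whose three cumulative-percentage requirements are all met; D when no
    row is.  The default table is the standard BHS protocol.
    """
    if len(pairs) == 0:
        raise ValueError("at least one comparison pair is required")
    table = BHS_GRADE_TABLE if grade_table is None else dict(grade_table)
    for grade, req in table.items():
        if len(req) != 3 or any(not (0 <= r <= 100) for r in req):
            raise ValueError(f"malformed grade table row {grade!r}: {req!r}")
        if list(req) != sorted(req):
            raise ValueError(f"grade row {grade!r} must be non-decreasing")
    abs_sbp = np.abs([p.diff_sbp for p in pairs])
    abs_dbp = np.abs([p.diff_dbp for p in pairs])
    pct_sbp = _cumulative_pct(abs_sbp)
    pct_dbp = _cumulative_pct(abs_dbp)
    return BhsGrades(
        grade_sbp=_grade_from_pct(pct_sbp, table),
        grade_dbp=_grade_from_pct(pct_dbp, table),
        pct_sbp=pct_sbp,
        pct_dbp=pct_dbp,
    )


DEFAULT_STRATA: tuple[tuple[float, float], ...] = ((22.0, 32.0), (33.0, 42.0))


@dataclass(frozen=True)
class StratumReport:
    stratum: Optional[tuple[float, float]]  # None = overall
    stats: DifferenceStats
    iso: IsoAssessment
    bhs: BhsGrades


@dataclass(frozen=True)
class ValidationReport:
    """Overall and per-arm-circumference-stratum validation results."""

    n_sequences: int
    scheme: str
    overall: StratumReport
    strata: tuple[StratumReport, ...] = ()
    empty_strata: tuple[tuple[float, float], ...] = ()

    def to_dict(self) -> dict:
        def _one(r: StratumReport) -> dict:
            return {
                "stratum": list(r.stratum) if r.stratum else None,
                "n_pairs": r.stats.n_pairs,
                "mean_diff_sbp": r.stats.mean_sbp,
                "sd_diff_sbp": r.stats.sd_sbp,
                "mean_diff_dbp": r.stats.mean_dbp,
                "sd_diff_dbp": r.stats.sd_dbp,
                "iso_pass": r.iso.overall_pass,
                "iso_pass_sbp": r.iso.sbp_pass,
                "iso_pass_dbp": r.iso.dbp_pass,
                "bhs_grade_sbp": r.bhs.grade_sbp,
                "bhs_grade_dbp": r.bhs.grade_dbp,
                "pct_within_5_10_15_sbp": list(r.bhs.pct_sbp),
                "pct_within_5_10_15_dbp": list(r.bhs.pct_dbp),
            }

        return {
            "n_sequences": self.n_sequences,
            "scheme": self.scheme,
            "overall": _one(self.overall),
            "strata": [_one(r) for r in self.strata],
            "empty_strata": [list(s) for s in self.empty_strata],
        }


def run_validation(
    sequences: Iterable[MeasurementSequence],
    scheme: str = "flanking_mean",
    mean_bound: float = 5.0,
    sd_bound: float = 8.0,
    grade_table: Optional[Mapping[str, tuple[float, float, float]]] = None,
    strata: Sequence[tuple[float, float]] = DEFAULT_STRATA,
) -> ValidationReport:
    """Full pipeline: pair, summarise, assess ISO, grade BHS — overall and
    within each arm-circumference stratum.  Deterministic given inputs."""
    sequences = list(sequences)
    pairs: list[ComparisonPair] = []
    for seq in sequences:
        pairs.extend(build_comparison_pairs(seq, scheme))

    def _report(subset: Sequence[ComparisonPair],
                stratum: Optional[tuple[float, float]]) -> StratumReport:
        stats = difference_stats(subset)
        return StratumReport(
            stratum=stratum,
            stats=stats,
            iso=iso_assess(stats, mean_bound, sd_bound),
            bhs=bhs_grade(subset, grade_table),
        )

    overall = _report(pairs, None)
    sub: list[StratumReport] = []
    empty: list[tuple[float, float]] = []
    for stratum in strata:
        selected = [p for p in pairs if _in_stratum(p, stratum)]
        if len(selected) < 2:
            empty.append(stratum)
        else:
            sub.append(_report(selected, stratum))
    return ValidationReport(
        n_sequences=len(sequences),
        scheme=scheme,
        overall=overall,
        strata=tuple(sub),
        empty_strata=tuple(empty),
    )
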