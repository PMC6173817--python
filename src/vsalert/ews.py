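"""Traffic-light early-warning classification of maternal vital signs.

The engine combines two alerting pathways over a single blood-pressure /
pulse observation:

* **Hypertension tiers** — systolic/diastolic pressure against established
  obstetric thresholds (yellow and red cut-offs for each component).
* **Shock tiers** — the Shock Index (pulse divided by systolic pressure),
  an early marker of haemodynamic compromise from haemorrhage or sepsis,
  against its own yellow/red cut-offs.

The overall alert colour is the more severe of the two tiers, but whenever
the shock pathway alerts the displayed condition is *shock* (flashing down
arrow), reflecting that shock usually demands more urgent intervention than
hypertension.  All numeric thresholds live in :class:`ThresholdConfig`, not
in code.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Any, Mapping, Optional, Union

__all__ = [
    "Tier",
    "Condition",
    "Context",
    "VitalReading",
    "Rejection",
    "ShockIndexValue",
    "ThresholdConfig",
    "AlertResult",
    "default_display_map",
    "shock_index",
    "classify_hypertension",
    "classify_shock",
    "alert",
    "validate_reading",
    "SBP_WINDOW",
    "DBP_WINDOW",
    "PULSE_WINDOW",
]

# Plausibility windows (mm Hg, beats/min); readings outside are rejected.
SBP_WINDOW = (40.0, 300.0)
DBP_WINDOW = (20.0, 200.0)
PULSE_WINDOW = (20.0, 250.0)


class Tier(enum.IntEnum):
    """Alert tier ordered by severity (comparable with ``<``/``max``)."""

    GREEN = 0
    YELLOW = 1
    RED = 2

    def __str__(self) -> str:  # stable lower-case token for files/JSON
        return self.name.lower()


class Condition(enum.Enum):
    """Which pathway is reported as driving the alert."""

    NONE = "none"
    HYPERTENSION = "hypertension"
    SHOCK = "shock"

    def __str__(self) -> str:
        return self.value


class Context(enum.Enum):
    """Care context of the observation."""

    ANTENATAL = "antenatal"
    INTRAPARTUM = "intrapartum"
    POSTNATAL = "postnatal"
    UNKNOWN = "unknown"

    def __str__(self) -> str:
        return self.value


@dataclass(frozen=True)
class VitalReading:
    """One subject's SBP/DBP/pulse observation, the unit of classification.

    Construct via :func:`validate_reading` when the source is untrusted;
    direct construction checks the same invariants.
    """

    subject_id: str
    sbp: float  # systolic blood pressure, mm Hg
    dbp: float  # diastolic blood pressure, mm Hg
    pulse: float  # heart rate, beats/min
    timestamp: Optional[str] = None  # ISO 8601 instant, opaque here
    context: Context = Context.UNKNOWN

    def __post_init__(self) -> None:
        reasons = _invariant_violations(self.sbp, self.dbp, self.pulse)
        if reasons:
            raise ValueError(f"invalid reading: {', '.join(reasons)}")


@dataclass(frozen=True)
class Rejection:
    """Structured refusal of a raw record, naming every violated invariant."""

    reasons: tuple[str, ...]
    record: Mapping[str, Any]

    def __bool__(self) -> bool:
        return False


@dataclass(frozen=True)
class ShockIndexValue:
    """Shock Index: pulse / systolic pressure, dimensionless.

    ``value`` is the exact ratio; :meth:`rounded` is for display only —
    tier classification always uses the unrounded ratio to avoid boundary
    artefacts.
    """

    value: float
    pulse: float
    sbp: float

    def rounded(self, ndigits: int = 2) -> float:
        """Round half to even, the convention for reported SI values."""
        return round(self.value, ndigits)

    def __float__(self) -> float:
        return self.value


def default_display_map() -> dict[str, str]:
    """Display symbols keyed by ``"<colour>:<condition>"``.

    Shock alerts flash a down arrow (higher urgency); hypertension-only
    alerts show a constant up arrow; green shows nothing.  Device utility
    states (low battery, generic error) are display entries only — they
    never participate in classification logic.
    """
    return {
        "green:none": "none",
        "yellow:hypertension": "constant up arrow",
        "red:hypertension": "constant up arrow",
        "yellow:shock": "flashing down arrow",
        "red:shock": "flashing down arrow",
        "low_battery": "battery symbol",
        "error": "error symbol",
    }


@dataclass(frozen=True)
class ThresholdConfig:
    """The traffic-light rule table.

    Hypertension tiers trigger on either pressure component; shock tiers on
    the Shock Index.  With ``inclusive_boundaries`` (the default), a value
    exactly at a threshold triggers that tier (the conventional reading of
    "140/90 defines hypertension"); with ``False`` the comparisons are
    strict.
    """

    hyp_yellow_sbp: float = 140.0  # mm Hg
    hyp_yellow_dbp: float = 90.0
    hyp_red_sbp: float = 160.0
    hyp_red_dbp: float = 110.0
    si_yellow: float = 0.9  # dimensionless
    si_red: float = 1.7
    inclusive_boundaries: bool = True
    display_map: Mapping[str, str] = field(default_factory=default_display_map)

    def __post_init__(self) -> None:
        problems = []
        for name in ("hyp_yellow_sbp", "hyp_yellow_dbp", "hyp_red_sbp",
                     "hyp_red_dbp", "si_yellow", "si_red"):
            if getattr(self, name) <= 0:
                problems.append(f"{name} must be positive")
        if self.hyp_yellow_sbp >= self.hyp_red_sbp:
            problems.append("hyp_yellow_sbp must be below hyp_red_sbp")
        if self.hyp_yellow_dbp >= self.hyp_red_dbp:
            problems.append("hyp_yellow_dbp must be below hyp_red_dbp")
        if self.si_yellow >= self.si_red:
            problems.append("si_yellow must be below si_red")
        if problems:
            raise ValueError("invalid threshold config: " + "; ".join(problems))

    def with_(self, **changes: Any) -> "ThresholdConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class AlertResult:
    """Outcome of classifying one reading.

    ``colour`` is the more severe of the two pathway tiers.  ``condition``
    is ``shock`` whenever the shock tier is at least yellow — even when the
    hypertension tier is the more severe one — so the shock display is
    always produced when shock alerts.  Both pathway tiers are retained.
    """

    colour: Tier
    condition: Condition
    hypertension_tier: Tier
    shock_tier: Tier
    display: str
    shock_index: ShockIndexValue


def shock_index(pulse: float, sbp: float) -> ShockIndexValue:
    """Shock Index = pulse / systolic blood pressure.

    Parameters are in beats/min and mm Hg; the ratio is reported unitless.
    Values outside the plausibility windows are rejected.
    """
    if not (PULSE_WINDOW[0] <= pulse <= PULSE_WINDOW[1]):
        raise ValueError(f"pulse {pulse!r} outside plausibility window {PULSE_WINDOW}")
    if not (SBP_WINDOW[0] <= sbp <= SBP_WINDOW[1]):
        raise ValueError(f"sbp {sbp!r} outside plausibility window {SBP_WINDOW}")
    return ShockIndexValue(value=pulse / sbp, pulse=pulse, sbp=sbp)


def _tier(value: float, yellow: float, red: float, inclusive: bool) -> Tier:
    if inclusive:
        if value >= red:
            return Tier.RED
        if value >= yellow:
            return Tier.YELLOW
    else:
        if value > red:
            return Tier.RED
        if value > yellow:
            return Tier.YELLOW
    return Tier.GREEN


def classify_hypertension(reading: VitalReading, cfg: ThresholdConfig) -> Tier:
    """Hypertension tier from SBP/DBP only; pulse never enters.

    A component at or above (strictly above, when boundaries are strict)
    its red cut-off gives red; otherwise at/above a yellow cut-off gives
    yellow; otherwise green.
    """
    sbp_tier = _tier(reading.sbp, cfg.hyp_yellow_sbp, cfg.hyp_red_sbp,
                     cfg.inclusive_boundaries)
    dbp_tier = _tier(reading.dbp, cfg.hyp_yellow_dbp, cfg.hyp_red_dbp,
                     cfg.inclusive_boundaries)
    return max(sbp_tier, dbp_tier)


def classify_shock(reading: VitalReading, cfg: ThresholdConfig) -> Tier:
    """Shock tier from the (unrounded) Shock Index."""
    si = shock_index(reading.pulse, reading.sbp)
    return _tier(si.value, cfg.si_yellow, cfg.si_red, cfg.inclusive_boundaries)


def alert(reading: VitalReading, cfg: ThresholdConfig) -> AlertResult:
    """Classify a reading through both pathways and resolve the display.

    Colour dominance: the alert colour is the maximum severity of the
    hypertension and shock tiers.  Shock priority: if the shock tier is at
    least yellow the reported condition (and display) is shock, regardless
    of which pathway supplied the colour.
    """
    h = classify_hypertension(reading, cfg)
    s = classify_shock(reading, cfg)
    colour = max(h, s)
    if s >= Tier.YELLOW:
        condition = Condition.SHOCK
    elif h >= Tier.YELLOW:
        condition = Condition.HYPERTENSION
    else:
        condition = Condition.NONE
    key = f"{colour}:{condition}"
    display = cfg.display_map.get(key, "none")
    return AlertResult(
        colour=colour,
        condition=condition,
        hypertension_tier=h,
        shock_tier=s,
        display=display,
        shock_index=shock_index(reading.pulse, reading.sbp),
    )


_REQUIRED_FIELDS = ("subject_id", "sbp", "dbp", "pulse")


def _invariant_violations(sbp: float, dbp: float, pulse: float) -> list[str]:
    reasons = []
    if not (SBP_WINDOW[0] <= sbp <= SBP_WINDOW[1]):
        reasons.append("sbp_window")
    if not (DBP_WINDOW[0] <= dbp <= DBP_WINDOW[1]):
        reasons.append("dbp_window")
    if not (PULSE_WINDOW[0] <= pulse <= PULSE_WINDOW[1]):
        reasons.append("pulse_window")
    if sbp <= dbp:
        reasons.append("sbp_le_dbp")
    return reasons


def validate_reading(raw: Mapping[str, Any]) -> Union[VitalReading, Rejection]:
    """Check a raw record and return a :class:`VitalReading` or a
    :class:`Rejection` naming every violated invariant.

    Reason codes: ``missing:<field>``, ``not_numeric:<field>``,
    ``sbp_window``, ``dbp_window``, ``pulse_window``, ``sbp_le_dbp``,
    ``bad_context``.
    """
    reasons: list[str] = []
    for name in _REQUIRED_FIELDS:
        value = raw.get(name)
        if value is None or value == "":
            reasons.append(f"missing:{name}")
    if reasons:
        return Rejection(tuple(reasons), dict(raw))

    numeric: dict[str, float] = {}
    for name in ("sbp", "dbp", "pulse"):
        try:
            numeric[name] = float(raw[name])
        except (TypeError, ValueError):
            reasons.append(f"not_numeric:{name}")
    if reasons:
        return Rejection(tuple(reasons), dict(raw))

    reasons.extend(_invariant_violations(numeric["sbp"], numeric["dbp"],
                                         numeric["pulse"]))

    context = raw.get("context") or Context.UNKNOWN
    if not isinstance(context, Context):
        try:
            context = Context(str(context).strip().lower())
        except ValueError:
            reasons.append("bad_context")

    if reasons:
        return Rejection(tuple(reasons), dict(raw))

    timestamp = raw.get("timestamp") or None
    return VitalReading(
        subject_id=str(raw["subject_id"]),
        sbp=numeric["sbp"],
        dbp=numeric["dbp"],
        pulse=numeric["pulse"],
        timestamp=str(timestamp) if timestamp is not None else None,
        context=context,  # type: ignore[arg-type]
    )
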