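"""File readers/writers and threshold-configuration loading.

All interchange formats are delimited text with explicit headers: the
domain has no standard binary format and field audits favour
human-readable files.  Rejected rows never abort a run silently — they are
returned with their line numbers and counted in the run manifest.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Any, Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from . import __version__
from .cohort import GROUPS, OutcomeCohort
from .ews import (
    AlertResult,
    Rejection,
    ThresholdConfig,
    VitalReading,
    default_display_map,
    validate_reading,
)
from .validation import Cuff, Measurement, MeasurementSequence, Source

__all__ = [
    "READINGS_COLUMNS",
    "PAIRED_COLUMNS",
    "RejectedRow",
    "RunManifest",
    "read_readings",
    "write_readings",
    "write_alerts",
    "write_rejects",
    "read_paired_study",
    "write_paired_study",
    "read_cohort",
    "write_cohort",
    "load_threshold_config",
    "dump_threshold_config",
    "write_manifest",
]

logger = logging.getLogger("vsalert")

READINGS_COLUMNS = ["subject_id", "timestamp", "sbp", "dbp", "pulse", "context"]
PAIRED_COLUMNS = [
    "subject_id", "position", "source", "sbp", "dbp", "arm_circumference", "cuff",
]


@dataclass(frozen=True)
class RejectedRow:
    line_number: int  # 1-based, header is line 1
    reasons: tuple[str, ...]
    raw: dict


def _check_header(found: Sequence[str], required: Sequence[str], path: Path) -> None:
    missing = [c for c in required if c not in found]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_readings(path: Union[str, Path]) -> tuple[list[VitalReading], list[RejectedRow]]:
    """Read a readings CSV, validating each row; order is preserved.

    Missing columns are a hard error; invalid rows are returned as
    :class:`RejectedRow` with their line numbers, not raised.
    """
    path = Path(path)
    accepted: list[VitalReading] = []
    rejected: list[RejectedRow] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        _check_header(reader.fieldnames, READINGS_COLUMNS, path)
        for line_no, row in enumerate(reader, start=2):
            result = validate_reading(row)
            if isinstance(result, Rejection):
                rejected.append(RejectedRow(line_no, result.reasons, dict(row)))
            else:
                accepted.append(result)
    return accepted, rejected


def _fmt(x: float) -> str:
    """Deterministic, round-trip-exact numeric formatting: integers lose
    the trailing .0, everything else uses the shortest repr."""
    x = float(x)
    return str(int(x)) if x.is_integer() else repr(x)


def write_readings(path: Union[str, Path], readings: Iterable[VitalReading]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(READINGS_COLUMNS)
        for r in readings:
            writer.writerow(
                [r.subject_id, r.timestamp or "", _fmt(r.sbp), _fmt(r.dbp),
                 _fmt(r.pulse), str(r.context)]
            )


ALERTS_COLUMNS = [
    "subject_id", "timestamp", "sbp", "dbp", "pulse", "shock_index",
    "colour", "condition", "hypertension_tier", "shock_tier", "display",
]


def write_alerts(
    path: Union[str, Path],
    results: Iterable[tuple[VitalReading, AlertResult]],
) -> None:
    """One row per accepted reading: the reading, its rounded Shock Index
    and the full alert result."""
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ALERTS_COLUMNS)
        for reading, res in results:
            writer.writerow(
                [
                    reading.subject_id,
                    reading.timestamp or "",
                    _fmt(reading.sbp),
                    _fmt(reading.dbp),
                    _fmt(reading.pulse),
                    f"{res.shock_index.rounded():.2f}",
                    str(res.colour),
                    str(res.condition),
                    str(res.hypertension_tier),
                    str(res.shock_tier),
                    res.display,
                ]
            )


def write_rejects(path: Union[str, Path], rejects: Iterable[RejectedRow]) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["line_number", "reasons", "raw"])
        for r in rejects:
            writer.writerow([r.line_number, ";".join(r.reasons), json.dumps(r.raw)])


def read_paired_study(path: Union[str, Path]) -> list[MeasurementSequence]:
    """Read one measurement per row and assemble per-subject sequences
    ordered by position.  Sequence invariants (alternating sources,
    reference first and last) are enforced on assembly."""
    path = Path(path)
    frame = pd.read_csv(path, dtype={"subject_id": str},
                        float_precision="round_trip")
    _check_header(list(frame.columns), PAIRED_COLUMNS, path)
    sequences = []
    for subject_id, sub in frame.groupby("subject_id", sort=True):
        sub = sub.sort_values("position")
        measurements = tuple(
            Measurement(Source(row.source), float(row.sbp), float(row.dbp))
            for row in sub.itertuples()
        )
        arm = float(sub["arm_circumference"].iloc[0])
        cuff = Cuff(str(sub["cuff"].iloc[0]))
        sequences.append(
            MeasurementSequence(
                subject_id=str(subject_id),
                arm_circumference=arm,
                measurements=measurements,
                cuff=cuff,
            )
        )
    return sequences


def write_paired_study(
    path: Union[str, Path], sequences: Iterable[MeasurementSequence]
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(PAIRED_COLUMNS)
        for seq in sequences:
            for pos, m in enumerate(seq.measurements):
                writer.writerow(
                    [seq.subject_id, pos, str(m.source), _fmt(m.sbp), _fmt(m.dbp),
                     _fmt(seq.arm_circumference), str(seq.cuff)]
                )


_TRUE = {"true", "1", "yes", "t"}
_FALSE = {"false", "0", "no", "f"}


def _parse_bool(value: Any) -> bool:
    token = str(value).strip().lower()
    if token in _TRUE:
        return True
    if token in _FALSE:
        return False
    raise ValueError(f"not a boolean: {value!r}")


def read_cohort(
    path: Union[str, Path],
    outcome_columns: Optional[Sequence[str]] = None,
) -> tuple[OutcomeCohort, list[RejectedRow]]:
    """Read a cohort CSV: readings columns plus ``group`` and boolean
    outcome columns.  When ``outcome_columns`` is omitted, every column
    beyond the readings schema and ``group`` is treated as an outcome."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file, expected a header row")
        _check_header(reader.fieldnames, READINGS_COLUMNS + ["group"], path)
        if outcome_columns is None:
            outcome_columns = [
                c for c in reader.fieldnames
                if c not in READINGS_COLUMNS and c != "group"
            ]
        if not outcome_columns:
            raise ValueError(f"{path}: no outcome columns found")
        _check_header(reader.fieldnames, outcome_columns, path)

        readings: list[VitalReading] = []
        groups: list[str] = []
        outcomes: dict[str, list[bool]] = {c: [] for c in outcome_columns}
        rejected: list[RejectedRow] = []
        for line_no, row in enumerate(reader, start=2):
            reasons: list[str] = []
            result = validate_reading(row)
            if isinstance(result, Rejection):
                reasons.extend(result.reasons)
            if row.get("group") not in GROUPS:
                reasons.append("bad_group")
            flags = {}
            for col in outcome_columns:
                try:
                    flags[col] = _parse_bool(row[col])
                except ValueError:
                    reasons.append(f"bad_outcome:{col}")
            if reasons:
                rejected.append(RejectedRow(line_no, tuple(reasons), dict(row)))
                continue
            readings.append(result)  # type: ignore[arg-type]
            groups.append(row["group"])
            for col in outcome_columns:
                outcomes[col].append(flags[col])
    cohort = OutcomeCohort(
        readings=tuple(readings),
        groups=tuple(groups),
        outcomes=pd.DataFrame(outcomes, dtype=bool),
    )
    return cohort, rejected


def write_cohort(path: Union[str, Path], cohort: OutcomeCohort) -> None:
    frame = cohort.to_frame()
    for col in cohort.outcome_names:
        frame[col] = frame[col].map(lambda v: "true" if v else "false")
    for col in ("sbp", "dbp", "pulse"):
        frame[col] = frame[col].map(_fmt)
    frame.to_csv(path, index=False)


_CONFIG_KEYS = [
    "hyp_yellow_sbp", "hyp_yellow_dbp", "hyp_red_sbp", "hyp_red_dbp",
    "si_yellow", "si_red",
]


def load_threshold_config(path: Union[str, Path]) -> ThresholdConfig:
    """Load a YAML threshold configuration.

    All six numeric thresholds are required (missing keys are reported
    together); ``inclusive_boundaries`` and ``display_map`` fall back to
    defaults, with a log message when the display map is defaulted.
    Ordering violations (yellow at or above red) are rejected by
    :class:`ThresholdConfig` itself.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a mapping of threshold keys")
    missing = [k for k in _CONFIG_KEYS if k not in data]
    if missing:
        raise ValueError(f"{path}: missing required keys {missing}")
    unknown = [
        k for k in data
        if k not in _CONFIG_KEYS + ["inclusive_boundaries", "display_map"]
    ]
    if unknown:
        raise ValueError(f"{path}: unknown keys {unknown}")
    kwargs: dict[str, Any] = {k: float(data[k]) for k in _CONFIG_KEYS}
    if "inclusive_boundaries" in data:
        kwargs["inclusive_boundaries"] = _parse_bool(data["inclusive_boundaries"])
    if "display_map" in data:
        dm = data["display_map"]
        if not isinstance(dm, dict):
            raise ValueError(f"{path}: display_map must be a mapping")
        kwargs["display_map"] = {str(k): str(v) for k, v in dm.items()}
    else:
        logger.info("%s: no display_map given, applying defaults", path)
    return ThresholdConfig(**kwargs)


def dump_threshold_config(path: Union[str, Path], cfg: ThresholdConfig) -> None:
    data = {k: getattr(cfg, k) for k in _CONFIG_KEYS}
    data["inclusive_boundaries"] = cfg.inclusive_boundaries
    data["display_map"] = dict(cfg.display_map)
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunManifest:
    """Provenance record emitted once per CLI run."""

    command: str
    inputs: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    config_digest: Optional[str] = None
    seed: Optional[int] = None
    version: str = __version__
    rows_accepted: Optional[int] = None
    rows_rejected: Optional[int] = None
    timestamp: str = ""

    def finalise(self) -> "RunManifest":
        self.timestamp = datetime.now(timezone.utc).isoformat(timespec="seconds")
        return self


def file_digest(path: Union[str, Path]) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def write_manifest(path: Union[str, Path], manifest: RunManifest) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        json.dump(asdict(manifest.finalise()), fh, indent=2, sort_keys=True)
        fh.write("\n")
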