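"""Electronic-checklist I/O: CSV/JSON patient records, config files, manifests.

Checklist files carry one row per patient with column names equal to the
domain field names.  Grades travel as Roman numerals ("I".."V"), sex as
"male"/"female", tropism as "present"/"absent"/"unknown" (the summary-table
symbols "+", "-", "+/-" are accepted on input).  Row-level problems are
collected with their line numbers rather than aborting the whole file.
"""

from __future__ import annotations

import csv
import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
import yaml

from .types import (
    Arm,
    Level,
    OutcomeLabel,
    OutcomeRecord,
    PatientRecord,
    RuleConfig,
    SegmentProfile,
    Sex,
    Timepoint,
    Tropism,
    grade_to_roman,
    roman_to_grade,
)

__all__ = [
    "read_checklist",
    "write_checklist",
    "records_to_frame",
    "load_rule_config",
    "save_rule_config",
    "RunManifest",
    "write_manifest",
    "file_digest",
]

_PROFILE_FLOATS = (
    "linear_translation",
    "sagittal_angulation",
    "facet_angle",
    "adc",
    "ivd_height",
    "height_loss_fraction",
    "general_lordosis",
)

_SCORES = ("odi", "vas_back", "vas_leg")

BASE_COLUMNS = (
    "id", "age", "sex", "bmi", "level",
    "linear_translation", "sagittal_angulation", "facet_angle", "tropism",
    "pfirrmann", "fujiwara", "adc", "ivd_height", "height_loss_fraction",
    "general_lordosis", "received_arm", "outcome_label",
)

_OUTCOME_COLUMNS = tuple(
    f"{score}_{tp.value}" for tp in Timepoint for score in _SCORES
)

_TROPISM_ALIASES = {
    "present": Tropism.PRESENT, "+": Tropism.PRESENT,
    "absent": Tropism.ABSENT, "-": Tropism.ABSENT, "–": Tropism.ABSENT,
    "unknown": Tropism.UNKNOWN, "+/-": Tropism.UNKNOWN, "+/–": Tropism.UNKNOWN, "": Tropism.UNKNOWN,
}


def _record_to_row(record: PatientRecord) -> dict:
    p = record.profile
    row = {
        "id": record.id,
        "age": record.age,
        "sex": record.sex.value,
        "bmi": record.bmi,
        "level": p.level.value,
        **{name: getattr(p, name) for name in _PROFILE_FLOATS},
        "tropism": p.tropism.value,
        "pfirrmann": grade_to_roman(p.pfirrmann),
        "fujiwara": grade_to_roman(p.fujiwara),
        "received_arm": record.received_arm.value if record.received_arm else "",
        "outcome_label": record.outcome_label.value if record.outcome_label else "",
    }
    for rec in record.outcomes:
        for score in _SCORES:
            row[f"{score}_{rec.timepoint.value}"] = getattr(rec, score)
    return row


def _row_to_record(row: dict) -> PatientRecord:
    """Parse one checklist row; raises ValueError with a field-specific message."""

    def need(key: str) -> str:
        value = str(row.get(key, "") or "").strip()
        if not value:
            raise ValueError(f"missing required field {key!r}")
        return value

    tropism_raw = str(row.get("tropism", "") or "").strip().lower()
    if tropism_raw not in _TROPISM_ALIASES:
        raise ValueError(f"unrecognized tropism {row.get('tropism')!r}")
    profile = SegmentProfile(
        level=Level(need("level")),
        linear_translation=float(need("linear_translation")),
        sagittal_angulation=float(need("sagittal_angulation")),
        facet_angle=float(need("facet_angle")),
        tropism=_TROPISM_ALIASES[tropism_raw],
        pfirrmann=roman_to_grade(need("pfirrmann")),
        fujiwara=roman_to_grade(need("fujiwara")),
        adc=float(need("adc")),
        ivd_height=float(need("ivd_height")),
        height_loss_fraction=float(need("height_loss_fraction")),
        general_lordosis=float(need("general_lordosis")),
    )
    outcomes = []
    for tp in Timepoint:
        values = {}
        for score in _SCORES:
            raw = str(row.get(f"{score}_{tp.value}", "") or "").strip()
            if raw:
                values[score] = float(raw)
        if values:
            if len(values) != len(_SCORES):
                raise ValueError(f"incomplete outcome triple at timepoint {tp.value}")
            outcomes.append(OutcomeRecord(timepoint=tp, **values))
    received = str(row.get("received_arm", "") or "").strip()
    label = str(row.get("outcome_label", "") or "").strip()
    record = PatientRecord(
        id=need("id"),
        age=float(need("age")),
        sex=Sex(need("sex").lower()),
        bmi=float(need("bmi")),
        profile=profile,
        received_arm=Arm(received) if received else None,
        outcome_label=OutcomeLabel(label.lower()) if label else None,
        outcomes=tuple(outcomes),
    )
    violations = record.validate()
    if violations:
        raise ValueError("; ".join(violations))
    return record


def _detect_format(path: Path, fmt: Optional[str]) -> str:
    if fmt:
        return fmt
    return "json" if path.suffix.lower() == ".json" else "csv"


def read_checklist(
    path: str | Path, fmt: Optional[str] = None
) -> tuple[list[PatientRecord], list[str]]:
    """Read patient records from a checklist file.

    Returns (records, errors); each error cites the offending line (CSV,
    header = line 1) or entry index (JSON) and the reason.  Unknown columns
    are reported once by name but do not reject rows.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    records: list[PatientRecord] = []
    errors: list[str] = []
    known = set(BASE_COLUMNS) | set(_OUTCOME_COLUMNS)

    if fmt == "csv":
        with path.open(newline="", encoding="utf-8") as fh:
            reader = csv.DictReader(fh)
            unknown = [c for c in (reader.fieldnames or []) if c not in known]
            if unknown:
                errors.append(f"unknown columns ignored: {', '.join(sorted(unknown))}")
            for lineno, row in enumerate(reader, start=2):
                try:
                    records.append(_row_to_record(row))
                except (ValueError, KeyError) as exc:
                    errors.append(f"line {lineno}: {exc}")
    elif fmt == "json":
        rows = json.loads(path.read_text(encoding="utf-8"))
        if not isinstance(rows, list):
            raise ValueError("JSON checklist must be a list of objects")
        for index, row in enumerate(rows):
            unknown = sorted(set(row) - known)
            if unknown:
                errors.append(f"entry {index}: unknown keys ignored: {', '.join(unknown)}")
            try:
                records.append(_row_to_record(row))
            except (ValueError, KeyError) as exc:
                errors.append(f"entry {index}: {exc}")
    else:
        raise ValueError(f"unsupported checklist format {fmt!r}")
    return records, errors


def write_checklist(records: Sequence[PatientRecord], path: str | Path, fmt: Optional[str] = None) -> Path:
    """Write records as a checklist file (CSV default, or JSON).

    CSV dialect: comma-separated, UTF-8, header row, "." decimal separator.
    """
    path = Path(path)
    fmt = _detect_format(path, fmt)
    rows = [_record_to_row(r) for r in records]
    used_outcomes = [c for c in _OUTCOME_COLUMNS if any(c in row for row in rows)]
    columns = list(BASE_COLUMNS) + used_outcomes
    if fmt == "csv":
        with path.open("w", newline="", encoding="utf-8") as fh:
            writer = csv.DictWriter(fh, fieldnames=columns, lineterminator="\n")
            writer.writeheader()
            for row in rows:
                writer.writerow({c: row.get(c, "") for c in columns})
    elif fmt == "json":
        path.write_text(json.dumps(rows, indent=1) + "\n", encoding="utf-8")
    else:
        raise ValueError(f"unsupported checklist format {fmt!r}")
    return path


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Tabular view of a cohort for the comparison machinery.

    Grades appear as integers (ordinal axis), tropism as a boolean
    ``tropism_present`` (unknown -> NA), outcomes as one column per
    score/timepoint pair.
    """
    rows = []
    for record in records:
        row = _record_to_row(record)
        row["pfirrmann"] = record.profile.pfirrmann
        row["fujiwara"] = record.profile.fujiwara
        row["tropism_present"] = {
            Tropism.PRESENT: True, Tropism.ABSENT: False, Tropism.UNKNOWN: pd.NA
        }[record.profile.tropism]
        rows.append(row)
    return pd.DataFrame(rows)


def load_rule_config(path: str | Path) -> RuleConfig:
    """Load a RuleConfig from a flat YAML mapping of field names to values."""
    mapping = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    return RuleConfig.from_mapping(mapping)


def save_rule_config(config: RuleConfig, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(yaml.safe_dump(config.to_mapping(), sort_keys=True), encoding="utf-8")
    return path


def file_digest(path: str | Path) -> str:
    return "sha256:" + hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class RunManifest:
    """Record of one CLI run: inputs, config, seeds and produced artifacts."""

    command: str
    config: dict
    inputs: dict = field(default_factory=dict)  # path -> digest
    seeds: dict = field(default_factory=dict)
    outputs: list = field(default_factory=list)
    timestamp: str = field(
        default_factory=lambda: _dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds")
    )


def write_manifest(manifest: RunManifest, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(asdict(manifest), indent=1) + "\n", encoding="utf-8")
    return path
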