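"""Canonical record types for both entities, independent of either rendering.

A record stores one value per identifier component. subject_id is held as a
plain integer — zero-padding (human format) and Base62 rendering (stub
format) are codec concerns, so there is a single source of truth with two
renderings.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, fields as dc_fields
from typing import Optional, Union

from .codebook import (
    BIOSAMPLE_FIELDS,
    BIOSAMPLE_OPTIONAL,
    SUBJECT_FIELDS,
    Codebook,
    PatternField,
    VocabField,
)
from .report import ValidationReport

#: Sentinel for "duration not available".
DURATION_NA = "P0N"

_AGE_GROUP_RE = re.compile(r"^A(\d{1,2})_(\d{1,2})$")


@dataclass(frozen=True)
class BiosampleRecord:
    """One biosample: nine mandatory components plus optional batch/replicate."""

    project: str
    species: str
    subject_id: int
    tissue: str
    sample_type: str
    assay: str
    condition: str
    timepoint: str
    duration: str
    batch: Optional[str] = None
    replicate: Optional[str] = None

    entity = "biosample"

    def to_dict(self) -> dict[str, str]:
        d = {
            "project": self.project,
            "species": self.species,
            "subject_id": str(self.subject_id),
            "tissue": self.tissue,
            "sample_type": self.sample_type,
            "assay": self.assay,
            "condition": self.condition,
            "timepoint": self.timepoint,
            "duration": self.duration,
        }
        if self.batch is not None:
            d["batch"] = self.batch
        if self.replicate is not None:
            d["replicate"] = self.replicate
        return d

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "BiosampleRecord":
        return cls(
            project=d["project"],
            species=d["species"],
            subject_id=int(d["subject_id"]),
            tissue=d["tissue"],
            sample_type=d["sample_type"],
            assay=d["assay"],
            condition=d["condition"],
            timepoint=d["timepoint"],
            duration=d["duration"],
            batch=d.get("batch") or None,
            replicate=d.get("replicate") or None,
        )


@dataclass(frozen=True)
class SubjectRecord:
    """One study participant: six mandatory components."""

    study: str
    subject_id: int
    type: str
    condition: str
    sex: str
    age_group: str

    entity = "subject"

    def to_dict(self) -> dict[str, str]:
        return {
            "study": self.study,
            "subject_id": str(self.subject_id),
            "type": self.type,
            "condition": self.condition,
            "sex": self.sex,
            "age_group": self.age_group,
        }

    @classmethod
    def from_dict(cls, d: dict[str, str]) -> "SubjectRecord":
        return cls(
            study=d["study"],
            subject_id=int(d["subject_id"]),
            type=d["type"],
            condition=d["condition"],
            sex=d["sex"],
            age_group=d["age_group"],
        )


Record = Union[BiosampleRecord, SubjectRecord]

#: Component order per entity (mandatory first, then optional).
COMPONENT_ORDER = {
    "biosample": BIOSAMPLE_FIELDS + BIOSAMPLE_OPTIONAL,
    "subject": SUBJECT_FIELDS,
}


def record_fields(entity: str) -> tuple[str, ...]:
    return COMPONENT_ORDER[entity]


def validate_record(rec: Record, cb: Codebook) -> ValidationReport:
    """Check every component of a record against the codebook.

    Violations are data, not exceptions: the report is empty iff every
    vocabulary field resolves and every pattern field matches its regex.
    """
    report = ValidationReport()
    entity = rec.entity
    max_id = cb.max_subject_id(entity)
    if not (0 <= rec.subject_id <= max_id):
        report.add(f"{entity}.subject_id", "range",
                   f"subject_id {rec.subject_id} outside [0, {max_id}] "
                   "(bounded by the human zero-pad and stub Base62 widths)")

    for name in COMPONENT_ORDER[entity]:
        if name == "subject_id":
            continue
        value = getattr(rec, name)
        if value is None:
            if name in BIOSAMPLE_OPTIONAL:
                continue
            report.add(f"{entity}.{name}", "missing", "mandatory component is missing")
            continue
        path = f"{entity}.{name}"
        if not isinstance(value, str) or not value:
            report.add(path, "empty", "component must be a non-empty string")
            continue
        if "-" in value:
            report.add(path, "hyphen",
                       "component may not contain '-' (the human-format delimiter)")
            continue
        try:
            fdef = cb.field(entity, name)
        except Exception:
            report.add(path, "missing_field", f"codebook does not define {path}")
            continue
        if isinstance(fdef, VocabField):
            if value in fdef.by_code:
                continue
            if fdef.pattern is not None and fdef.pattern.match(value):
                continue  # free-form field (study) matching its fallback pattern
            report.add(path, "vocabulary", f"{value!r} is not in the {path} vocabulary")
        elif isinstance(fdef, PatternField):
            if not fdef.matches(value):
                report.add(path, "pattern",
                           f"{value!r} does not match {fdef.regex.pattern!r}")
            elif name == "duration" and len(value) > 4:  # 'P' + <=3-char payload
                report.add(path, "width", "duration payload must be at most 3 characters")

    if entity == "subject":
        m = _AGE_GROUP_RE.match(rec.age_group or "")
        if m and not int(m.group(1)) < int(m.group(2)):
            report.add("subject.age_group", "range",
                       f"age_group {rec.age_group!r} must have lower bound < upper bound")
    return report


def make_record(entity: str, components: dict[str, str]) -> Record:
    """Build a record from a flat component→string map (the CSV row contract)."""
    cls = BiosampleRecord if entity == "biosample" else SubjectRecord
    return cls.from_dict(components)
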