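"""The verbose, hyphen-delimited rendering.

Biosample grammar (9 mandatory + 2 optional components)::

    project-species-subject_id-tissue-sample_type-assay-condition-timepoint-duration[-batch][-replicate]

Subject grammar (6 components)::

    study-subject_id-type-condition-sex-age_group

The hyphen is reserved as the delimiter, which is why record validation
rejects any component containing one; names with internal separators use
underscores (``CNAG_Test``, ``TARGET_AML``).
"""

from __future__ import annotations

import re

from .codebook import Codebook
from .errors import DecodeError, EncodeError, StructuralError, VocabularyError
from .records import BiosampleRecord, Record, SubjectRecord, validate_record

_BATCH_RE = re.compile(r"^B\d{2}$")
_REPL_RE = re.compile(r"^R\d{2}$")


def encode_human(rec: Record, cb: Codebook) -> str:
    """Render a record in human format. The record must validate cleanly."""
    report = validate_record(rec, cb)
    if not report.ok:
        raise EncodeError(report.violations)
    hw, _ = cb.id_widths(rec.entity)
    sid = str(rec.subject_id).zfill(hw)
    if rec.entity == "biosample":
        parts = [rec.project, rec.species, sid, rec.tissue, rec.sample_type,
                 rec.assay, rec.condition, rec.timepoint, rec.duration]
        if rec.batch is not None:
            parts.append(rec.batch)
        if rec.replicate is not None:
            parts.append(rec.replicate)
    else:
        parts = [rec.study, sid, rec.type, rec.condition, rec.sex, rec.age_group]
    return "-".join(parts)


def decode_human(s: str, entity: str, cb: Codebook, lenient: bool = False) -> Record:
    """Parse a human-format identifier back into a record.

    Strict by default: surrounding whitespace is an error unless
    ``lenient=True``, which trims it first.
    """
    if lenient:
        s = s.strip()
    if not s or s != s.strip():
        raise StructuralError(f"identifier {s!r} has surrounding whitespace or is empty")
    parts = s.split("-")
    if entity == "subject":
        return _decode_subject(s, parts, cb)
    if entity == "biosample":
        return _decode_biosample(s, parts, cb)
    raise StructuralError(f"unknown entity {entity!r}")


def _check_parts(parts: list[str], s: str) -> None:
    if any(p == "" for p in parts):
        raise StructuralError(f"identifier {s!r} contains an empty component")


def _decode_subject(s: str, parts: list[str], cb: Codebook) -> SubjectRecord:
    if len(parts) != 6:
        raise StructuralError(
            f"subject identifier must have 6 hyphen-separated parts, got {len(parts)}: {s!r}")
    _check_parts(parts, s)
    study, sid, type_, condition, sex, age_group = parts
    rec = SubjectRecord(
        study=study,
        subject_id=_parse_id(sid),
        type=type_,
        condition=condition,
        sex=sex,
        age_group=age_group,
    )
    _require_valid(rec, cb)
    return rec


def _decode_biosample(s: str, parts: list[str], cb: Codebook) -> BiosampleRecord:
    if len(parts) not in (9, 10, 11):
        raise StructuralError(
            "biosample identifier must have 9 mandatory parts plus up to 2 "
            f"optional ones (9-11 total), got {len(parts)}: {s!r}")
    _check_parts(parts, s)
    batch = replicate = None
    tail = parts[9:]
    if len(tail) == 2:
        batch, replicate = tail
        if not _BATCH_RE.match(batch) or not _REPL_RE.match(replicate):
            raise StructuralError(
                f"optional parts must be batch (B##) then replicate (R##), got {tail}")
    elif len(tail) == 1:
        # a single optional part is batch or replicate depending on its shape
        if _BATCH_RE.match(tail[0]):
            batch = tail[0]
        elif _REPL_RE.match(tail[0]):
            replicate = tail[0]
        else:
            raise StructuralError(
                f"10th part must be a batch (B##) or replicate (R##), got {tail[0]!r}")
    rec = BiosampleRecord(
        project=parts[0],
        species=parts[1],
        subject_id=_parse_id(parts[2]),
        tissue=parts[3],
        sample_type=parts[4],
        assay=parts[5],
        condition=parts[6],
        timepoint=parts[7],
        duration=parts[8],
        batch=batch,
        replicate=replicate,
    )
    _require_valid(rec, cb)
    return rec


def _parse_id(token: str) -> int:
    if not token.isdigit():
        raise DecodeError(f"subject_id component {token!r} is not numeric")
    return int(token)


def _require_valid(rec: Record, cb: Codebook) -> None:
    report = validate_record(rec, cb)
    for v in report.violations:
        if v.kind == "vocabulary":
            entity, field = v.path.split(".", 1)
            raise VocabularyError(entity, field, getattr(rec, field))
    if not report.ok:
        raise DecodeError(
            "decoded record failed validation: "
            + "; ".join(str(v) for v in report.violations))
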