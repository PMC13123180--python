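"""The compact, delimiter-free "stub" rendering.

Layout (all positions fixed-width except where noted)::

    biosample: projectStub · species(2) · subject_id62(3) · tissue(1) ·
               sample_type(1) · assay(1) · condition(5) · timepoint(1-2) ·
               durationPayload(2-3) · [B##] · [R##]
    subject:   studyStub · subject_id62(3) · type(1) · condition(5) ·
               sex(1) · age_group(2)

subject_id is Base62 at the codebook's stub width (default 3, so up to
238,327 ids); the binding cap on a record is the smaller of the human and
stub caps. Decoding a biosample stub consumes the longest registered
project-stub prefix, reads the fixed-width fields through the condition
stub, then parses the remainder from the END: optional replicate ``R##``,
optional batch ``B##``, the duration payload ``\\d{1,2}[A-Z]``, and the
residue is the timepoint stub (variable 1-2 characters, resolved against
the codebook, with backtracking over the duration split). Subject stubs
keep a fixed 12-character tail, so the study stub is everything before it.

Condition stubs are 5 Base62 characters. The codebook's override table is
consulted first; otherwise the ICD-10 code minus its dot is read as a
base-36 integer (``0-9A-Z``) and rendered in Base62 at width 5. Decoding
inverts: override reverse-map first, else Base62 → base-36, with the dot
reinserted after the third character when more than three remain. Because
ICD-10 codes start with a letter (base-36 value >= 10) the natural base-36
rendering has no leading zero, so the round trip is exact.
"""

from __future__ import annotations

import re

from .base62 import base62_decode, base62_encode, is_base62
from .codebook import Codebook, ICD10_RE, VocabField
from .errors import (
    DecodeError,
    EncodeError,
    StructuralError,
    VocabularyError,
)
from .records import BiosampleRecord, Record, SubjectRecord, validate_record

_BASE36 = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZ"
_B36_INDEX = {c: i for i, c in enumerate(_BASE36)}

CONDITION_STUB_WIDTH = 5
_DUR_PAYLOAD_RE = re.compile(r"^\d{1,2}[A-Z]$")
_BATCH_RE = re.compile(r"B\d{2}$")
_REPL_RE = re.compile(r"R\d{2}$")

#: widths of the fixed biosample segment after the project stub
_SPECIES_W, _TISSUE_W, _ST_W, _ASSAY_W = 2, 1, 1, 1
#: widths of the fixed subject tail after the study stub (id62 added at runtime)
_TYPE_W, _SEX_W, _AGE_W = 1, 1, 2


# -- condition stub codec ----------------------------------------------


def condition_fallback_encode(icd10: str) -> str:
    """Algorithmic condition stub: base-36 of the dotless code, in Base62."""
    if not ICD10_RE.match(icd10):
        raise StructuralError(f"{icd10!r} is not a valid ICD-10 code")
    value = 0
    for c in icd10.replace(".", ""):
        value = value * 36 + _B36_INDEX[c]
    return base62_encode(value, CONDITION_STUB_WIDTH)


def condition_fallback_decode(stub: str) -> str:
    """Invert :func:`condition_fallback_encode`; raises on non-images."""
    value = base62_decode(stub)
    if value == 0:
        raise DecodeError(f"condition stub {stub!r} does not decode to an ICD-10 code")
    digits = []
    while value:
        value, r = divmod(value, 36)
        digits.append(_BASE36[r])
    body = "".join(reversed(digits))
    if len(body) > 3:
        body = body[:3] + "." + body[3:]
    if not ICD10_RE.match(body):
        raise DecodeError(f"condition stub {stub!r} decodes to {body!r}, "
                          "which is not a valid ICD-10 code")
    return body


def encode_condition_stub(icd10: str, cb: Codebook) -> str:
    """Override table first (byte-exact compatibility), fallback otherwise."""
    override = cb.condition_stub_overrides.get(icd10)
    if override is not None:
        return override
    return condition_fallback_encode(icd10)


def decode_condition_stub(stub: str, cb: Codebook) -> str:
    if len(stub) != CONDITION_STUB_WIDTH or not is_base62(stub):
        raise DecodeError(
            f"condition stub must be {CONDITION_STUB_WIDTH} Base62 characters, got {stub!r}")
    for code, s in cb.condition_stub_overrides.items():
        if s == stub:
            return code
    return condition_fallback_decode(stub)


# -- helpers ------------------------------------------------------------


def _stub_of(cb: Codebook, entity: str, field: str, code: str) -> str:
    return cb.lookup(entity, field, code).stub_code


def _study_stub(cb: Codebook, study: str) -> str:
    """Registered stub alias if any, else the study name verbatim."""
    fdef = cb.entities["subject"].get("study")
    if isinstance(fdef, VocabField) and study in fdef.by_code:
        return fdef.by_code[study].stub_code
    return study


def _study_from_stub(cb: Codebook, stub: str) -> str:
    fdef = cb.entities["subject"].get("study")
    if isinstance(fdef, VocabField) and stub in fdef.by_stub:
        return fdef.by_stub[stub].code
    return stub


def _project_stub_prefixes(cb: Codebook) -> dict[str, str]:
    fdef = cb.entities["biosample"].get("project")
    if isinstance(fdef, VocabField):
        return {e.stub_code: e.code for e in fdef.entries.values()}
    return {}


def _strict(s: str) -> str:
    if not s or s != s.strip():
        raise StructuralError(f"identifier {s!r} has surrounding whitespace or is empty")
    return s


# -- encoding ------------------------------------------------------------


def encode_stub(rec: Record, cb: Codebook) -> str:
    """Render a record in stub format. The record must validate cleanly."""
    report = validate_record(rec, cb)
    if not report.ok:
        raise EncodeError(report.violations)
    _, sw = cb.id_widths(rec.entity)
    sid = base62_encode(rec.subject_id, sw)
    cond = encode_condition_stub(rec.condition, cb)
    if rec.entity == "biosample":
        parts = [
            _stub_of(cb, "biosample", "project", rec.project),
            _stub_of(cb, "biosample", "species", rec.species),
            sid,
            _stub_of(cb, "biosample", "tissue", rec.tissue),
            _stub_of(cb, "biosample", "sample_type", rec.sample_type),
            _stub_of(cb, "biosample", "assay", rec.assay),
            cond,
            _stub_of(cb, "biosample", "timepoint", rec.timepoint),
            rec.duration[1:],  # ISO payload without the leading 'P'
        ]
        if rec.batch is not None:
            parts.append(rec.batch)
        if rec.replicate is not None:
            parts.append(rec.replicate)
    else:
        parts = [
            _study_stub(cb, rec.study),
            sid,
            _stub_of(cb, "subject", "type", rec.type),
            cond,
            _stub_of(cb, "subject", "sex", rec.sex),
            _stub_of(cb, "subject", "age_group", rec.age_group),
        ]
    return "".join(parts)


# -- decoding ------------------------------------------------------------


def decode_stub(s: str, entity: str, cb: Codebook, lenient: bool = False) -> Record:
    """Parse a stub identifier back into a record (strict on whitespace)."""
    if lenient:
        s = s.strip()
    _strict(s)
    if entity == "subject":
        return _decode_subject_stub(s, cb)
    if entity == "biosample":
        return _decode_biosample_stub(s, cb)
    raise StructuralError(f"unknown entity {entity!r}")


def _decode_subject_stub(s: str, cb: Codebook) -> SubjectRecord:
    _, sw = cb.id_widths("subject")
    tail = sw + _TYPE_W + CONDITION_STUB_WIDTH + _SEX_W + _AGE_W
    if len(s) < tail + 1:
        raise StructuralError(
            f"subject stub must be at least {tail + 1} characters "
            f"(study stub + fixed {tail}-character tail), got {len(s)}: {s!r}")
    study_stub, rest = s[:-tail], s[-tail:]
    pos = 0
    sid62 = rest[pos:pos + sw]; pos += sw
    type_stub = rest[pos:pos + _TYPE_W]; pos += _TYPE_W
    cond_stub = rest[pos:pos + CONDITION_STUB_WIDTH]; pos += CONDITION_STUB_WIDTH
    sex_stub = rest[pos:pos + _SEX_W]; pos += _SEX_W
    age_stub = rest[pos:]
    rec = SubjectRecord(
        study=_study_from_stub(cb, study_stub),
        subject_id=base62_decode(sid62),
        type=cb.reverse_lookup("subject", "type", type_stub).code,
        condition=decode_condition_stub(cond_stub, cb),
        sex=cb.reverse_lookup("subject", "sex", sex_stub).code,
        age_group=cb.reverse_lookup("subject", "age_group", age_stub).code,
    )
    _require_valid(rec, cb)
    return rec


def _decode_biosample_stub(s: str, cb: Codebook) -> BiosampleRecord:
    prefixes = _project_stub_prefixes(cb)
    matches = [p for p in prefixes if s.startswith(p)]
    if not matches:
        raise VocabularyError("biosample", "project", s[:8] + ("…" if len(s) > 8 else ""),
                              kind="stub prefix")
    pstub = max(matches, key=len)
    _, sw = cb.id_widths("biosample")
    pos = len(pstub)
    need = _SPECIES_W + sw + _TISSUE_W + _ST_W + _ASSAY_W + CONDITION_STUB_WIDTH
    if len(s) < pos + need + 3:  # +3: shortest timepoint (1) + shortest duration payload (2)
        raise StructuralError(f"biosample stub {s!r} is too short")
    species_stub = s[pos:pos + _SPECIES_W]; pos += _SPECIES_W
    sid62 = s[pos:pos + sw]; pos += sw
    tissue_stub = s[pos:pos + _TISSUE_W]; pos += _TISSUE_W
    st_stub = s[pos:pos + _ST_W]; pos += _ST_W
    assay_stub = s[pos:pos + _ASSAY_W]; pos += _ASSAY_W
    cond_stub = s[pos:pos + CONDITION_STUB_WIDTH]; pos += CONDITION_STUB_WIDTH
    rest = s[pos:]

    batch = replicate = None
    m = _REPL_RE.search(rest)
    if m:
        replicate, rest = rest[m.start():], rest[:m.start()]
    m = _BATCH_RE.search(rest)
    if m:
        batch, rest = rest[m.start():], rest[:m.start()]
    if not rest:
        raise StructuralError(
            f"biosample stub {s!r} is missing its timepoint/duration segment")

    timepoint, duration = _split_timepoint_duration(rest, cb)
    rec = BiosampleRecord(
        project=prefixes[pstub],
        species=cb.reverse_lookup("biosample", "species", species_stub).code,
        subject_id=base62_decode(sid62),
        tissue=cb.reverse_lookup("biosample", "tissue", tissue_stub).code,
        sample_type=cb.reverse_lookup("biosample", "sample_type", st_stub).code,
        assay=cb.reverse_lookup("biosample", "assay", assay_stub).code,
        condition=decode_condition_stub(cond_stub, cb),
        timepoint=timepoint,
        duration=duration,
        batch=batch,
        replicate=replicate,
    )
    _require_valid(rec, cb)
    return rec


def _split_timepoint_duration(rest: str, cb: Codebook) -> tuple[str, str]:
    """End-anchored split of <timepointStub><durationPayload>.

    The duration payload is 2-3 characters (``\\d{1,2}[A-Z]``); the residue
    must resolve as a timepoint stub. Longer payloads are preferred, with
    backtracking to the shorter split when the residue does not resolve.
    """
    last_error: Exception | None = None
    for plen in (3, 2):
        if len(rest) <= plen:
            continue
        payload, tp_stub = rest[-plen:], rest[:-plen]
        if not _DUR_PAYLOAD_RE.match(payload):
            continue
        try:
            entry = cb.reverse_lookup("biosample", "timepoint", tp_stub)
        except VocabularyError as exc:
            last_error = exc
            continue
        return entry.code, "P" + payload
    if last_error is not None:
        raise last_error
    raise StructuralError(
        f"cannot split {rest!r} into a timepoint stub and a duration payload "
        "(expected <stub><digits><UPPERCASE> at the end)")


def _require_valid(rec: Record, cb: Codebook) -> None:
    report = validate_record(rec, cb)
    if not report.ok:
        raise DecodeError("decoded record failed validation: "
                          + "; ".join(str(v) for v in report.violations))
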