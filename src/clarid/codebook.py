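"""Load, validate and query the YAML codebook.

The codebook is the single source of truth for both identifier renderings:
every controlled-vocabulary component maps a long-form ``code`` (used in
the hyphen-delimited human format) to a compact ``stub_code`` (used in the
delimiter-free stub format). Fields whose values cannot be enumerated
(subject_id, duration, batch, replicate, condition, study) are defined by
anchored regular expressions instead.

Layout: under each entity section (``biosample``, ``subject``) every field
is a key. Vocabulary fields list their entries as sub-keys carrying
``code``/``stub_code``/``id``/``label`` (plus ``tax_code`` for species);
pattern fields use the reserved ``pattern`` sub-key (optionally with
``human_width``/``stub_width``). A field may carry both entries and a
``pattern`` — the study field does, because studies are free-form unless a
compact stub alias is registered for them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from typing import Any, Optional, Union

import yaml

from .base62 import is_base62
from .errors import CodebookError, ConfigError, VocabularyError
from .report import ValidationReport
from .schemaval import check_schema, load_schema, validate as schema_validate

#: Mandatory field order per entity — also the component order in identifiers.
BIOSAMPLE_FIELDS = (
    "project", "species", "subject_id", "tissue", "sample_type",
    "assay", "condition", "timepoint", "duration",
)
BIOSAMPLE_OPTIONAL = ("batch", "replicate")
SUBJECT_FIELDS = ("study", "subject_id", "type", "condition", "sex", "age_group")

#: Expected stub widths (min, max) for fixed-width vocabulary fields.
#: project and study stubs are free-form (and may contain a hyphen).
STUB_WIDTHS: dict[tuple[str, str], tuple[int, int]] = {
    ("biosample", "species"): (2, 2),
    ("biosample", "tissue"): (1, 1),
    ("biosample", "sample_type"): (1, 1),
    ("biosample", "assay"): (1, 1),
    ("biosample", "timepoint"): (1, 2),
    ("subject", "type"): (1, 1),
    ("subject", "sex"): (1, 1),
    ("subject", "age_group"): (2, 2),
}

_FREE_STUB_FIELDS = {"project", "study"}
#: Fields exempt from the uniform-stub-length rule (timepoint is 1-2 chars
#: by design: the end-anchored duration parse disambiguates on decode).
_VARIABLE_STUB_FIELDS = _FREE_STUB_FIELDS | {"timepoint"}

_RESERVED_FIELD_KEYS = {"pattern", "human_width", "stub_width"}
_CURIE_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.-]*:\S+$")
ICD10_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")

DEFAULT_HUMAN_ID_WIDTH = 5
DEFAULT_STUB_ID_WIDTH = 3


@dataclass(frozen=True)
class VocabEntry:
    """One controlled-vocabulary term.

    ``id``/``label`` follow the ontologyClass convention: ``id`` is a CURIE
    (e.g. ``UBERON:0002107``) and ``label`` the class name. Both are
    reference annotations; only ``code`` and ``stub_code`` are ever emitted
    into identifiers. ``tax_code`` (species only) is likewise retained for
    reference and disambiguation, never rendered.
    """

    key: str
    code: str
    stub_code: str
    id: Optional[str] = None
    label: Optional[str] = None
    tax_code: Optional[str] = None


@dataclass
class PatternField:
    """A field whose values are constrained by an anchored regex."""

    name: str
    regex: re.Pattern
    human_width: Optional[int] = None
    stub_width: Optional[int] = None

    def matches(self, value: str) -> bool:
        return bool(self.regex.match(value))


@dataclass
class VocabField:
    """A controlled-vocabulary field, with optional free-form fallback pattern."""

    name: str
    entries: dict[str, VocabEntry] = dc_field(default_factory=dict)
    pattern: Optional[re.Pattern] = None
    by_code: dict[str, VocabEntry] = dc_field(default_factory=dict)
    by_stub: dict[str, VocabEntry] = dc_field(default_factory=dict)

    def rebuild_index(self) -> None:
        # last writer wins on duplicates; validate_codebook reports them
        self.by_code = {e.code: e for e in self.entries.values()}
        self.by_stub = {e.stub_code: e for e in self.entries.values()}


FieldDef = Union[VocabField, PatternField]


class Codebook:
    """Parsed codebook with bidirectional vocabulary indices."""

    def __init__(
        self,
        biosample: dict[str, FieldDef],
        subject: dict[str, FieldDef],
        condition_stub_overrides: Optional[dict[str, str]] = None,
        version: str = "",
        raw: Optional[dict] = None,
    ):
        self.entities: dict[str, dict[str, FieldDef]] = {
            "biosample": biosample,
            "subject": subject,
        }
        self.condition_stub_overrides = dict(condition_stub_overrides or {})
        self.version = version
        self.raw = raw if raw is not None else {}

    # -- construction -------------------------------------------------

    @classmethod
    def from_dict(cls, doc: dict) -> "Codebook":
        if not isinstance(doc, dict):
            raise CodebookError("codebook document must be a YAML mapping")
        for section in ("biosample", "subject"):
            if section not in doc:
                raise CodebookError(f"codebook is missing the {section!r} section")
            if not isinstance(doc[section], dict):
                raise CodebookError(f"codebook section {section!r} must be a mapping")
        entities = {}
        for section in ("biosample", "subject"):
            fields: dict[str, FieldDef] = {}
            for fname, node in doc[section].items():
                fields[str(fname)] = _parse_field(section, str(fname), node)
            entities[section] = fields
        overrides = doc.get("condition_stub_overrides") or {}
        if not isinstance(overrides, dict):
            raise CodebookError("condition_stub_overrides must be a mapping")
        return cls(
            biosample=entities["biosample"],
            subject=entities["subject"],
            condition_stub_overrides={str(k): str(v) for k, v in overrides.items()},
            version=str(doc.get("version", "")),
            raw=doc,
        )

    # -- queries ------------------------------------------------------

    def field(self, entity: str, name: str) -> FieldDef:
        try:
            fields = self.entities[entity]
        except KeyError:
            raise CodebookError(f"unknown entity {entity!r}") from None
        try:
            return fields[name]
        except KeyError:
            raise CodebookError(f"entity {entity!r} has no field {name!r}") from None

    def vocab(self, entity: str, name: str) -> VocabField:
        f = self.field(entity, name)
        if not isinstance(f, VocabField):
            raise CodebookError(f"{entity}.{name} is not vocabulary-backed")
        return f

    def lookup(self, entity: str, field: str, code: str) -> VocabEntry:
        """Resolve a human-format token to its vocabulary entry."""
        f = self.vocab(entity, field)
        try:
            return f.by_code[code]
        except KeyError:
            raise VocabularyError(entity, field, code, kind="code") from None

    def reverse_lookup(self, entity: str, field: str, stub: str) -> VocabEntry:
        """Resolve a stub-format token to its vocabulary entry."""
        f = self.vocab(entity, field)
        try:
            return f.by_stub[stub]
        except KeyError:
            raise VocabularyError(entity, field, stub, kind="stub") from None

    def id_widths(self, entity: str) -> tuple[int, int]:
        """(human zero-pad width, stub Base62 width) for subject_id."""
        f = self.entities[entity].get("subject_id")
        hw = sw = None
        if isinstance(f, PatternField):
            hw, sw = f.human_width, f.stub_width
        return (hw or DEFAULT_HUMAN_ID_WIDTH, sw or DEFAULT_STUB_ID_WIDTH)

    def max_subject_id(self, entity: str) -> int:
        hw, sw = self.id_widths(entity)
        return min(10**hw, 62**sw) - 1


def _parse_field(entity: str, name: str, node: Any) -> FieldDef:
    if not isinstance(node, dict) or not node:
        raise CodebookError(f"{entity}.{name}: field definition must be a non-empty mapping")
    pattern = None
    if "pattern" in node:
        try:
            pattern = re.compile(str(node["pattern"]))
        except re.error as exc:
            raise CodebookError(f"{entity}.{name}: invalid pattern: {exc}") from exc
    entry_keys = [k for k in node if k not in _RESERVED_FIELD_KEYS]
    if not entry_keys:
        if pattern is None:
            raise CodebookError(f"{entity}.{name}: needs entries or a pattern")
        return PatternField(
            name=name,
            regex=pattern,
            human_width=_opt_int(entity, name, node, "human_width"),
            stub_width=_opt_int(entity, name, node, "stub_width"),
        )
    entries = {}
    for key in entry_keys:
        spec = node[key]
        if not isinstance(spec, dict):
            raise CodebookError(f"{entity}.{name}.{key}: entry must be a mapping")
        entries[str(key)] = VocabEntry(
            key=str(key),
            code=str(spec.get("code", key)),
            stub_code=str(spec.get("stub_code", "")),
            id=_opt_str(spec, "id"),
            label=_opt_str(spec, "label"),
            tax_code=_opt_str(spec, "tax_code"),
        )
    f = VocabField(name=name, entries=entries, pattern=pattern)
    f.rebuild_index()
    return f


def _opt_str(spec: dict, key: str) -> Optional[str]:
    v = spec.get(key)
    return None if v is None else str(v)


def _opt_int(entity: str, name: str, node: dict, key: str) -> Optional[int]:
    v = node.get(key)
    if v is None:
        return None
    if not isinstance(v, int) or isinstance(v, bool) or v <= 0:
        raise CodebookError(f"{entity}.{name}: {key} must be a positive integer")
    return v


# -- loading ----------------------------------------------------------


def load_codebook(path: Union[str, Path]) -> Codebook:
    """Read and parse a codebook YAML file.

    Raises :class:`CodebookError` with a line number on YAML syntax errors
    and on missing entity sections.
    """
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except OSError as exc:
        raise CodebookError(f"cannot read codebook {path}: {exc}") from exc
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        mark = getattr(exc, "problem_mark", None)
        where = f" at line {mark.line + 1}" if mark is not None else ""
        raise CodebookError(f"YAML parse error in {path}{where}: {exc}") from exc
    if doc is None:
        raise CodebookError(f"codebook {path} is empty")
    return Codebook.from_dict(doc)


def bundled_schema_path() -> Path:
    return Path(str(resources.files("clarid").joinpath("data/codebook.schema.json")))


def bundled_codebook_path() -> Path:
    return Path(str(resources.files("clarid").joinpath("data/codebook.yaml")))


# -- validation -------------------------------------------------------


def validate_codebook(
    cb: Codebook,
    schema: Union[str, Path, None] = None,
    debug: bool = False,
) -> ValidationReport:
    """Validate a codebook against a JSON Schema plus the semantic rules
    the schema cannot express (cross-entry uniqueness, stub widths, CURIE
    shape, override consistency).

    With ``debug=True`` the schema document itself is also self-validated
    and any meta-level findings are included in the report.
    """
    schema_doc = load_schema(schema if schema is not None else bundled_schema_path())
    report = ValidationReport()
    if debug:
        report.extend(check_schema(schema_doc))
    if cb.raw:
        report.extend(schema_validate(cb.raw, schema_doc, path="$"))
    _semantic_checks(cb, report)
    return report


def _semantic_checks(cb: Codebook, report: ValidationReport) -> None:
    for entity, mandatory in (("biosample", BIOSAMPLE_FIELDS + BIOSAMPLE_OPTIONAL),
                              ("subject", SUBJECT_FIELDS)):
        fields = cb.entities[entity]
        for fname in mandatory:
            if fname not in fields:
                report.add(f"{entity}.{fname}", "missing_field",
                           f"entity {entity!r} must define field {fname!r}")
        for fname, fdef in fields.items():
            base = f"{entity}.{fname}"
            if isinstance(fdef, PatternField):
                _check_pattern_field(base, fdef, report)
            else:
                _check_vocab_field(entity, base, fdef, report)
                if fdef.pattern is not None:
                    _check_anchoring(base, fdef.pattern, report)
    _check_overrides(cb, report)


def _check_pattern_field(base: str, fdef: PatternField, report: ValidationReport) -> None:
    _check_anchoring(base, fdef.regex, report)


def _check_anchoring(base: str, regex: re.Pattern, report: ValidationReport) -> None:
    pat = regex.pattern
    if not (pat.startswith("^") and pat.endswith("$")):
        report.add(f"{base}.pattern", "anchoring",
                   f"pattern {pat!r} must be anchored at both ends")


def _check_vocab_field(entity: str, base: str, fdef: VocabField,
                       report: ValidationReport) -> None:
    seen_codes: dict[str, str] = {}
    seen_stubs: dict[str, str] = {}
    widths = STUB_WIDTHS.get((entity, fdef.name))
    lengths = set()
    for key, e in fdef.entries.items():
        epath = f"{base}.{key}"
        if not e.code:
            report.add(f"{epath}.code", "empty", "code must be non-empty")
        elif "-" in e.code:
            report.add(f"{epath}.code", "hyphen",
                       "code may not contain '-' (the human-format delimiter)")
        if not e.stub_code:
            report.add(f"{epath}.stub_code", "empty", "stub_code must be non-empty")
        else:
            if fdef.name in _FREE_STUB_FIELDS:
                body = e.stub_code.replace("-", "")
                if not body or not is_base62(body):
                    report.add(f"{epath}.stub_code", "alphabet",
                               f"stub {e.stub_code!r} must be Base62 (hyphen allowed)")
            elif not is_base62(e.stub_code):
                report.add(f"{epath}.stub_code", "alphabet",
                           f"stub {e.stub_code!r} contains non-Base62 characters")
            lengths.add(len(e.stub_code))
            if widths is not None:
                lo, hi = widths
                if not (lo <= len(e.stub_code) <= hi):
                    want = str(lo) if lo == hi else f"{lo}-{hi}"
                    report.add(f"{epath}.stub_code", "width",
                               f"stub {e.stub_code!r} must be {want} character(s)")
        if e.code in seen_codes:
            report.add(f"{epath}.code", "duplicate_code",
                       f"code {e.code!r} already used by entry {seen_codes[e.code]!r}")
        else:
            seen_codes[e.code] = key
        if e.stub_code in seen_stubs:
            report.add(f"{epath}.stub_code", "duplicate_stub",
                       f"stub {e.stub_code!r} already used by entry {seen_stubs[e.stub_code]!r}")
        else:
            seen_stubs[e.stub_code] = key
        if e.id is not None and not _CURIE_RE.match(e.id):
            report.add(f"{epath}.id", "curie",
                       f"{e.id!r} is not a CURIE (expected prefix:local)")
    if fdef.name not in _VARIABLE_STUB_FIELDS and len(lengths) > 1:
        report.add(f"{base}", "width",
                   f"stub_code lengths within {base} must be uniform, found {sorted(lengths)}")


def _check_overrides(cb: Codebook, report: ValidationReport) -> None:
    from .stub import condition_fallback_decode  # local import: avoids cycle

    for code, stub in cb.condition_stub_overrides.items():
        base = f"condition_stub_overrides.{code}"
        if not ICD10_RE.match(code):
            report.add(base, "pattern", f"{code!r} is not a valid ICD-10 code")
        if len(stub) != 5 or not is_base62(stub):
            report.add(base, "width",
                       f"override stub {stub!r} must be exactly 5 Base62 characters")
            continue
        # an override must not shadow the algorithmic image of a *different* code
        try:
            shadowed = condition_fallback_decode(stub)
        except Exception:
            continue
        if shadowed != code:
            report.add(base, "override_collision",
                       f"override {stub!r} collides with the fallback encoding of {shadowed!r}")
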