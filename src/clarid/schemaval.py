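"""Minimal JSON-Schema (draft 2020-12 subset) validator.

Supports the keyword subset the bundled codebook schema uses:
``type``, ``enum``, ``const``, ``pattern``, ``minLength``, ``maxLength``,
``minimum``, ``maximum``, ``required``, ``properties``,
``patternProperties``, ``additionalProperties``, ``items``, ``anyOf``.
Annotation keywords (``$schema``, ``$id``, ``title``, ``description``,
``default``, ``examples``) are ignored. Applicators outside this subset
(``$ref``, ``allOf``...) are rejected by :func:`check_schema` so a schema
relying on them fails loudly instead of silently passing documents.
"""

from __future__ import annotations

import re
from typing import Any

from .errors import ConfigError
from .report import ValidationReport

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
    "null": type(None),
}

_ANNOTATIONS = {"$schema", "$id", "title", "description", "default", "examples", "$comment"}
_SUPPORTED = _ANNOTATIONS | {
    "type", "enum", "const", "pattern", "minLength", "maxLength",
    "minimum", "maximum", "required", "properties", "patternProperties",
    "additionalProperties", "items", "anyOf",
}


def _type_ok(value: Any, tname: str) -> bool:
    py = _TYPES.get(tname)
    if py is None:
        return False
    if tname == "integer":
        return isinstance(value, int) and not isinstance(value, bool)
    if tname == "number":
        return isinstance(value, (int, float)) and not isinstance(value, bool)
    if tname == "boolean":
        return isinstance(value, bool)
    return isinstance(value, py)


def validate(instance: Any, schema: dict, path: str = "$") -> ValidationReport:
    """Validate ``instance`` against ``schema``; returns a report of violations."""
    report = ValidationReport()
    _validate(instance, schema, path, report)
    return report


def _validate(value: Any, schema: Any, path: str, report: ValidationReport) -> None:
    if schema is True or schema == {}:
        return
    if schema is False:
        report.add(path, "schema", "value not permitted here")
        return

    if "type" in schema:
        types = schema["type"]
        if isinstance(types, str):
            types = [types]
        if not any(_type_ok(value, t) for t in types):
            report.add(path, "schema", f"expected type {'/'.join(types)}, got {type(value).__name__}")
            return  # type mismatch makes the remaining keywords moot

    if "enum" in schema and value not in schema["enum"]:
        report.add(path, "schema", f"{value!r} is not one of {schema['enum']}")
    if "const" in schema and value != schema["const"]:
        report.add(path, "schema", f"{value!r} != const {schema['const']!r}")

    if isinstance(value, str):
        if "pattern" in schema and not re.search(schema["pattern"], value):
            report.add(path, "schema", f"{value!r} does not match pattern {schema['pattern']!r}")
        if "minLength" in schema and len(value) < schema["minLength"]:
            report.add(path, "schema", f"length {len(value)} < minLength {schema['minLength']}")
        if "maxLength" in schema and len(value) > schema["maxLength"]:
            report.add(path, "schema", f"length {len(value)} > maxLength {schema['maxLength']}")

    if isinstance(value, (int, float)) and not isinstance(value, bool):
        if "minimum" in schema and value < schema["minimum"]:
            report.add(path, "schema", f"{value} < minimum {schema['minimum']}")
        if "maximum" in schema and value > schema["maximum"]:
            report.add(path, "schema", f"{value} > maximum {schema['maximum']}")

    if isinstance(value, dict):
        for req in schema.get("required", []):
            if req not in value:
                report.add(path, "schema", f"required property {req!r} is missing")
        props = schema.get("properties", {})
        patprops = schema.get("patternProperties", {})
        addl = schema.get("additionalProperties", True)
        for key, sub in value.items():
            kpath = f"{path}.{key}"
            matched = False
            if key in props:
                matched = True
                _validate(sub, props[key], kpath, report)
            for pat, psch in patprops.items():
                if re.search(pat, str(key)):
                    matched = True
                    _validate(sub, psch, kpath, report)
            if not matched:
                if addl is False:
                    report.add(kpath, "schema", f"additional property {key!r} not allowed")
                elif isinstance(addl, dict):
                    _validate(sub, addl, kpath, report)

    if isinstance(value, list) and "items" in schema:
        for i, item in enumerate(value):
            _validate(item, schema["items"], f"{path}[{i}]", report)

    if "anyOf" in schema:
        branches = schema["anyOf"]
        if not any(validate(value, br, path).ok for br in branches):
            report.add(path, "schema", "value matches none of the anyOf branches")


def check_schema(schema: Any, path: str = "$") -> ValidationReport:
    """Self-validate a schema document: well-formed keyword values, and no
    applicators outside the supported subset."""
    report = ValidationReport()
    _check(schema, path, report)
    return report


def _check(schema: Any, path: str, report: ValidationReport) -> None:
    if isinstance(schema, bool):
        return
    if not isinstance(schema, dict):
        report.add(path, "meta", f"schema must be an object or boolean, got {type(schema).__name__}")
        return
    for key, val in schema.items():
        kpath = f"{path}.{key}"
        if key not in _SUPPORTED:
            report.add(kpath, "meta", f"unsupported schema keyword {key!r}")
            continue
        if key == "type":
            names = [val] if isinstance(val, str) else val
            if not isinstance(names, list) or any(t not in _TYPES for t in names):
                report.add(kpath, "meta", f"invalid type specifier {val!r}")
        elif key == "pattern":
            try:
                re.compile(val)
            except (re.error, TypeError):
                report.add(kpath, "meta", f"invalid regular expression {val!r}")
        elif key in {"minLength", "maxLength"}:
            if not isinstance(val, int) or isinstance(val, bool) or val < 0:
                report.add(kpath, "meta", f"{key} must be a non-negative integer")
        elif key in {"minimum", "maximum"}:
            if not isinstance(val, (int, float)) or isinstance(val, bool):
                report.add(kpath, "meta", f"{key} must be a number")
        elif key == "required":
            if not isinstance(val, list) or not all(isinstance(x, str) for x in val):
                report.add(kpath, "meta", "required must be an array of strings")
        elif key == "enum":
            if not isinstance(val, list) or not val:
                report.add(kpath, "meta", "enum must be a non-empty array")
        elif key in {"properties", "patternProperties"}:
            if not isinstance(val, dict):
                report.add(kpath, "meta", f"{key} must be an object")
                continue
            for sub_key, sub in val.items():
                if key == "patternProperties":
                    try:
                        re.compile(sub_key)
                    except re.error:
                        report.add(f"{kpath}.{sub_key}", "meta", "invalid property pattern")
                _check(sub, f"{kpath}.{sub_key}", report)
        elif key in {"additionalProperties", "items"}:
            _check(val, kpath, report)
        elif key == "anyOf":
            if not isinstance(val, list) or not val:
                report.add(kpath, "meta", "anyOf must be a non-empty array")
                continue
            for i, sub in enumerate(val):
                _check(sub, f"{kpath}[{i}]", report)


def load_schema(path) -> dict:
    """Read a JSON Schema document from disk."""
    import json

    try:
        with open(path, "r", encoding="utf-8") as fh:
            schema = json.load(fh)
    except (OSError, ValueError) as exc:
        raise ConfigError(f"cannot read schema {path}: {exc}") from exc
    if not isinstance(schema, (dict, bool)):
        raise ConfigError(f"schema {path} is not a JSON object")
    return schema
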