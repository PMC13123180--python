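"""The YAML mapping layer: binding input table columns to record components.

A mapping file states, per entity, which column feeds each component
(``columns``), which components are fixed for the whole table
(``constants``), how missing values are standardized (``na_token`` +
``na_policy``), how ages are binned into age groups (``age_binning``) and
how numeric subject ids are derived (``id_policy``: pass a column through,
or assign 1, 2, 3... in first-appearance order of a unique-id column so
UUID-keyed exports gain compact numeric ids).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional, Union

import yaml

from .codebook import Codebook
from .errors import MappingError
from .records import (
    BIOSAMPLE_OPTIONAL,
    Record,
    make_record,
    record_fields,
    validate_record,
)

DEFAULT_NA_TOKEN = "NA"
DEFAULT_AGE_BIN_WIDTH = 10


@dataclass(frozen=True)
class RowIssue:
    """A per-row mapping or validation problem; processing continues past it."""

    row: int  # 1-based data-row number (header not counted)
    field: str
    message: str

    def __str__(self) -> str:
        return f"row {self.row}: {self.field}: {self.message}"


@dataclass
class IdPolicy:
    mode: str  # "sequential" | "passthrough"
    column: str


@dataclass
class AgeBinning:
    column: str
    width: int = DEFAULT_AGE_BIN_WIDTH


@dataclass
class MappingConfig:
    entity: str
    column_map: dict[str, str] = dc_field(default_factory=dict)
    constants: dict[str, str] = dc_field(default_factory=dict)
    na_token: str = DEFAULT_NA_TOKEN
    na_policy: dict[str, str] = dc_field(default_factory=dict)
    age_binning: Optional[AgeBinning] = None
    id_policy: Optional[IdPolicy] = None

    def required_columns(self) -> set[str]:
        cols = set(self.column_map.values())
        if self.age_binning:
            cols.add(self.age_binning.column)
        if self.id_policy:
            cols.add(self.id_policy.column)
        return cols

    def check(self, header: list[str]) -> None:
        """Validate the mapping against a table header and the entity grammar."""
        fields = record_fields(self.entity)
        covered = set(self.column_map) | set(self.constants)
        if self.age_binning and self.entity == "subject":
            covered.add("age_group")
        if self.id_policy:
            covered.add("subject_id")
        missing = [f for f in fields
                   if f not in covered and f not in BIOSAMPLE_OPTIONAL]
        if missing:
            raise MappingError(
                f"mapping covers no source for mandatory component(s): {', '.join(missing)}")
        unknown = [f for f in list(self.column_map) + list(self.constants)
                   if f not in fields]
        if unknown:
            raise MappingError(f"mapping names unknown component(s): {', '.join(unknown)}")
        absent = sorted(self.required_columns() - set(header))
        if absent:
            raise MappingError(f"input table lacks mapped column(s): {', '.join(absent)}")


def load_mapping(path: Union[str, Path]) -> MappingConfig:
    try:
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
    except OSError as exc:
        raise MappingError(f"cannot read mapping {path}: {exc}") from exc
    except yaml.YAMLError as exc:
        raise MappingError(f"mapping {path} is not valid YAML: {exc}") from exc
    return mapping_from_dict(doc, source=str(path))


def mapping_from_dict(doc: dict, source: str = "<dict>") -> MappingConfig:
    if not isinstance(doc, dict):
        raise MappingError(f"mapping {source} must be a YAML mapping")
    entity = doc.get("entity")
    if entity not in ("biosample", "subject"):
        raise MappingError(f"mapping {source}: entity must be 'biosample' or 'subject'")
    age = None
    if "age_binning" in doc and doc["age_binning"]:
        ab = doc["age_binning"]
        if not isinstance(ab, dict) or "column" not in ab:
            raise MappingError(f"mapping {source}: age_binning needs a 'column'")
        width = ab.get("width", DEFAULT_AGE_BIN_WIDTH)
        if not isinstance(width, int) or isinstance(width, bool) or width <= 0:
            raise MappingError(f"mapping {source}: age_binning width must be a positive integer")
        age = AgeBinning(column=str(ab["column"]), width=width)
    idp = None
    if "id_policy" in doc and doc["id_policy"]:
        ip = doc["id_policy"]
        mode = ip.get("mode") if isinstance(ip, dict) else None
        if mode not in ("sequential", "passthrough") or "column" not in ip:
            raise MappingError(
                f"mapping {source}: id_policy needs mode sequential|passthrough and a column")
        idp = IdPolicy(mode=mode, column=str(ip["column"]))
    return MappingConfig(
        entity=entity,
        column_map={str(k): str(v) for k, v in (doc.get("columns") or {}).items()},
        constants={str(k): str(v) for k, v in (doc.get("constants") or {}).items()},
        na_token=str(doc.get("na_token", DEFAULT_NA_TOKEN)),
        na_policy={str(k): str(v) for k, v in (doc.get("na_policy") or {}).items()},
        age_binning=age,
        id_policy=idp,
    )


def bin_age(age: int, width: int = DEFAULT_AGE_BIN_WIDTH) -> str:
    """Decade-style binning: age 43 at width 10 -> ``A40_49``."""
    lo = width * (age // width)
    return f"A{lo}_{lo + width - 1}"


def apply_mapping(
    rows: list[dict[str, str]],
    m: MappingConfig,
    cb: Codebook,
) -> tuple[list[Optional[Record]], list[RowIssue]]:
    """Turn input rows into records; failures are row-scoped, never global.

    Returns one entry per input row (a record, or None when that row
    failed) plus the collected issues.
    """
    if rows:
        m.check(sorted({k for k in rows[0]}))
    records: list[Optional[Record]] = []
    issues: list[RowIssue] = []
    seq_ids: dict[str, int] = {}

    for i, row in enumerate(rows, start=1):
        row_issues: list[RowIssue] = []
        comp: dict[str, str] = dict(m.constants)

        for fld, col in m.column_map.items():
            value = row.get(col, "")
            if value == m.na_token or value == "":
                if fld in m.na_policy:
                    value = m.na_policy[fld]
                elif fld in BIOSAMPLE_OPTIONAL:
                    continue  # optional component simply absent
                else:
                    row_issues.append(RowIssue(i, fld,
                        f"missing value in column {col!r} and no NA substitute configured"))
                    continue
            comp[fld] = value

        if m.age_binning is not None:
            raw = row.get(m.age_binning.column, "")
            if raw == m.na_token or raw == "":
                row_issues.append(RowIssue(i, "age_group",
                    f"missing age in column {m.age_binning.column!r}"))
            else:
                try:
                    comp["age_group"] = bin_age(int(raw), m.age_binning.width)
                except ValueError:
                    row_issues.append(RowIssue(i, "age_group",
                        f"age value {raw!r} is not an integer"))

        if m.id_policy is not None:
            key = row.get(m.id_policy.column, "")
            if key == m.na_token or key == "":
                row_issues.append(RowIssue(i, "subject_id",
                    f"missing id key in column {m.id_policy.column!r}"))
            elif m.id_policy.mode == "sequential":
                comp["subject_id"] = str(seq_ids.setdefault(key, len(seq_ids) + 1))
            else:
                if key.isdigit():
                    comp["subject_id"] = str(int(key))
                else:
                    row_issues.append(RowIssue(i, "subject_id",
                        f"passthrough id {key!r} is not numeric"))

        if row_issues:
            issues.extend(row_issues)
            records.append(None)
            continue

        try:
            rec = make_record(m.entity, comp)
        except (KeyError, ValueError) as exc:
            issues.append(RowIssue(i, "record", f"cannot assemble record: {exc!r}"))
            records.append(None)
            continue
        report = validate_record(rec, cb)
        if report.ok:
            records.append(rec)
        else:
            issues.extend(RowIssue(i, v.path, v.message) for v in report.violations)
            records.append(None)
    return records, issues


def bundled_mapping_path(entity: str) -> Path:
    from importlib import resources

    return Path(str(resources.files("clarid").joinpath(f"data/mapping_{entity}.yaml")))
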