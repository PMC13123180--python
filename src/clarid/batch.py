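"""Batch encode/decode of tables and codebook validation entry points.

These back the ``code`` and ``validate`` CLI subcommands but are plain
functions so pipelines can call them directly. Data goes to the output
table only; diagnostics go to logging (stderr), so outputs stay
byte-identical across runs on identical inputs.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

from .codebook import Codebook, load_codebook, validate_codebook
from .conditions import ConditionTable, load_conditions
from .errors import ClaridError, CodebookError
from .human import decode_human, encode_human
from .mapping import MappingConfig, apply_mapping, load_mapping
from .records import record_fields
from .report import ValidationReport
from .stub import decode_stub, encode_stub
from .tables import read_table, write_table

log = logging.getLogger("clarid")

#: cell marker written for rows that failed to encode/decode
FAILURE_MARKER = "!ERROR"
#: default name of the identifier column (encode output, decode input)
ID_COLUMN = "clarid"


def encode_table(
    rows: list[dict[str, str]],
    m: MappingConfig,
    cb: Codebook,
    fmt: str,
) -> tuple[list[dict[str, str]], int]:
    """Append an identifier column to every row; returns (rows, n_failed)."""
    encode = encode_human if fmt == "human" else encode_stub
    records, issues = apply_mapping(rows, m, cb)
    for issue in issues:
        log.error("%s", issue)
    out = []
    n_failed = 0
    for i, (row, rec) in enumerate(zip(rows, records), start=1):
        new = dict(row)
        if rec is None:
            new[ID_COLUMN] = FAILURE_MARKER
            n_failed += 1
        else:
            try:
                new[ID_COLUMN] = encode(rec, cb)
            except ClaridError as exc:
                log.error("row %d: %s", i, exc)
                new[ID_COLUMN] = FAILURE_MARKER
                n_failed += 1
        out.append(new)
    return out, n_failed


def decode_table(
    rows: list[dict[str, str]],
    entity: str,
    cb: Codebook,
    fmt: str,
    id_column: str = ID_COLUMN,
    conditions: Optional[ConditionTable] = None,
) -> tuple[list[dict[str, str]], list[str], int]:
    """Decode an identifier column into one column per component.

    Returns (rows, added column names, n_failed). When a condition table is
    given, a ``condition_name`` column is added as well (absent codes get
    the "NA" marker); without it the output schema is unchanged.
    """
    decode = decode_human if fmt == "human" else decode_stub
    components = list(record_fields(entity))
    added = components + (["condition_name"] if conditions is not None else [])
    out = []
    n_failed = 0
    for i, row in enumerate(rows, start=1):
        new = dict(row)
        ident = row.get(id_column, "")
        try:
            rec = decode(ident, entity, cb)
            d = rec.to_dict()
            for c in components:
                new[c] = d.get(c, "")
            if conditions is not None:
                new["condition_name"] = conditions.name_or_marker(rec.condition)
        except ClaridError as exc:
            log.error("row %d: cannot decode %r: %s", i, ident, exc)
            for c in added:
                new[c] = FAILURE_MARKER
            n_failed += 1
        out.append(new)
    return out, added, n_failed


def run_code(
    action: str,
    fmt: str,
    entity: str,
    input_path: Union[str, Path],
    codebook_path: Union[str, Path, None] = None,
    mapping_path: Union[str, Path, None] = None,
    with_condition_name: bool = False,
    output_path: Union[str, Path, None] = None,
    id_column: str = ID_COLUMN,
    conditions_path: Union[str, Path, None] = None,
) -> tuple[int, list[str], list[dict[str, str]]]:
    """File-level encode/decode; returns (exit status, fieldnames, rows).

    Exit status is nonzero iff any row failed; partial output is still
    produced with failure markers so a bad row never silently disappears.
    """
    if action not in ("encode", "decode"):
        raise ClaridError(f"unknown action {action!r}")
    if fmt not in ("human", "stub"):
        raise ClaridError(f"unknown format {fmt!r}")
    cb = load_codebook(codebook_path) if codebook_path else _bundled_codebook()
    header, rows = read_table(input_path)

    if action == "encode":
        if mapping_path is None:
            raise ClaridError("encoding a table requires a mapping file")
        m = load_mapping(mapping_path)
        if m.entity != entity:
            raise ClaridError(
                f"mapping is for entity {m.entity!r}, requested {entity!r}")
        out_rows, n_failed = encode_table(rows, m, cb, fmt)
        fieldnames = header + [ID_COLUMN]
    else:
        table = load_conditions(conditions_path) if with_condition_name else None
        out_rows, added, n_failed = decode_table(
            rows, entity, cb, fmt, id_column=id_column, conditions=table)
        fieldnames = header + [c for c in added if c not in header]

    if output_path is not None:
        write_table(output_path, fieldnames, out_rows)
    if n_failed:
        log.warning("%d of %d row(s) failed", n_failed, len(rows))
    return (1 if n_failed else 0), fieldnames, out_rows


def run_validate(
    codebook_path: Union[str, Path],
    schema_path: Union[str, Path, None] = None,
    debug: bool = False,
) -> tuple[int, ValidationReport]:
    """Validate a codebook file; returns (exit status, report).

    Unparseable codebooks are reported as a single violation rather than a
    crash so the CLI can print something actionable.
    """
    report = ValidationReport()
    try:
        cb = load_codebook(codebook_path)
    except CodebookError as exc:
        report.add(str(codebook_path), "load", str(exc))
        return 1, report
    report = validate_codebook(cb, schema=schema_path, debug=debug)
    return (0 if report.ok else 1), report


def _bundled_codebook() -> Codebook:
    from .codebook import bundled_codebook_path

    return load_codebook(bundled_codebook_path())
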