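"""CSV/TSV reading and writing with verbatim cell preservation.

The delimiter is inferred from the extension (``.csv`` comma with RFC-4180
quoting; ``.tsv``/``.txt`` tab with no quoting, tabs forbidden in cells).
Cells are never coerced: the literal ``NA`` token survives intact, which
the mapping layer depends on.
"""

from __future__ import annotations

import csv
import io
from pathlib import Path
from typing import Iterable, Optional, Sequence, TextIO, Union

from .errors import TableFormatError

Row = dict[str, str]


def delimiter_for(path: Union[str, Path]) -> str:
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return ","
    if suffix in (".tsv", ".txt"):
        return "\t"
    raise TableFormatError(f"cannot infer delimiter from extension {suffix!r} "
                           "(expected .csv, .tsv or .txt)")


def _reader(fh: TextIO, delimiter: str) -> csv.reader:
    if delimiter == "\t":
        return csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
    return csv.reader(fh, delimiter=delimiter)


def read_table(path: Union[str, Path], delimiter: Optional[str] = None) -> tuple[list[str], list[Row]]:
    """Read a delimited table; returns (header, rows as ordered key→string maps).

    Ragged rows raise :class:`TableFormatError` naming the offending line.
    """
    delimiter = delimiter or delimiter_for(path)
    with open(path, "r", encoding="utf-8", newline="") as fh:
        return parse_table(fh, delimiter)


def parse_table(fh: TextIO, delimiter: str) -> tuple[list[str], list[Row]]:
    reader = _reader(fh, delimiter)
    try:
        header = next(reader)
    except StopIteration:
        raise TableFormatError("table is empty: no header line") from None
    if not header or any(h == "" for h in header):
        raise TableFormatError("header line has empty column names")
    rows: list[Row] = []
    for cells in reader:
        if not cells:
            continue  # tolerate a trailing blank line
        if len(cells) != len(header):
            raise TableFormatError(
                f"line {reader.line_num}: expected {len(header)} cells, got {len(cells)}")
        rows.append(dict(zip(header, cells)))
    return header, rows


def write_table(path: Union[str, Path], fieldnames: Sequence[str],
                rows: Iterable[Row], delimiter: Optional[str] = None) -> None:
    delimiter = delimiter or delimiter_for(path)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        dump_table(fh, fieldnames, rows, delimiter)


def dump_table(fh: TextIO, fieldnames: Sequence[str], rows: Iterable[Row],
               delimiter: str) -> None:
    if delimiter == "\t":
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter="\t",
                                quoting=csv.QUOTE_NONE, quotechar=None,
                                lineterminator="\n", restval="")
    else:
        writer = csv.DictWriter(fh, fieldnames=fieldnames, delimiter=delimiter,
                                lineterminator="\n", restval="")
    writer.writeheader()
    for row in rows:
        if delimiter == "\t" and any("\t" in str(v) for v in row.values()):
            raise TableFormatError("cells may not contain tabs in TSV output")
        writer.writerow({k: row.get(k, "") for k in fieldnames})


def format_table(fieldnames: Sequence[str], rows: Iterable[Row],
                 delimiter: str = ",") -> str:
    buf = io.StringIO()
    dump_table(buf, fieldnames, rows, delimiter)
    return buf.getvalue()
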