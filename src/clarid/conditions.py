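"""ICD-10 condition lookup: code → human-readable condition name.

Conditions are deliberately kept out of the main codebook and handled
through a flat JSON table. The bundled table is a small curated subset
(the worked-example codes plus common diagnoses); supply a fuller table
via ``load_conditions(path)`` when needed.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional, Union

from .codebook import ICD10_RE
from .errors import ConfigError
from .report import ValidationReport

#: marker emitted when a code has no entry in the table
NOT_FOUND = "NA"


class ConditionTable:
    def __init__(self, entries: dict[str, str]):
        self.entries = dict(entries)

    def get(self, code: str) -> Optional[str]:
        """Condition name for a code, or None (an absent code is not an error)."""
        return self.entries.get(code)

    def name_or_marker(self, code: str) -> str:
        return self.entries.get(code, NOT_FOUND)

    def __contains__(self, code: str) -> bool:
        return code in self.entries

    def __len__(self) -> int:
        return len(self.entries)

    def validate(self) -> ValidationReport:
        report = ValidationReport()
        for code, name in self.entries.items():
            if not ICD10_RE.match(code):
                report.add(f"conditions.{code}", "pattern",
                           f"{code!r} is not a valid ICD-10 code")
            if not isinstance(name, str) or not name.strip():
                report.add(f"conditions.{code}", "empty", "condition name must be non-empty")
        return report


def bundled_conditions_path() -> Path:
    return Path(str(resources.files("clarid").joinpath("data/conditions.json")))


def load_conditions(path: Union[str, Path, None] = None) -> ConditionTable:
    """Load a JSON object of ICD-10 code → condition name.

    With no path, the bundled table is used.
    """
    p = Path(path) if path is not None else bundled_conditions_path()
    try:
        with open(p, "r", encoding="utf-8") as fh:
            doc = json.load(fh)
    except OSError as exc:
        raise ConfigError(f"cannot read condition table {p}: {exc}") from exc
    except ValueError as exc:
        raise ConfigError(f"condition table {p} is not valid JSON: {exc}") from exc
    if not isinstance(doc, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in doc.items()
    ):
        raise ConfigError(f"condition table {p} must be a flat JSON object of strings")
    return ConditionTable(doc)


def annotate(components: dict[str, str], table: ConditionTable) -> dict[str, str]:
    """Return a copy of a decoded component map with ``condition_name`` added.

    Existing fields are never altered; an absent code yields the "NA" marker.
    """
    out = dict(components)
    out["condition_name"] = table.name_or_marker(components.get("condition", ""))
    return out
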