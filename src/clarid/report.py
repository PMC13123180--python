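"""Validation reporting shared by codebook and record validation."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator


@dataclass(frozen=True)
class Violation:
    """One validation finding.

    path
        JSON-pointer-ish location into the offending document, e.g.
        ``biosample.tissue.LIV.stub_code``.
    kind
        Machine-readable category (``duplicate_stub``, ``width``,
        ``pattern``, ``schema``...).
    message
        Human-readable explanation.
    """

    path: str
    kind: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - repr convenience
        return f"[{self.kind}] {self.path}: {self.message}"


@dataclass
class ValidationReport:
    violations: list[Violation] = field(default_factory=list)

    def add(self, path: str, kind: str, message: str) -> None:
        self.violations.append(Violation(path, kind, message))

    def extend(self, other: "ValidationReport") -> None:
        self.violations.extend(other.violations)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:
        return self.ok

    def __len__(self) -> int:
        return len(self.violations)

    def __iter__(self) -> Iterator[Violation]:
        return iter(self.violations)

    def to_json_lines(self) -> str:
        """Serialize as JSON lines, one violation per line."""
        return "\n".join(
            json.dumps({"path": v.path, "kind": v.kind, "message": v.message})
            for v in self.violations
        )
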