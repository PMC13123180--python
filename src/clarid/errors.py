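"""Exception hierarchy.

Rule of thumb: malformed *inputs* raise (parse failures, unknown tokens,
structural problems in identifier strings); questionable *data* inside an
otherwise well-formed document is reported as violations in a
:class:`~clarid.report.ValidationReport` instead.
"""

from __future__ import annotations


class ClaridError(Exception):
    """Base class for every error raised by this package."""


class CodebookError(ClaridError):
    """The codebook document is unreadable or structurally invalid."""


class ConfigError(ClaridError):
    """A configuration input (schema, mapping file, CLI usage) is unusable."""


class VocabularyError(ClaridError, KeyError):
    """A token does not resolve in the codebook vocabulary.

    Carries the entity, field and offending token so that decode-time
    failures can be reported precisely.
    """

    def __init__(self, entity: str, field: str, token: str, kind: str = "code"):
        self.entity = entity
        self.field = field
        self.token = token
        self.kind = kind
        super().__init__(
            f"unknown {kind} {token!r} for {entity}.{field}"
        )


class StructuralError(ClaridError, ValueError):
    """An identifier string has the wrong shape (part count, length, grammar)."""


class DecodeError(ClaridError, ValueError):
    """An identifier component decodes to an invalid value."""


class EncodeError(ClaridError, ValueError):
    """A record failed validation at encode time; aggregates the violations."""

    def __init__(self, violations):
        self.violations = list(violations)
        msgs = "; ".join(str(v) for v in self.violations)
        super().__init__(f"record failed validation: {msgs}")


class Base62Error(ClaridError, ValueError):
    """Base62 overflow or foreign character."""


class MappingError(ConfigError):
    """A column-mapping configuration does not fit the input table."""


class TableFormatError(ClaridError, ValueError):
    """A CSV/TSV input is malformed (ragged row, missing header...)."""


class QRError(ClaridError):
    """Base class for QR generation/reading failures."""


class QRDetectionError(QRError):
    """No QR symbol could be located in the image."""


class QRAmbiguityError(QRError):
    """More than one QR symbol was located in the image."""
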