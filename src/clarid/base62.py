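"""Fixed-width Base62 integer codec.

The alphabet is ``0-9A-Za-z`` in that order, so numeric value increases
with ASCII code and the encoding of 1001 at width 3 is ``0G9``
(16*62 + 9 = 1001). Codes are left-padded with ``0``; overflow is an
error, never truncation.
"""

from __future__ import annotations

from .errors import Base62Error

ALPHABET = "0123456789ABCDEFGHIJKLMNOPQRSTUVWXYZabcdefghijklmnopqrstuvwxyz"
BASE = 62
_INDEX = {c: i for i, c in enumerate(ALPHABET)}


def base62_encode(n: int, width: int) -> str:
    """Encode ``n`` as a fixed-width Base62 string.

    Raises :class:`Base62Error` if ``n`` is negative or does not fit in
    ``width`` digits.
    """
    if width < 1:
        raise Base62Error(f"width must be positive, got {width}")
    if n < 0:
        raise Base62Error(f"cannot encode negative integer {n}")
    if n >= BASE**width:
        raise Base62Error(f"{n} does not fit in {width} Base62 digit(s) (max {BASE**width - 1})")
    digits = []
    m = n
    while m:
        m, r = divmod(m, BASE)
        digits.append(ALPHABET[r])
    return "".join(reversed(digits)).rjust(width, "0")


def base62_decode(s: str) -> int:
    """Decode a Base62 string (any width) to a non-negative integer."""
    if not s:
        raise Base62Error("empty Base62 string")
    n = 0
    for c in s:
        try:
            n = n * BASE + _INDEX[c]
        except KeyError:
            raise Base62Error(f"character {c!r} is not in the Base62 alphabet") from None
    return n


def is_base62(s: str) -> bool:
    return bool(s) and all(c in _INDEX for c in s)
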