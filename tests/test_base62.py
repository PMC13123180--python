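"""Fixed-width Base62 codec against an independent positional-number oracle."""

import pytest
from hypothesis import given, settings, strategies as st

from clarid.base62 import ALPHABET, base62_decode, base62_encode
from clarid.errors import Base62Error


def oracle_encode(n: int, width: int) -> str:
    """Independent oracle: index-table positional expansion, most significant
    digit computed first via integer powers (no shared code path)."""
    digits = []
    for k in range(width - 1, -1, -1):
        q = n // (62 ** k)
        digits.append(ALPHABET[q])
        n -= q * 62 ** k
    return "".join(digits)


def oracle_decode(s: str) -> int:
    return sum(ALPHABET.index(c) * 62 ** i for i, c in enumerate(reversed(s)))


@pytest.mark.parametrize(
    "n,width,expected",
    [
        (1001, 3, "0G9"),  # pins the alphabet: 16*62 + 9
        (0, 3, "000"),
        (61, 1, "z"),
        (62, 2, "10"),
        (3, 3, "003"),
        (238327, 3, "zzz"),
    ],
)
def test_known_encodings(n, width, expected):
    assert base62_encode(n, width) == expected
    assert base62_decode(expected) == n
    assert oracle_encode(n, width) == expected


@settings(derandomize=True, max_examples=300)
@given(st.integers(min_value=0, max_value=10**6 - 1))
def test_agrees_with_oracle_and_roundtrips(n):
    s = base62_encode(n, 4)
    assert s == oracle_encode(n, 4)
    assert base62_decode(s) == n == oracle_decode(s)


@pytest.mark.parametrize("n,width", [(62, 1), (62**3, 3), (-1, 3)])
def test_overflow_and_negative_rejected(n, width):
    with pytest.raises(Base62Error):
        base62_encode(n, width)


@pytest.mark.parametrize("s", ["", "0G-", "àbc", "1 2"])
def test_foreign_characters_rejected(s):
    with pytest.raises(Base62Error):
        base62_decode(s)
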