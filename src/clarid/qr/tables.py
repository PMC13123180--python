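"""Symbol constants for QR versions 1-10 (micro symbols not supported).

Block structure per (version, EC level): (parity codewords per block,
[(block count, data codewords per block), ...]). Identifiers are short, so
version 10 (213 bytes at level M) leaves ample headroom.
"""

from __future__ import annotations

MAX_VERSION = 10

#: error-correction level bit patterns in the format information
EC_BITS = {"L": 1, "M": 0, "Q": 3, "H": 2}

#: (version, level) -> (ec codewords per block, [(n_blocks, data cw per block), ...])
BLOCKS: dict[tuple[int, str], tuple[int, list[tuple[int, int]]]] = {
    (1, "L"): (7, [(1, 19)]),
    (1, "M"): (10, [(1, 16)]),
    (1, "Q"): (13, [(1, 13)]),
    (1, "H"): (17, [(1, 9)]),
    (2, "L"): (10, [(1, 34)]),
    (2, "M"): (16, [(1, 28)]),
    (2, "Q"): (22, [(1, 22)]),
    (2, "H"): (28, [(1, 16)]),
    (3, "L"): (15, [(1, 55)]),
    (3, "M"): (26, [(1, 44)]),
    (3, "Q"): (18, [(2, 17)]),
    (3, "H"): (22, [(2, 13)]),
    (4, "L"): (20, [(1, 80)]),
    (4, "M"): (18, [(2, 32)]),
    (4, "Q"): (26, [(2, 24)]),
    (4, "H"): (16, [(4, 9)]),
    (5, "L"): (26, [(1, 108)]),
    (5, "M"): (24, [(2, 43)]),
    (5, "Q"): (18, [(2, 15), (2, 16)]),
    (5, "H"): (22, [(2, 11), (2, 12)]),
    (6, "L"): (18, [(2, 68)]),
    (6, "M"): (16, [(4, 27)]),
    (6, "Q"): (24, [(4, 19)]),
    (6, "H"): (28, [(4, 15)]),
    (7, "L"): (20, [(2, 78)]),
    (7, "M"): (18, [(4, 31)]),
    (7, "Q"): (18, [(2, 14), (4, 15)]),
    (7, "H"): (26, [(4, 13), (1, 14)]),
    (8, "L"): (24, [(2, 97)]),
    (8, "M"): (22, [(2, 38), (2, 39)]),
    (8, "Q"): (22, [(4, 18), (2, 19)]),
    (8, "H"): (26, [(4, 14), (2, 15)]),
    (9, "L"): (30, [(2, 116)]),
    (9, "M"): (22, [(3, 36), (2, 37)]),
    (9, "Q"): (20, [(4, 16), (4, 17)]),
    (9, "H"): (24, [(4, 12), (4, 13)]),
    (10, "L"): (18, [(2, 68), (2, 69)]),
    (10, "M"): (26, [(4, 43), (1, 44)]),
    (10, "Q"): (24, [(6, 19), (2, 20)]),
    (10, "H"): (28, [(6, 15), (2, 16)]),
}

#: alignment pattern centre coordinates per version
ALIGNMENT = {
    1: [],
    2: [6, 18],
    3: [6, 22],
    4: [6, 26],
    5: [6, 30],
    6: [6, 34],
    7: [6, 22, 38],
    8: [6, 24, 42],
    9: [6, 26, 46],
    10: [6, 28, 50],
}


def size_of(version: int) -> int:
    return 17 + 4 * version


def data_codewords(version: int, level: str) -> int:
    _, blocks = BLOCKS[(version, level)]
    return sum(n * k for n, k in blocks)


def total_codewords(version: int, level: str) -> int:
    ec, blocks = BLOCKS[(version, level)]
    return data_codewords(version, level) + ec * sum(n for n, _ in blocks)


def char_count_bits(version: int) -> int:
    """Byte-mode character-count indicator width."""
    return 8 if version <= 9 else 16


def byte_capacity(version: int, level: str) -> int:
    """Maximum byte-mode payload length."""
    bits = data_codewords(version, level) * 8 - 4 - char_count_bits(version)
    return bits // 8


def pick_version(payload_len: int, level: str) -> int:
    for v in range(1, MAX_VERSION + 1):
        if byte_capacity(v, level) >= payload_len:
            return v
    raise ValueError(
        f"payload of {payload_len} bytes exceeds the {byte_capacity(MAX_VERSION, level)}-byte "
        f"capacity of version {MAX_VERSION} at level {level}")


# -- BCH codes for format / version information -------------------------

_G15 = 0b10100110111
_G18 = 0b1111100100101
_FMT_MASK = 0b101010000010010


def _bch_remainder(value: int, gen: int) -> int:
    glen = gen.bit_length()
    v = value
    while v.bit_length() >= glen:
        v ^= gen << (v.bit_length() - glen)
    return v


def format_bits(level: str, mask: int) -> int:
    data = (EC_BITS[level] << 3) | mask
    return ((data << 10) | _bch_remainder(data << 10, _G15)) ^ _FMT_MASK


def version_bits(version: int) -> int:
    return (version << 12) | _bch_remainder(version << 12, _G18)


#: all 32 valid format codewords, for nearest-codeword decoding
FORMAT_CODEWORDS = {
    format_bits(level, mask): (level, mask)
    for level in EC_BITS
    for mask in range(8)
}
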