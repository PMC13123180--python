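"""QR symbol generation (byte mode, versions 1-10).

The pipeline: UTF-8 payload → byte-mode bit stream (mode 0100, character
count, terminator, pad bytes 0xEC/0x11) → per-block Reed-Solomon parity →
codeword interleaving → module placement under each of the eight masks →
the mask with the lowest penalty wins, its format (and, from version 7,
version) information is written, and the matrix is rendered to PNG with a
quiet zone.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from PIL import Image

from .gf import rs_encode
from .matrix import (
    MASKS,
    data_coords,
    empty_matrix,
    format_positions,
    penalty,
    place_function_patterns,
    reserve_map,
    version_positions,
)
from .tables import (
    BLOCKS,
    char_count_bits,
    data_codewords,
    format_bits,
    pick_version,
    size_of,
    version_bits,
)

_PAD = (0xEC, 0x11)
QUIET_ZONE = 4


def _bitstream(payload: bytes, version: int, level: str) -> list[int]:
    """Byte-mode data codewords, padded to the version's full capacity."""
    bits: list[int] = []

    def push(value: int, width: int) -> None:
        bits.extend((value >> (width - 1 - k)) & 1 for k in range(width))

    push(0b0100, 4)
    push(len(payload), char_count_bits(version))
    for b in payload:
        push(b, 8)
    capacity = data_codewords(version, level) * 8
    push(0, min(4, capacity - len(bits)))  # terminator
    if len(bits) % 8:
        push(0, 8 - len(bits) % 8)
    codewords = [
        sum(bit << (7 - k) for k, bit in enumerate(bits[i:i + 8]))
        for i in range(0, len(bits), 8)
    ]
    i = 0
    while len(codewords) < capacity // 8:
        codewords.append(_PAD[i % 2])
        i += 1
    return codewords


def _interleave(codewords: list[int], version: int, level: str) -> list[int]:
    nsym, groups = BLOCKS[(version, level)]
    blocks: list[list[int]] = []
    pos = 0
    for count, k in groups:
        for _ in range(count):
            blocks.append(codewords[pos:pos + k])
            pos += k
    parities = [rs_encode(block, nsym) for block in blocks]
    out: list[int] = []
    for i in range(max(len(b) for b in blocks)):
        out.extend(b[i] for b in blocks if i < len(b))
    for i in range(nsym):
        out.extend(p[i] for p in parities)
    return out


def _write_format(m: list[list[int]], level: str, mask: int) -> None:
    bits = format_bits(level, mask)
    for i, (v, h) in enumerate(format_positions(len(m))):
        bit = (bits >> i) & 1
        m[v[0]][v[1]] = bit
        m[h[0]][h[1]] = bit


def _write_version(m: list[list[int]], version: int) -> None:
    bits = version_bits(version)
    for i, (a, b) in enumerate(version_positions(len(m))):
        bit = (bits >> i) & 1
        m[a[0]][a[1]] = bit
        m[b[0]][b[1]] = bit


def build_matrix(payload: bytes, level: str = "M") -> list[list[int]]:
    """Construct the module matrix (1=dark) for a byte-mode payload."""
    version = pick_version(len(payload), level)
    final = _interleave(_bitstream(payload, version, level), version, level)
    coords = data_coords(version)
    bits = []
    for cw in final:
        bits.extend((cw >> (7 - k)) & 1 for k in range(8))
    bits.extend([0] * (len(coords) - len(bits)))  # remainder bits

    best = None
    best_score = None
    reserved = reserve_map(version)
    n = size_of(version)
    for mask_id, mask_fn in enumerate(MASKS):
        m = empty_matrix(version)
        place_function_patterns(m, version)
        for (r, c), bit in zip(coords, bits):
            m[r][c] = bit ^ (1 if mask_fn(r, c) else 0)
        _write_format(m, level, mask_id)
        if version >= 7:
            _write_version(m, version)
        for r in range(n):  # any still-unset reserved cells default light
            for c in range(n):
                if m[r][c] is None:
                    m[r][c] = 0
        assert all(m[r][c] is not None or reserved[r][c] for r in range(n) for c in range(n))
        score = penalty(m)
        if best_score is None or score < best_score:
            best, best_score = m, score
    return best


def render(matrix: list[list[int]], scale: int = 8,
           quiet_zone: int = QUIET_ZONE) -> Image.Image:
    n = len(matrix)
    side = (n + 2 * quiet_zone) * scale
    img = Image.new("L", (side, side), 255)
    px = img.load()
    for r in range(n):
        for c in range(n):
            if matrix[r][c]:
                x0 = (c + quiet_zone) * scale
                y0 = (r + quiet_zone) * scale
                for dy in range(scale):
                    for dx in range(scale):
                        px[x0 + dx, y0 + dy] = 0
    return img


def generate(text: str, path: Union[str, Path], scale: int = 8,
             level: str = "M") -> Path:
    """Encode ``text`` (UTF-8, byte mode) and write a PNG to ``path``."""
    matrix = build_matrix(text.encode("utf-8"), level=level)
    img = render(matrix, scale=scale)
    path = Path(path)
    img.save(path, format="PNG")
    return path
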