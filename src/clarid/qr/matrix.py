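"""Symbol matrix construction shared by the QR encoder and decoder.

Keeping the coordinate bookkeeping (function patterns, format/version bit
placement, zigzag data traversal, mask predicates) in one module guarantees
the reader samples exactly where the writer wrote.
"""

from __future__ import annotations

from .tables import ALIGNMENT, size_of

MASKS = [
    lambda i, j: (i + j) % 2 == 0,
    lambda i, j: i % 2 == 0,
    lambda i, j: j % 3 == 0,
    lambda i, j: (i + j) % 3 == 0,
    lambda i, j: (i // 2 + j // 3) % 2 == 0,
    lambda i, j: (i * j) % 2 + (i * j) % 3 == 0,
    lambda i, j: ((i * j) % 2 + (i * j) % 3) % 2 == 0,
    lambda i, j: ((i * j) % 3 + (i + j) % 2) % 2 == 0,
]


def empty_matrix(version: int) -> list[list]:
    n = size_of(version)
    return [[None] * n for _ in range(n)]


def place_function_patterns(m: list[list], version: int) -> None:
    """Finders, separators, timing, alignment and the dark module.

    Format/version areas stay None here; :func:`reserve_map` marks them as
    non-data so the zigzag skips them either way.
    """
    n = len(m)
    for r0, c0 in ((0, 0), (0, n - 7), (n - 7, 0)):
        for dr in range(-1, 8):
            for dc in range(-1, 8):
                r, c = r0 + dr, c0 + dc
                if not (0 <= r < n and 0 <= c < n):
                    continue
                in_outer = 0 <= dr <= 6 and 0 <= dc <= 6
                on_ring = dr in (0, 6) or dc in (0, 6)
                in_core = 2 <= dr <= 4 and 2 <= dc <= 4
                m[r][c] = 1 if in_outer and (on_ring or in_core) else 0
    for k in range(8, n - 8):
        m[6][k] = m[k][6] = 1 if k % 2 == 0 else 0
    centers = ALIGNMENT[version]
    for rc in centers:
        for cc in centers:
            # skip alignment patterns overlapping a finder corner
            if (rc < 9 and cc < 9) or (rc < 9 and cc > n - 10) or (rc > n - 10 and cc < 9):
                continue
            for dr in range(-2, 3):
                for dc in range(-2, 3):
                    ring = max(abs(dr), abs(dc))
                    m[rc + dr][cc + dc] = 1 if ring != 1 else 0
    m[n - 8][8] = 1  # dark module


def format_positions(n: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """For format bit i (i=0 least significant): (vertical, horizontal) cells."""
    out = []
    for i in range(15):
        if i < 6:
            v = (i, 8)
        elif i < 8:
            v = (i + 1, 8)
        else:
            v = (n - 15 + i, 8)
        if i < 8:
            h = (8, n - 1 - i)
        elif i < 9:
            h = (8, 15 - i - 1 + 1)
        else:
            h = (8, 15 - i - 1)
        out.append((v, h))
    return out


def version_positions(n: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """For version bit i (least significant first): its two mirrored cells."""
    out = []
    for i in range(18):
        a = (i // 3, i % 3 + n - 11)
        out.append((a, (a[1], a[0])))
    return out


def reserve_map(version: int) -> list[list[bool]]:
    """True where a module is function/reserved (not data)."""
    n = size_of(version)
    m = empty_matrix(version)
    place_function_patterns(m, version)
    reserved = [[m[r][c] is not None for c in range(n)] for r in range(n)]
    for v, h in format_positions(n):
        reserved[v[0]][v[1]] = True
        reserved[h[0]][h[1]] = True
    if version >= 7:
        for a, b in version_positions(n):
            reserved[a[0]][a[1]] = True
            reserved[b[0]][b[1]] = True
    return reserved


def data_coords(version: int) -> list[tuple[int, int]]:
    """Module coordinates in codeword placement order (the upward/downward
    two-column zigzag, skipping the vertical timing column)."""
    n = size_of(version)
    reserved = reserve_map(version)
    coords = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for r in rows:
            for c in (col, col - 1):
                if not reserved[r][c]:
                    coords.append((r, c))
        upward = not upward
        col -= 2
    return coords


def penalty(m: list[list[int]]) -> int:
    """Standard four-rule mask evaluation score (lower is better)."""
    n = len(m)
    score = 0
    # rule 1: runs of >=5 same-coloured modules, rows and columns
    for grid in (m, list(zip(*m))):
        for line in grid:
            run = 1
            for k in range(1, n):
                if line[k] == line[k - 1]:
                    run += 1
                else:
                    if run >= 5:
                        score += 3 + (run - 5)
                    run = 1
            if run >= 5:
                score += 3 + (run - 5)
    # rule 2: 2x2 blocks of one colour
    for r in range(n - 1):
        for c in range(n - 1):
            if m[r][c] == m[r][c + 1] == m[r + 1][c] == m[r + 1][c + 1]:
                score += 3
    # rule 3: finder-like 1:1:3:1:1 pattern with 4-module light flank
    pat1 = [1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0]
    pat2 = pat1[::-1]
    for grid in (m, [list(col) for col in zip(*m)]):
        for line in grid:
            for k in range(n - 10):
                window = line[k:k + 11]
                if window == pat1 or window == pat2:
                    score += 40
    # rule 4: dark-module proportion
    dark = sum(sum(row) for row in m)
    ratio = dark * 100 // (n * n)
    score += 10 * (abs(ratio - 50) // 5)
    return score
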