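"""Read back QR labels produced by :mod:`clarid.qr.encode`.

The reader targets clean, upright label images (screen renders, printed
labels scanned square-on): it locates the three finder patterns by their
1:1:3:1:1 run signature, derives the module grid from their centres,
samples the matrix, validates the format information against the 32 legal
codewords and Reed-Solomon-corrects each block. Rotated or perspective-
distorted photographs are out of scope.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

import numpy as np
from PIL import Image

from ..errors import QRAmbiguityError, QRDetectionError, QRError
from .gf import RSError, rs_decode
from .matrix import MASKS, data_coords, format_positions
from .tables import BLOCKS, FORMAT_CODEWORDS, MAX_VERSION, char_count_bits, total_codewords


def _binarize(path: Union[str, Path]) -> np.ndarray:
    try:
        img = Image.open(path).convert("L")
    except (OSError, ValueError) as exc:
        raise QRDetectionError(f"cannot open image {path}: {exc}") from exc
    arr = np.asarray(img, dtype=np.int16)
    lo, hi = int(arr.min()), int(arr.max())
    if hi - lo < 32:
        raise QRDetectionError("image has no contrast; no QR symbol found")
    return arr < (lo + hi) / 2  # True = dark


def _finder_candidates(dark: np.ndarray) -> list[tuple[float, float, float]]:
    """(x, y, module_size) for every row-wise 1:1:3:1:1 signature that also
    verifies vertically."""
    h, w = dark.shape
    out = []
    for y in range(h):
        row = dark[y]
        # run-length encode the row
        edges = np.flatnonzero(np.diff(row.astype(np.int8)))
        starts = np.concatenate(([0], edges + 1))
        lengths = np.diff(np.concatenate((starts, [w])))
        values = row[starts]
        for k in range(len(starts) - 4):
            if not values[k]:
                continue
            runs = lengths[k:k + 5]
            if not _ratio_ok(runs):
                continue
            total = int(runs.sum())
            cx = starts[k] + total / 2.0
            module = total / 7.0
            cy = _vertical_check(dark, int(round(cx)), y, module)
            if cy is not None:
                out.append((cx, cy, module))
    return out


def _ratio_ok(runs) -> bool:
    module = runs.sum() / 7.0
    if module < 1:
        return False
    expect = (1, 1, 3, 1, 1)
    return all(abs(r - e * module) <= max(1.0, 0.75 * module * (1 if e == 1 else 1.5))
               for r, e in zip(runs, expect))


def _vertical_check(dark: np.ndarray, x: int, y: int, module: float):
    """Demand the full dark:light:dark:light:dark 1:1:3:1:1 signature in the
    column through (x, y); returns the refined centre y, or None."""
    h = dark.shape[0]
    if not (0 <= x < dark.shape[1]) or not dark[y, x]:
        return None
    col = dark[:, x]
    runs = []  # (start, length, value) for the 5 runs centred on y's run
    # find the run containing y
    s = y
    while s > 0 and col[s - 1] == col[y]:
        s -= 1
    e = y
    while e + 1 < h and col[e + 1] == col[y]:
        e += 1
    runs.append((s, e - s + 1))
    # two runs above and two below
    bounds = [s, e]
    for _ in range(2):
        s2 = bounds[0] - 1
        if s2 < 0:
            return None
        s = s2
        while s > 0 and col[s - 1] == col[s2]:
            s -= 1
        runs.insert(0, (s, s2 - s + 1))
        bounds[0] = s
        e2 = bounds[1] + 1
        if e2 >= h:
            return None
        e = e2
        while e + 1 < h and col[e + 1] == col[e2]:
            e += 1
        runs.append((e2, e - e2 + 1))
        bounds[1] = e
    lengths = np.array([r[1] for r in runs])
    if not _ratio_ok(lengths):
        return None
    return runs[0][0] + lengths.sum() / 2.0


def _cluster(cands: list[tuple[float, float, float]]) -> list[tuple[float, float, float]]:
    """Group candidate centres lying within ~2 modules of each other; each
    cluster is summarized by its medians, which shrugs off stray matches
    adjacent to a true finder."""
    clusters: list[list[tuple[float, float, float]]] = []
    for c in cands:
        for cl in clusters:
            x0 = _median([p[0] for p in cl])
            y0 = _median([p[1] for p in cl])
            m0 = _median([p[2] for p in cl])
            if abs(c[0] - x0) <= 2.0 * m0 and abs(c[1] - y0) <= 2.0 * m0:
                cl.append(c)
                break
        else:
            clusters.append([c])
    return [
        (_median([p[0] for p in cl]), _median([p[1] for p in cl]),
         _median([p[2] for p in cl]))
        for cl in clusters
    ]


def _median(vals: list[float]) -> float:
    vs = sorted(vals)
    k = len(vs)
    return vs[k // 2] if k % 2 else (vs[k // 2 - 1] + vs[k // 2]) / 2.0


def _as_corners(triple):
    """Order a candidate triple as (top-left, top-right, bottom-left), or
    None when its geometry is not an upright finder constellation."""
    tl = min(triple, key=lambda c: c[0] + c[1])
    rest = [c for c in triple if c is not tl]
    tr = max(rest, key=lambda c: c[0] - c[1])
    bl = min(rest, key=lambda c: c[0] - c[1])
    if tr is bl:
        return None
    module = (tl[2] + tr[2] + bl[2]) / 3.0
    # equal module estimates
    if any(abs(c[2] - module) > 0.25 * module for c in triple):
        return None
    # axis alignment: tr level with tl, bl plumb with tl
    if abs(tr[1] - tl[1]) > module or abs(bl[0] - tl[0]) > module:
        return None
    span_x = tr[0] - tl[0]
    span_y = bl[1] - tl[1]
    # square symbol with at least version-1 extent (14 modules between centres)
    if span_x < 10 * module or span_y < 10 * module:
        return None
    if abs(span_x - span_y) > 2 * module:
        return None
    return tl, tr, bl


def select_symbol(centers):
    """Pick the unique geometrically consistent finder triple.

    Disjoint consistent triples mean several symbols (ambiguity); none
    means no symbol.
    """
    from itertools import combinations

    triples = [t for t in
               (_as_corners(tr) for tr in combinations(centers, 3))
               if t is not None]
    if not triples:
        raise QRDetectionError(
            f"found {len(centers)} finder pattern candidate(s) but no "
            "geometrically consistent QR symbol")
    if len(triples) > 1:
        ids = [set(map(id, t)) for t in triples]
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                if not ids[i] & ids[j]:
                    raise QRAmbiguityError(
                        "more than one QR symbol detected in the image")
        # overlapping alternatives: keep the tightest module agreement
        triples.sort(key=lambda t: max(c[2] for c in t) - min(c[2] for c in t))
    return triples[0]


def _sample_matrix(dark: np.ndarray, corners) -> list[list[int]]:
    tl, tr, bl = corners
    module = (tl[2] + tr[2] + bl[2]) / 3.0
    span_x = tr[0] - tl[0]
    span_y = bl[1] - tl[1]
    n_est = (span_x / module + span_y / module) / 2.0 + 7
    version = int(round((n_est - 17) / 4))
    if not 1 <= version <= MAX_VERSION:
        raise QRDetectionError(f"implied symbol version {version} out of range")
    n = 17 + 4 * version
    sx = span_x / (n - 7)
    sy = span_y / (n - 7)
    x0 = tl[0] - 3.5 * sx
    y0 = tl[1] - 3.5 * sy
    h, w = dark.shape
    m = []
    for r in range(n):
        row = []
        for c in range(n):
            x = int(round(x0 + (c + 0.5) * sx))
            y = int(round(y0 + (r + 0.5) * sy))
            if not (0 <= x < w and 0 <= y < h):
                raise QRDetectionError("module grid extends outside the image")
            row.append(1 if dark[y, x] else 0)
        m.append(row)
    return m


def _read_format(m: list[list[int]]) -> tuple[str, int]:
    n = len(m)
    positions = format_positions(n)
    for which in (0, 1):
        raw = 0
        for i, pair in enumerate(positions):
            r, c = pair[which]
            raw |= (m[r][c] & 1) << i
        best = min(FORMAT_CODEWORDS, key=lambda cw: bin(cw ^ raw).count("1"))
        if bin(best ^ raw).count("1") <= 3:
            return FORMAT_CODEWORDS[best]
    raise QRError("format information unreadable in both copies")


def decode_matrix(m: list[list[int]]) -> bytes:
    n = len(m)
    version = (n - 17) // 4
    level, mask_id = _read_format(m)
    mask_fn = MASKS[mask_id]
    bits = [m[r][c] ^ (1 if mask_fn(r, c) else 0) for r, c in data_coords(version)]
    ncw = total_codewords(version, level)
    codewords = [
        sum(bit << (7 - k) for k, bit in enumerate(bits[i * 8:i * 8 + 8]))
        for i in range(ncw)
    ]
    data = _deinterleave_and_correct(codewords, version, level)
    return _parse_bitstream(data, version)


def _deinterleave_and_correct(codewords: list[int], version: int, level: str) -> list[int]:
    nsym, groups = BLOCKS[(version, level)]
    lens = [k for count, k in groups for _ in range(count)]
    nblocks = len(lens)
    data_blocks: list[list[int]] = [[] for _ in range(nblocks)]
    idx = 0
    for i in range(max(lens)):
        for b in range(nblocks):
            if i < lens[b]:
                data_blocks[b].append(codewords[idx])
                idx += 1
    par_blocks: list[list[int]] = [[] for _ in range(nblocks)]
    for _ in range(nsym):
        for b in range(nblocks):
            par_blocks[b].append(codewords[idx])
            idx += 1
    out: list[int] = []
    for b in range(nblocks):
        try:
            corrected = rs_decode(data_blocks[b] + par_blocks[b], nsym)
        except RSError as exc:
            raise QRError(f"block {b}: {exc}") from exc
        out.extend(corrected[:lens[b]])
    return out


def _parse_bitstream(data: list[int], version: int) -> bytes:
    bits = []
    for cw in data:
        bits.extend((cw >> (7 - k)) & 1 for k in range(8))
    pos = 0

    def take(width: int) -> int:
        nonlocal pos
        v = 0
        for _ in range(width):
            v = (v << 1) | bits[pos]
            pos += 1
        return v

    mode = take(4)
    if mode != 0b0100:
        raise QRError(f"unsupported mode indicator {mode:04b} (only byte mode)")
    count = take(char_count_bits(version))
    if count * 8 > len(bits) - pos:
        raise QRError("declared payload length exceeds the data stream")
    return bytes(take(8) for _ in range(count))


def read(path: Union[str, Path]) -> str:
    """Locate and decode the single QR symbol in a PNG; returns its payload."""
    dark = _binarize(path)
    centers = _cluster(_finder_candidates(dark))
    if len(centers) < 3:
        raise QRDetectionError(
            f"found {len(centers)} finder pattern(s); no complete QR symbol in the image")
    corners = select_symbol(centers)
    return decode_matrix(_sample_matrix(dark, corners)).decode("utf-8")
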