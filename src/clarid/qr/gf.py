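"""GF(256) arithmetic and Reed-Solomon coding for QR symbols.

Field: GF(2^8) with primitive polynomial x^8+x^4+x^3+x^2+1 (0x11d),
generator element 2. The RS code uses consecutive roots starting at
alpha^0, as QR requires. Polynomials are lists of ints, highest-degree
coefficient first.
"""

from __future__ import annotations

_EXP = [0] * 512
_LOG = [0] * 256
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


class RSError(ValueError):
    """Uncorrectable Reed-Solomon block."""


def gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return _EXP[_LOG[a] + _LOG[b]]


def gf_div(a: int, b: int) -> int:
    if b == 0:
        raise ZeroDivisionError
    if a == 0:
        return 0
    return _EXP[(_LOG[a] - _LOG[b]) % 255]


def gf_pow(a: int, n: int) -> int:
    if a == 0:
        return 0
    return _EXP[(_LOG[a] * n) % 255]


def gf_inv(a: int) -> int:
    return _EXP[255 - _LOG[a]]


def poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        if a == 0:
            continue
        for j, b in enumerate(q):
            out[i + j] ^= gf_mul(a, b)
    return out


def poly_add(p: list[int], q: list[int]) -> list[int]:
    out = [0] * max(len(p), len(q))
    out[len(out) - len(p):] = p[:]
    for i, b in enumerate(q):
        out[len(out) - len(q) + i] ^= b
    return out


def poly_scale(p: list[int], s: int) -> list[int]:
    return [gf_mul(c, s) for c in p]


def poly_eval(p: list[int], x: int) -> int:
    y = 0
    for c in p:
        y = gf_mul(y, x) ^ c
    return y


def rs_generator(nsym: int) -> list[int]:
    g = [1]
    for i in range(nsym):
        g = poly_mul(g, [1, gf_pow(2, i)])
    return g


def rs_encode(data: list[int], nsym: int) -> list[int]:
    """Return the ``nsym`` parity codewords for ``data``."""
    gen = rs_generator(nsym)
    rem = list(data) + [0] * nsym
    for i in range(len(data)):
        coef = rem[i]
        if coef == 0:
            continue
        for j in range(1, len(gen)):
            rem[i + j] ^= gf_mul(gen[j], coef)
    return rem[-nsym:]


def _syndromes(msg: list[int], nsym: int) -> list[int]:
    return [poly_eval(msg, gf_pow(2, i)) for i in range(nsym)]


def rs_decode(msg: list[int], nsym: int) -> list[int]:
    """Correct up to nsym//2 codeword errors in-place semantics; returns the
    corrected message (data + parity). Raises :class:`RSError` when the
    block is uncorrectable."""
    synd = _syndromes(msg, nsym)
    if max(synd) == 0:
        return list(msg)
    # Berlekamp-Massey for the error locator polynomial
    err_loc = [1]
    old_loc = [1]
    for i in range(nsym):
        old_loc.append(0)
        delta = synd[i]
        for j in range(1, len(err_loc)):
            delta ^= gf_mul(err_loc[-(j + 1)], synd[i - j])
        if delta != 0:
            if len(old_loc) > len(err_loc):
                new_loc = poly_scale(old_loc, delta)
                old_loc = poly_scale(err_loc, gf_inv(delta))
                err_loc = new_loc
            err_loc = poly_add(err_loc, poly_scale(old_loc, delta))
    while err_loc and err_loc[0] == 0:
        err_loc.pop(0)
    n_err = len(err_loc) - 1
    if n_err * 2 > nsym:
        raise RSError(f"too many errors ({n_err}) for {nsym} parity codewords")
    # Chien search: roots of the locator give error positions
    err_pos = []
    n = len(msg)
    for i in range(n):
        if poly_eval(err_loc, gf_pow(2, 255 - i)) == 0:
            # x = alpha^{-i} is a root <=> error at coefficient degree i
            err_pos.append(n - 1 - i)
    if len(err_pos) != n_err:
        raise RSError("error locator degree does not match its root count")
    # Forney: error magnitudes from the evaluator polynomial
    out = list(msg)
    synd_poly = list(reversed(synd))  # highest degree first
    omega = poly_mul(synd_poly, err_loc)
    omega = omega[-nsym:] if len(omega) > nsym else omega  # mod x^nsym
    # formal derivative of the locator (highest degree first)
    deg = len(err_loc) - 1
    deriv = [c if (deg - k) % 2 == 1 else 0 for k, c in enumerate(err_loc)]
    deriv = deriv[:-1] if len(deriv) > 1 else [0]
    for pos in err_pos:
        x = gf_pow(2, n - 1 - pos)  # X_j
        xinv = gf_inv(x)
        denom = poly_eval(deriv, xinv)
        if denom == 0:
            raise RSError("Forney denominator vanished")
        magnitude = gf_mul(x, gf_div(poly_eval(omega, xinv), denom))
        out[pos] ^= magnitude
    if max(_syndromes(out, nsym)) != 0:
        raise RSError("correction failed to zero the syndromes")
    return out
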