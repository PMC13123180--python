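"""QR-code labels for identifiers: generation and read-back.

Both renderings fit comfortably in small byte-mode symbols; labels default
to error-correction level M for print robustness.
"""

from __future__ import annotations

from pathlib import Path
from typing import Union

from ..errors import QRError
from .encode import build_matrix, generate, render
from .decode import decode_matrix, read


def qr_generate(identifier: str, output: Union[str, Path],
                scale: int = 8, level: str = "M") -> Path:
    """Write a PNG QR label whose payload is ``identifier`` byte-for-byte."""
    if not identifier:
        raise QRError("cannot generate a QR label for an empty identifier")
    return generate(identifier, output, scale=scale, level=level)


def qr_read(image: Union[str, Path]) -> str:
    """Decode the single QR symbol in ``image`` back to its identifier."""
    return read(image)


__all__ = ["qr_generate", "qr_read", "build_matrix", "decode_matrix",
           "generate", "render", "read"]
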