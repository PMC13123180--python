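"""QR label generation and read-back."""

import random

import pytest
from PIL import Image

from clarid.errors import QRAmbiguityError, QRDetectionError, QRError
from clarid.qr import build_matrix, decode_matrix, qr_generate, qr_read
from clarid.qr.gf import RSError, rs_decode, rs_encode
from clarid.qr.tables import format_bits


@pytest.mark.parametrize("payload", [
    "CT01001LTR0N401T1W",
    "CNAG_Test-HomSap-00001-LIV-TUM-RNA-C22.0-TRT-P1W",
    "TCGA-LIHC003C0N401MA4",
    "x",
    "µ-labels are UTF-8",
    "A" * 213,  # full version-10/M capacity
])
def test_image_round_trip(tmp_path, payload):
    p = qr_generate(payload, tmp_path / "label.png")
    assert qr_read(p) == payload


def test_empty_identifier_is_precondition_error(tmp_path):
    with pytest.raises(QRError):
        qr_generate("", tmp_path / "x.png")


def test_blank_image_is_detection_error(tmp_path):
    p = tmp_path / "blank.png"
    Image.new("L", (120, 120), 255).save(p)
    with pytest.raises(QRDetectionError):
        qr_read(p)


def test_two_symbols_is_ambiguity_error(tmp_path):
    a = Image.open(qr_generate("LEFT01", tmp_path / "a.png"))
    b = Image.open(qr_generate("RIGHT02", tmp_path / "b.png"))
    canvas = Image.new("L", (a.width + b.width + 24, max(a.height, b.height)), 255)
    canvas.paste(a, (0, 0))
    canvas.paste(b, (a.width + 24, 0))
    p = tmp_path / "two.png"
    canvas.save(p)
    with pytest.raises(QRAmbiguityError):
        qr_read(p)


def test_matrix_survives_module_errors_within_rs_budget():
    payload = b"CT01001LTR0N401T1W"
    m = build_matrix(payload, level="M")
    rng = random.Random(0)
    n = len(m)
    for r, c in {(rng.randrange(9, n - 9), rng.randrange(9, n - 9))
                 for _ in range(6)}:
        m[r][c] ^= 1
    assert decode_matrix(m) == payload


def test_reed_solomon_corrects_up_to_half_parity():
    rng = random.Random(1)
    data = [rng.randrange(256) for _ in range(30)]
    msg = data + rs_encode(data, 16)
    corrupted = list(msg)
    for pos in rng.sample(range(len(msg)), 8):
        corrupted[pos] ^= rng.randrange(1, 256)
    assert rs_decode(corrupted, 16) == msg
    for pos in rng.sample(range(len(msg)), 12):  # beyond the t=8 budget
        corrupted[pos] ^= rng.randrange(1, 256)
    with pytest.raises(RSError):
        rs_decode(corrupted, 16)


def test_format_information_codewords_have_distance():
    cws = [format_bits(lv, m) for lv in "LMQH" for m in range(8)]
    assert len(set(cws)) == 32
    dmin = min(bin(a ^ b).count("1")
               for i, a in enumerate(cws) for b in cws[i + 1:])
    assert dmin >= 5  # BCH(15,5) minimum distance guarantees 3-bit tolerance
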