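"""Self-contained QR model-2 codec (byte mode, error-correction level M).

Implements enough of the QR symbology for deterministic "one code, one
image" fingerprint export and its verification decode:

* encoder — byte-mode segments, versions 1-25 (auto-sized, up to ~1000
  payload bytes at level M), Reed-Solomon block ECC over GF(256)
  (primitive polynomial 0x11D), standard interleaving, penalty-scored mask
  selection, format/version BCH codes; rendering to a PIL image with a
  4-module quiet zone;
* decoder — for clean, axis-aligned, unrotated renders such as the ones the
  encoder produces: grid resampling, format decode, unmasking, zigzag
  codeword extraction, block de-interleaving and full Reed-Solomon error
  correction (Berlekamp-Massey / Chien / Forney), then byte-mode parsing.

Everything is a pure function of the payload, so the same text always yields
a pixel-identical image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

MAX_VERSION = 25


class QRCapacityError(ValueError):
    """Payload too large for the supported symbol versions."""


class QRDecodeError(ValueError):
    """Image does not decode to a valid symbol."""


# ---------------------------------------------------------------------------
# GF(256) arithmetic and Reed-Solomon
# ---------------------------------------------------------------------------

_EXP = np.zeros(512, dtype=np.int32)
_LOG = np.zeros(256, dtype=np.int32)
_x = 1
for _i in range(255):
    _EXP[_i] = _x
    _LOG[_x] = _i
    _x <<= 1
    if _x & 0x100:
        _x ^= 0x11D
for _i in range(255, 512):
    _EXP[_i] = _EXP[_i - 255]


def _gf_mul(a: int, b: int) -> int:
    if a == 0 or b == 0:
        return 0
    return int(_EXP[_LOG[a] + _LOG[b]])


def _gf_poly_mul(p: list[int], q: list[int]) -> list[int]:
    out = [0] * (len(p) + len(q) - 1)
    for i, a in enumerate(p):
        for j, b in enumerate(q):
            out[i + j] ^= _gf_mul(a, b)
    return out


def _rs_generator(n_ecc: int) -> list[int]:
    g = [1]
    for i in range(n_ecc):
        g = _gf_poly_mul(g, [1, int(_EXP[i])])
    return g


def rs_encode(data: list[int], n_ecc: int) -> list[int]:
    """Reed-Solomon parity bytes for a data block."""
    gen = _rs_generator(n_ecc)
    rem = list(data) + [0] * n_ecc
    for i in range(len(data)):
        coef = rem[i]
        if coef:
            for j in range(1, len(gen)):
                rem[i + j] ^= _gf_mul(gen[j], coef)
    return rem[len(data):]


def _poly_eval(poly: list[int], x: int) -> int:
    y = 0
    for c in poly:
        y = _gf_mul(y, x) ^ c
    return y


def rs_decode(block: list[int], n_ecc: int) -> list[int]:
    """Correct a received block in place; returns the data bytes.

    Raises :class:`QRDecodeError` when more than n_ecc//2 byte errors are
    present.
    """
    msg = list(block)
    synd = [_poly_eval(msg, int(_EXP[i])) for i in range(n_ecc)]
    if max(synd) == 0:
        return msg[:-n_ecc]
    # Berlekamp-Massey for the error locator sigma
    sigma = [1]
    prev = [1]
    L = 0
    m = 1
    b = 1
    for n in range(n_ecc):
        d = synd[n]
        for i in range(1, L + 1):
            d ^= _gf_mul(sigma[i], synd[n - i])
        if d == 0:
            m += 1
        elif 2 * L <= n:
            t = list(sigma)
            scale = _gf_mul(d, int(_EXP[255 - _LOG[b]]))
            shifted = [0] * m + prev
            sigma = _xor_poly(sigma, [_gf_mul(scale, c) for c in shifted])
            L = n + 1 - L
            prev = t
            b = d
            m = 1
        else:
            scale = _gf_mul(d, int(_EXP[255 - _LOG[b]]))
            shifted = [0] * m + prev
            sigma = _xor_poly(sigma, [_gf_mul(scale, c) for c in shifted])
            m += 1
    # Chien search over message positions
    n_total = len(msg)
    err_pos = []
    for pos in range(n_total):
        x_inv = int(_EXP[(255 - (n_total - 1 - pos)) % 255])
        if _poly_eval(sigma[::-1], x_inv) == 0:
            err_pos.append(pos)
    if len(err_pos) != L or L == 0:
        raise QRDecodeError("uncorrectable Reed-Solomon block")
    # Forney magnitudes
    omega = _poly_mod_mul(synd, sigma, n_ecc)
    for pos in err_pos:
        xi = int(_EXP[(n_total - 1 - pos) % 255])
        x_inv = int(_EXP[(255 - _LOG[xi]) % 255])
        num = _poly_eval(omega[::-1], x_inv)
        den = 0
        # sigma'(x): odd-degree terms
        for deg in range(1, len(sigma), 2):
            den ^= _gf_mul(sigma[deg], int(_EXP[(_LOG[x_inv] * (deg - 1)) % 255]))
        if den == 0:
            raise QRDecodeError("Forney division by zero")
        # e_j = X_j * omega(X_j^-1) / sigma'(X_j^-1) for syndromes based at a^0
        mag = _gf_mul(_gf_mul(num, int(_EXP[255 - _LOG[den]]) if den else 0), xi) \
            if num else 0
        msg[pos] ^= mag
    if any(_poly_eval(msg, int(_EXP[i])) for i in range(n_ecc)):
        raise QRDecodeError("residual syndromes after correction")
    return msg[:-n_ecc]


def _xor_poly(a: list[int], b: list[int]) -> list[int]:
    if len(a) < len(b):
        a, b = b, a
    out = list(a)
    for i, c in enumerate(b):
        out[i] ^= c
    return out


def _poly_mod_mul(synd: list[int], sigma: list[int], n_ecc: int) -> list[int]:
    # omega = synd * sigma mod x^n_ecc, polynomials in ascending-degree order
    out = [0] * n_ecc
    for i, s in enumerate(synd):
        for j, c in enumerate(sigma):
            if i + j < n_ecc:
                out[i + j] ^= _gf_mul(s, c)
    return out


# ---------------------------------------------------------------------------
# Symbol tables (error-correction level M)
# ---------------------------------------------------------------------------

# version -> (ecc codewords per block, [(n_blocks, data codewords per block)])
_ECC_M = {
    1: (10, [(1, 16)]), 2: (16, [(1, 28)]), 3: (26, [(1, 44)]),
    4: (18, [(2, 32)]), 5: (24, [(2, 43)]), 6: (16, [(4, 27)]),
    7: (18, [(4, 31)]), 8: (22, [(2, 38), (2, 39)]), 9: (22, [(3, 36), (2, 37)]),
    10: (26, [(4, 43), (1, 44)]), 11: (30, [(1, 50), (4, 51)]),
    12: (22, [(6, 36), (2, 37)]), 13: (22, [(8, 37), (1, 38)]),
    14: (24, [(4, 40), (5, 41)]), 15: (24, [(5, 41), (5, 42)]),
    16: (28, [(7, 45), (3, 46)]), 17: (28, [(10, 46), (1, 47)]),
    18: (26, [(9, 43), (4, 44)]), 19: (26, [(3, 44), (11, 45)]),
    20: (26, [(3, 41), (13, 42)]), 21: (26, [(17, 42)]),
    22: (28, [(17, 46)]), 23: (28, [(4, 47), (14, 48)]),
    24: (28, [(6, 45), (14, 46)]), 25: (28, [(8, 47), (13, 48)]),
}

_ALIGNMENT = {
    1: [], 2: [6, 18], 3: [6, 22], 4: [6, 26], 5: [6, 30], 6: [6, 34],
    7: [6, 22, 38], 8: [6, 24, 42], 9: [6, 26, 46], 10: [6, 28, 50],
    11: [6, 30, 54], 12: [6, 32, 58], 13: [6, 34, 62], 14: [6, 26, 46, 66],
    15: [6, 26, 48, 70], 16: [6, 26, 50, 74], 17: [6, 30, 54, 78],
    18: [6, 30, 56, 82], 19: [6, 30, 58, 86], 20: [6, 34, 62, 90],
    21: [6, 28, 50, 72, 94], 22: [6, 26, 50, 74, 98], 23: [6, 30, 54, 78, 102],
    24: [6, 28, 54, 80, 106], 25: [6, 32, 58, 84, 110],
}


def _data_capacity(version: int) -> int:
    ecc, blocks = _ECC_M[version]
    return sum(nb * dc for nb, dc in blocks)


def choose_version(n_bytes: int) -> int:
    for v in range(1, MAX_VERSION + 1):
        count_bits = 8 if v <= 9 else 16
        need = 4 + count_bits + 8 * n_bytes
        if need <= 8 * _data_capacity(v):
            return v
    raise QRCapacityError(
        f"payload of {n_bytes} bytes exceeds the level-M capacity of "
        f"version {MAX_VERSION} ({_data_capacity(MAX_VERSION) - 2} bytes)"
    )


# ---------------------------------------------------------------------------
# Matrix construction
# ---------------------------------------------------------------------------

def _function_mask(version: int) -> np.ndarray:
    """Boolean map of reserved (function-pattern) modules."""
    n = 17 + 4 * version
    fm = np.zeros((n, n), dtype=bool)
    for r0, c0 in ((0, 0), (0, n - 8), (n - 8, 0)):
        fm[max(r0, 0):r0 + 8, max(c0, 0):c0 + 8] = True  # finder + separator
    fm[6, :] = True
    fm[:, 6] = True
    centers = _ALIGNMENT[version]
    for r in centers:
        for c in centers:
            if (r < 9 and c < 9) or (r < 9 and c > n - 10) or (r > n - 10 and c < 9):
                continue
            fm[r - 2:r + 3, c - 2:c + 3] = True
    # format areas
    fm[8, :9] = True
    fm[:9, 8] = True
    fm[8, n - 8:] = True
    fm[n - 8:, 8] = True
    if version >= 7:
        fm[:6, n - 11:n - 8] = True
        fm[n - 11:n - 8, :6] = True
    return fm


def _place_function_patterns(mat: np.ndarray, version: int) -> None:
    n = mat.shape[0]
    finder = np.zeros((7, 7), dtype=np.uint8)
    finder[0, :] = finder[-1, :] = finder[:, 0] = finder[:, -1] = 1
    finder[2:5, 2:5] = 1
    for r0, c0 in ((0, 0), (0, n - 7), (n - 7, 0)):
        mat[r0:r0 + 7, c0:c0 + 7] = finder
    for i in range(n):
        mat[6, i] = mat[i, 6] = (i + 1) % 2
    align = np.zeros((5, 5), dtype=np.uint8)
    align[0, :] = align[-1, :] = align[:, 0] = align[:, -1] = 1
    align[2, 2] = 1
    centers = _ALIGNMENT[version]
    for r in centers:
        for c in centers:
            if (r < 9 and c < 9) or (r < 9 and c > n - 10) or (r > n - 10 and c < 9):
                continue
            mat[r - 2:r + 3, c - 2:c + 3] = align
    mat[n - 8, 8] = 1  # dark module


def _bch_format(data5: int) -> int:
    g = 0x537
    rem = data5 << 10
    for i in range(14, 9, -1):
        if rem & (1 << i):
            rem ^= g << (i - 10)
    return ((data5 << 10) | rem) ^ 0x5412


def _bch_version(version: int) -> int:
    g = 0x1F25
    rem = version << 12
    for i in range(17, 11, -1):
        if rem & (1 << i):
            rem ^= g << (i - 12)
    return (version << 12) | rem


_FMT_COPY1 = [(8, 0), (8, 1), (8, 2), (8, 3), (8, 4), (8, 5), (8, 7), (8, 8),
              (7, 8), (5, 8), (4, 8), (3, 8), (2, 8), (1, 8), (0, 8)]


def _fmt_copy2(n: int):
    return [(n - 1 - i, 8) for i in range(7)] + [(8, n - 8 + i) for i in range(8)]


def _write_format(mat: np.ndarray, mask_id: int) -> None:
    n = mat.shape[0]
    fmt = _bch_format((0b00 << 3) | mask_id)  # ECC level M = bits 00
    bits = [(fmt >> (14 - i)) & 1 for i in range(15)]
    for (r, c), b in zip(_FMT_COPY1, bits):
        mat[r, c] = b
    for (r, c), b in zip(_fmt_copy2(n), bits):
        mat[r, c] = b


def _write_version(mat: np.ndarray, version: int) -> None:
    if version < 7:
        return
    n = mat.shape[0]
    bits = _bch_version(version)
    for i in range(18):
        b = (bits >> i) & 1
        mat[i // 3, n - 11 + i % 3] = b
        mat[n - 11 + i % 3, i // 3] = b


def _zigzag_coords(version: int):
    """Module coordinates in codeword placement order."""
    n = 17 + 4 * version
    fm = _function_mask(version)
    coords = []
    col = n - 1
    upward = True
    while col > 0:
        if col == 6:
            col -= 1
        rows = range(n - 1, -1, -1) if upward else range(n)
        for r in rows:
            for c in (col, col - 1):
                if not fm[r, c]:
                    coords.append((r, c))
        col -= 2
        upward = not upward
    return coords


def _mask_matrix(n: int, mask_id: int) -> np.ndarray:
    i, j = np.mgrid[0:n, 0:n]
    if mask_id == 0:
        m = (i + j) % 2 == 0
    elif mask_id == 1:
        m = i % 2 == 0
    elif mask_id == 2:
        m = j % 3 == 0
    elif mask_id == 3:
        m = (i + j) % 3 == 0
    elif mask_id == 4:
        m = (i // 2 + j // 3) % 2 == 0
    elif mask_id == 5:
        m = (i * j) % 2 + (i * j) % 3 == 0
    elif mask_id == 6:
        m = ((i * j) % 2 + (i * j) % 3) % 2 == 0
    elif mask_id == 7:
        m = ((i + j) % 2 + (i * j) % 3) % 2 == 0
    else:
        raise ValueError("mask id must be 0..7")
    return m


def _penalty(mat: np.ndarray) -> int:
    n = mat.shape[0]
    score = 0
    # rule 1: runs of >= 5 same-colour modules (rows and columns)
    for arr in (mat, mat.T):
        for row in arr:
            change = np.flatnonzero(np.diff(row)) + 1
            bounds = np.concatenate(([0], change, [n]))
            runs = np.diff(bounds)
            long = runs[runs >= 5]
            score += int((3 + (long - 5)).sum())
    # rule 2: 2x2 blocks of one colour
    blocks = (mat[:-1, :-1] == mat[1:, :-1]) & (mat[:-1, :-1] == mat[:-1, 1:]) \
        & (mat[:-1, :-1] == mat[1:, 1:])
    score += 3 * int(blocks.sum())
    # rule 3: finder-like 1:1:3:1:1 patterns with a 4-module light flank
    pat = np.array([1, 0, 1, 1, 1, 0, 1, 0, 0, 0, 0], dtype=np.uint8)
    for arr in (mat, mat.T):
        win = np.lib.stride_tricks.sliding_window_view(arr, 11, axis=1)
        score += 40 * int((win == pat).all(-1).sum())
        score += 40 * int((win == pat[::-1]).all(-1).sum())
    # rule 4: dark-module proportion
    dark_pct = 100.0 * mat.sum() / mat.size
    score += 10 * int(abs(dark_pct - 50) // 5)
    return score


# ---------------------------------------------------------------------------
# Encode
# ---------------------------------------------------------------------------

def _build_codewords(payload: bytes, version: int) -> list[int]:
    count_bits = 8 if version <= 9 else 16
    bits = []

    def push(val: int, width: int) -> None:
        for i in range(width - 1, -1, -1):
            bits.append((val >> i) & 1)

    push(0b0100, 4)  # byte mode
    push(len(payload), count_bits)
    for b in payload:
        push(b, 8)
    cap = 8 * _data_capacity(version)
    push(0, min(4, cap - len(bits)))  # terminator
    while len(bits) % 8:
        bits.append(0)
    data = [int("".join(map(str, bits[i:i + 8])), 2) for i in range(0, len(bits), 8)]
    pads = [0xEC, 0x11]
    k = 0
    while len(data) < _data_capacity(version):
        data.append(pads[k % 2])
        k += 1

    ecc_n, blocks = _ECC_M[version]
    data_blocks, ecc_blocks = [], []
    pos = 0
    for n_blocks, dc in blocks:
        for _ in range(n_blocks):
            blk = data[pos:pos + dc]
            pos += dc
            data_blocks.append(blk)
            ecc_blocks.append(rs_encode(blk, ecc_n))
    out = []
    max_dc = max(len(b) for b in data_blocks)
    for i in range(max_dc):
        for blk in data_blocks:
            if i < len(blk):
                out.append(blk[i])
    for i in range(ecc_n):
        for blk in ecc_blocks:
            out.append(blk[i])
    return out


@dataclass
class QRSymbol:
    matrix: np.ndarray  # n x n, 1 = dark
    version: int
    mask_id: int

    @property
    def n_modules(self) -> int:
        return self.matrix.shape[0]

    def to_image(self, scale: int = 4, border: int = 4) -> Image.Image:
        m = np.pad(self.matrix, border, constant_values=0)
        img = (1 - m).astype(np.uint8) * 255
        img = np.kron(img, np.ones((scale, scale), dtype=np.uint8))
        return Image.fromarray(img, mode="L")


def encode(payload: str | bytes) -> QRSymbol:
    """Encode text to a QR symbol (byte mode, level M, mask by penalty)."""
    data = payload.encode("utf-8") if isinstance(payload, str) else bytes(payload)
    if len(data) == 0:
        raise ValueError("empty payload")
    version = choose_version(len(data))
    codewords = _build_codewords(data, version)
    n = 17 + 4 * version
    coords = _zigzag_coords(version)
    base = np.zeros((n, n), dtype=np.uint8)
    _place_function_patterns(base, version)
    _write_version(base, version)
    bitstream = np.zeros(len(coords), dtype=np.uint8)
    for idx, cw in enumerate(codewords):
        for b in range(8):
            bitstream[idx * 8 + b] = (cw >> (7 - b)) & 1
    fm = _function_mask(version)
    best = None
    for mask_id in range(8):
        mat = base.copy()
        mpat = _mask_matrix(n, mask_id)
        for (r, c), bit in zip(coords, bitstream):
            mat[r, c] = bit ^ int(mpat[r, c])
        _write_format(mat, mask_id)
        score = _penalty(mat)
        if best is None or score < best[0] or (score == best[0] and mask_id < best[1]):
            best = (score, mask_id, mat)
    _, mask_id, mat = best
    return QRSymbol(matrix=mat, version=version, mask_id=mask_id)


# ---------------------------------------------------------------------------
# Decode
# ---------------------------------------------------------------------------

def decode_matrix(mat: np.ndarray) -> bytes:
    """Decode an n x n module matrix (1 = dark)."""
    n = mat.shape[0]
    if mat.shape[1] != n or (n - 17) % 4:
        raise QRDecodeError(f"invalid symbol size {mat.shape}")
    version = (n - 17) // 4
    if version < 1 or version > MAX_VERSION:
        raise QRDecodeError(f"unsupported version {version}")
    raw = 0
    for r, c in _FMT_COPY1:
        raw = (raw << 1) | int(mat[r, c])
    data5 = (raw ^ 0x5412) >> 10
    if _bch_format(data5) != raw:
        raise QRDecodeError("format information BCH check failed")
    ecc_bits = data5 >> 3
    mask_id = data5 & 0b111
    if ecc_bits != 0b00:
        raise QRDecodeError("only error-correction level M is supported")
    mpat = _mask_matrix(n, mask_id)
    coords = _zigzag_coords(version)
    bits = [int(mat[r, c]) ^ int(mpat[r, c]) for r, c in coords]
    n_cw = len(bits) // 8
    stream = [
        int("".join(map(str, bits[i * 8:(i + 1) * 8])), 2) for i in range(n_cw)
    ]
    ecc_n, blocks = _ECC_M[version]
    sizes = [dc for nb, dc in blocks for _ in range(nb)]
    n_blocks = len(sizes)
    data_blocks: list[list[int]] = [[] for _ in range(n_blocks)]
    pos = 0
    max_dc = max(sizes)
    for i in range(max_dc):
        for b in range(n_blocks):
            if i < sizes[b]:
                data_blocks[b].append(stream[pos])
                pos += 1
    ecc_blocks: list[list[int]] = [[] for _ in range(n_blocks)]
    for i in range(ecc_n):
        for b in range(n_blocks):
            ecc_blocks[b].append(stream[pos])
            pos += 1
    data = []
    for b in range(n_blocks):
        data.extend(rs_decode(data_blocks[b] + ecc_blocks[b], ecc_n))
    # parse byte-mode segment
    bitpos = 0

    def take(width: int) -> int:
        nonlocal bitpos
        val = 0
        for _ in range(width):
            val = (val << 1) | ((data[bitpos // 8] >> (7 - bitpos % 8)) & 1)
            bitpos += 1
        return val

    mode = take(4)
    if mode != 0b0100:
        raise QRDecodeError(f"unsupported mode {mode:04b} (byte mode expected)")
    count = take(8 if version <= 9 else 16)
    if 4 + (8 if version <= 9 else 16) + 8 * count > 8 * len(data):
        raise QRDecodeError("declared length exceeds data capacity")
    return bytes(take(8) for _ in range(count))


def decode_image(img) -> bytes:
    """Decode a clean, axis-aligned QR image (path, PIL image or array)."""
    if isinstance(img, (str, bytes)) or hasattr(img, "__fspath__"):
        img = Image.open(img)
    if isinstance(img, Image.Image):
        arr = np.asarray(img.convert("L"))
    else:
        arr = np.asarray(img)
    dark = arr < 128
    rows = np.flatnonzero(dark.any(axis=1))
    cols = np.flatnonzero(dark.any(axis=0))
    if rows.size == 0:
        raise QRDecodeError("blank image")
    r0, r1, c0, c1 = rows[0], rows[-1], cols[0], cols[-1]
    crop = dark[r0:r1 + 1, c0:c1 + 1]
    # module size from the top-left finder's leading dark run (7 modules)
    first_row = crop[0]
    run = np.argmin(first_row) if not first_row.all() else first_row.size
    if run == 0:
        raise QRDecodeError("cannot locate finder pattern")
    module = run / 7.0
    n = int(round(crop.shape[1] / module))
    if n < 21:
        raise QRDecodeError("symbol too small")
    centers = ((np.arange(n) + 0.5) * crop.shape[1] / n).astype(int)
    centers_r = ((np.arange(n) + 0.5) * crop.shape[0] / n).astype(int)
    mat = crop[np.ix_(centers_r, centers)].astype(np.uint8)
    return decode_matrix(mat)
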