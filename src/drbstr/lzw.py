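"""Adaptive Lempel-Ziv (LZW) coder emitting classic Unix ``compress`` ``.Z`` streams.

The compression stage of the STR analysis writes each tandem-amplified
sequence to a ``.Z`` stream and uses the stream size in bytes as the
sequence's complexity summary.  The dialect is pinned to the classic
``compress`` defaults: magic ``0x1F 0x9D``, block-compress flag set
(flags byte ``0x90``), variable-width LZW codes growing from 9 to 16
bits, codes packed least-significant-bit first, and the code stream
padded to an 8-code group boundary whenever the code width changes.
Streams produced here are decodable by the reference ``uncompress`` /
``gzip -d`` tools.

Notes on the dialect
--------------------
* In block mode code 256 is reserved as CLEAR; the first free dictionary
  code is 257.  This implementation never emits CLEAR (inputs here are
  far too small to fill a 16-bit dictionary), which is a valid stream:
  once the table is full, coding simply continues without new entries.
* The code width grows from ``n`` to ``n+1`` bits immediately after the
  code whose emission makes the next free entry unrepresentable, and the
  bit stream is padded with zeros to a multiple of ``8*n`` bits at that
  point, mirroring the reference encoder's buffered output.  Because 256
  codes are emitted at 9 bits, 512 at 10 bits, and so on, this padding
  is vacuous unless CLEAR resets occur mid-group.
"""

from __future__ import annotations

MAGIC = b"\x1f\x9d"
BLOCK_MODE = 0x80
CLEAR_CODE = 256
FIRST_FREE = 257
INIT_BITS = 9
MAX_BITS_DEFAULT = 16


class LZWFormatError(ValueError):
    """Raised when a byte stream is not a valid ``.Z`` LZW stream."""


def compress_lzw(data: bytes, max_bits: int = MAX_BITS_DEFAULT) -> bytes:
    """Compress ``data`` into a Unix-compress-compatible ``.Z`` byte stream.

    Parameters
    ----------
    data:
        Arbitrary bytes; the empty string yields the 3-byte header alone.
    max_bits:
        Maximum LZW code width (9-16); the classic default is 16.
    """
    if not 9 <= max_bits <= 16:
        raise ValueError(f"max_bits must be in 9..16, got {max_bits}")
    out = bytearray(MAGIC)
    out.append(max_bits | BLOCK_MODE)
    if not data:
        return bytes(out)

    max_max_code = 1 << max_bits
    n_bits = INIT_BITS
    max_code = (1 << n_bits) - 1
    free_ent = FIRST_FREE
    table: dict[int, int] = {}

    bit_buf = 0  # pending bits, LSB-first
    bit_cnt = 0
    phase_bits = 0  # bits emitted since the last width change

    def emit(code: int) -> None:
        nonlocal bit_buf, bit_cnt, phase_bits, n_bits, max_code
        bit_buf |= code << bit_cnt
        bit_cnt += n_bits
        phase_bits += n_bits
        while bit_cnt >= 8:
            out.append(bit_buf & 0xFF)
            bit_buf >>= 8
            bit_cnt -= 8
        # reference encoder: bump width after the code that outgrew it,
        # padding the current 8-code group (counted from the previous
        # bump, whose buffer flush restarts the group) with zero bits
        if free_ent > max_code:
            pad = (-phase_bits) % (n_bits * 8)
            bit_cnt += pad
            while bit_cnt >= 8:
                out.append(bit_buf & 0xFF)
                bit_buf >>= 8
                bit_cnt -= 8
            phase_bits = 0
            n_bits += 1
            max_code = max_max_code if n_bits == max_bits else (1 << n_bits) - 1

    ent = data[0]
    for c in data[1:]:
        key = (ent << 8) | c
        nxt = table.get(key)
        if nxt is not None:
            ent = nxt
            continue
        emit(ent)
        if free_ent < max_max_code:
            table[key] = free_ent
            free_ent += 1
        ent = c
    emit(ent)
    if bit_cnt > 0:
        out.append(bit_buf & 0xFF)
    return bytes(out)


def decompress_lzw(data: bytes) -> bytes:
    """Decode a ``.Z`` LZW stream produced by :func:`compress_lzw` or ``compress``."""
    if len(data) < 3 or data[:2] != MAGIC:
        raise LZWFormatError("not a .Z stream: bad magic bytes")
    flags = data[2]
    max_bits = flags & 0x1F
    block = bool(flags & BLOCK_MODE)
    if not 9 <= max_bits <= 16:
        raise LZWFormatError(f"unsupported max code width {max_bits}")
    body = data[3:]
    if not body:
        return b""

    max_max_code = 1 << max_bits
    n_bits = INIT_BITS
    max_code = (1 << n_bits) - 1
    free_ent = FIRST_FREE if block else 256
    # code -> (prefix code, final byte); literals implicit
    prefix: dict[int, tuple[int, int]] = {}

    total_bits = len(body) * 8
    bit_pos = 0
    phase_start = 0  # bit offset of the last width change / reset
    out = bytearray()
    prev_code: int | None = None
    prev_bytes = b""

    def entry_bytes(code: int) -> bytes:
        chunk = bytearray()
        while code >= 256:
            code, b = prefix[code]
            chunk.append(b)
        chunk.append(code)
        chunk.reverse()
        return bytes(chunk)

    while True:
        if free_ent > max_code and n_bits < max_bits:
            group = n_bits * 8
            rel = bit_pos - phase_start  # resync to 8-code boundary
            bit_pos = phase_start + -(-rel // group) * group
            phase_start = bit_pos
            n_bits += 1
            max_code = max_max_code if n_bits == max_bits else (1 << n_bits) - 1
        if bit_pos + n_bits > total_bits:
            break
        byte_i, off = divmod(bit_pos, 8)
        window = int.from_bytes(body[byte_i : byte_i + 3], "little")
        code = (window >> off) & ((1 << n_bits) - 1)
        bit_pos += n_bits

        if block and code == CLEAR_CODE:
            group = n_bits * 8
            rel = bit_pos - phase_start
            bit_pos = phase_start + -(-rel // group) * group
            phase_start = bit_pos
            prefix.clear()
            free_ent = FIRST_FREE
            n_bits = INIT_BITS
            max_code = (1 << n_bits) - 1
            prev_code = None
            continue
        if prev_code is None:
            if code >= 256:
                raise LZWFormatError("first code after reset must be a literal")
            prev_code = code
            prev_bytes = bytes([code])
            out += prev_bytes
            continue
        if code > free_ent:
            raise LZWFormatError(f"corrupt stream: code {code} beyond dictionary")
        if code == free_ent:  # KwKwK special case
            cur = prev_bytes + prev_bytes[:1]
        elif code < 256:
            cur = bytes([code])
        else:
            cur = entry_bytes(code)
        out += cur
        if free_ent < max_max_code:
            prefix[free_ent] = (prev_code, cur[0])
            free_ent += 1
        prev_code = code
        prev_bytes = cur
    return bytes(out)
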