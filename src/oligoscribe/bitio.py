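"""Bit-string and bit-matrix input/output.

Bit strings are plain text of ``0``/``1`` characters (whitespace ignored);
arbitrary binary files become bit strings byte by byte, MSB first.  Bit
matrices — e.g. a QR-like pixel grid, which is nothing more than a
two-dimensional bit string — are read and written as plain PBM (P1)
bitmaps and flattened row-major, top-left first.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError


def clean_bits(text: str) -> str:
    """Strip whitespace from a 0/1 text; validate the remainder."""
    bits = "".join(text.split())
    if not bits:
        raise FormatError("no bits found")
    bad = set(bits) - {"0", "1"}
    if bad:
        raise FormatError(f"non-bit character(s): {sorted(bad)}")
    return bits


def bytes_to_bits(data: bytes) -> str:
    """Bytes to a bit string, each byte MSB first."""
    if not data:
        raise FormatError("empty input")
    return "".join(format(byte, "08b") for byte in data)


def bits_to_bytes(bits: str) -> bytes:
    if len(bits) % 8:
        raise FormatError(f"bit count {len(bits)} is not a multiple of 8")
    return bytes(int(bits[i:i + 8], 2) for i in range(0, len(bits), 8))


@dataclass(frozen=True)
class BitMatrix:
    """An h x w grid of bits stored as row strings."""

    rows: tuple[str, ...]

    def __post_init__(self):
        if not self.rows:
            raise FormatError("matrix must have at least one row")
        w = len(self.rows[0])
        if w == 0 or any(len(r) != w for r in self.rows):
            raise FormatError("all matrix rows must have equal, nonzero width")
        for r in self.rows:
            if set(r) - {"0", "1"}:
                raise FormatError("matrix rows must contain only 0/1")

    @property
    def height(self) -> int:
        return len(self.rows)

    @property
    def width(self) -> int:
        return len(self.rows[0])

    def flatten(self) -> str:
        """Row-major bit string, top-left bit first."""
        return "".join(self.rows)

    @classmethod
    def from_bits(cls, bits: str, height: int, width: int) -> "BitMatrix":
        if len(bits) != height * width:
            raise FormatError(
                f"{len(bits)} bits do not fill a {height}x{width} matrix"
            )
        return cls(tuple(bits[i * width:(i + 1) * width] for i in range(height)))

    # ---- plain PBM (P1) -------------------------------------------------
    def to_pbm(self, path) -> None:
        with open(path, "w", encoding="ascii") as fh:
            fh.write(f"P1\n{self.width} {self.height}\n")
            for row in self.rows:
                fh.write(" ".join(row) + "\n")

    @classmethod
    def from_pbm(cls, path) -> "BitMatrix":
        with open(path, encoding="ascii") as fh:
            tokens = []
            for line in fh:
                line = line.split("#", 1)[0]
                tokens.extend(line.split())
        if not tokens or tokens[0] != "P1":
            raise FormatError(f"{path}: not a plain PBM (P1) file")
        try:
            width, height = int(tokens[1]), int(tokens[2])
        except (IndexError, ValueError):
            raise FormatError(f"{path}: malformed PBM header") from None
        bits = "".join(tokens[3:])
        if len(bits) != width * height:
            raise FormatError(
                f"{path}: expected {width * height} pixels, found {len(bits)}"
            )
        return cls.from_bits(bits, height, width)
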