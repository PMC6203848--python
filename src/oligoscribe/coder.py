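"""Encode bit strings as collections of index-tagged oligomer sequences.

The writing side of molecular data storage on sequence-defined oligomers:
a bit string is interpreted as one big integer, rewritten in the base-B
numeral system realised by the chemical alphabet (B = number of coding
building blocks), and the digit stream is cut into short fragments because
a single oligomer cannot hold hundreds of units.  Each fragment is tagged
with an index region so the unordered collection can be reassembled, a
length record preserves the exact bit count (and with it any leading
zeros), and the last fragment is padded with a non-coding spacer block.
Decoding dereplicates the observed sequences, sorts them by index, checks
contiguity, strips index/length/spacer regions and converts the digits
back to bits.

Three field layouts are provided (``EncodingConfig.length_record``):

``"dedicated"`` (default)
    Fixed-width index prepended to every fragment; one extra, variable
    length fragment carrying the bit count trails the data fragments at
    the next index.  Stateless and simple.

``"replicated"``
    Fixed-width index and a fixed-width copy of the bit count in *every*
    fragment.

``"header"``
    The calibrated reference layout (see ``reference.py``): minimal-width
    index, a fixed per-fragment payload of ``capacity - 2`` digits, the
    bit count distributed one digit at a time over the first
    ``header_width`` fragments, and a single-unit oligomer announcing
    ``header_width`` so the collection is self-describing.  Under the
    shipped reference configuration (B=15, capacity 6, header_width 4)
    any 1089-bit input becomes exactly 71 oligomers: 1 monomer,
    11 pentamers and 59 hexamers.
"""

from __future__ import annotations

import json
import math
from collections import Counter
from dataclasses import dataclass, field

from .alphabet import ROLE_SPACER, Alphabet
from .errors import (
    CapacityError,
    ConfigError,
    ConflictError,
    CorruptionError,
    FormatError,
    MissingFragmentError,
)

_LAYOUTS = ("dedicated", "replicated", "header")

# ---------------------------------------------------------------------------
# base conversion


def digit_width(n_bits: int, base: int) -> int:
    """Smallest D with base**D >= 2**n_bits (exact integer arithmetic)."""
    if n_bits < 1:
        raise FormatError("bit-string length must be >= 1")
    if base < 2:
        raise FormatError("base must be >= 2")
    target = 1 << n_bits
    d, power = 0, 1
    while power < target:
        power *= base
        d += 1
    return d


def bits_to_digits(bits: str, base: int) -> list[int]:
    """Base-B digits (MSB first) of the bit string, left-padded with zeros.

    The width is fixed by the bit count alone, so leading zeros of the bit
    string survive the conversion (given that the count is recorded).
    """
    if not bits:
        raise FormatError("bit-string length must be >= 1")
    if set(bits) - {"0", "1"}:
        bad = sorted(set(bits) - {"0", "1"})
        raise FormatError(f"bit string contains non-bit character(s): {bad}")
    value = int(bits, 2)
    width = digit_width(len(bits), base)
    digits = [0] * width
    for i in range(width - 1, -1, -1):
        value, digits[i] = divmod(value, base)
    return digits


def digits_to_bits(digits, base: int, n_bits: int) -> str:
    """Exact inverse of :func:`bits_to_digits` for the recorded bit count."""
    if base < 2:
        raise FormatError("base must be >= 2")
    if n_bits < 1:
        raise FormatError("bit-string length must be >= 1")
    value = 0
    for d in digits:
        if not 0 <= d < base:
            raise FormatError(f"digit {d} out of range for base {base}")
        value = value * base + d
    if value >= (1 << n_bits):
        raise CorruptionError(
            f"decoded payload value needs more than the recorded {n_bits} bits"
        )
    return format(value, f"0{n_bits}b")


def _int_to_digits(value: int, base: int, width: int | None = None) -> list[int]:
    """Non-negative integer to base-B digits, optionally fixed width."""
    digits = []
    v = value
    while v:
        v, r = divmod(v, base)
        digits.append(r)
    if not digits:
        digits = [0]
    digits.reverse()
    if width is not None:
        if len(digits) > width:
            raise CapacityError(
                f"value {value} does not fit in {width} base-{base} digit(s)"
            )
        digits = [0] * (width - len(digits)) + digits
    return digits


def _digits_to_int(digits, base: int) -> int:
    v = 0
    for d in digits:
        v = v * base + d
    return v


def sequence_space_size(base: int, length: int) -> int:
    """Number of distinct sequences of given length over ``base`` blocks."""
    if base < 1:
        raise ConfigError("base must be >= 1")
    if length < 0:
        raise ConfigError("length must be >= 0")
    return base ** length


# ---------------------------------------------------------------------------
# configuration and containers


@dataclass(frozen=True)
class EncodingConfig:
    """Layout parameters of the chemical encoder.

    ``capacity`` is the maximum number of units per oligomer fragment
    (hexamers by default, matching what the synthesis platform comfortably
    reaches).  ``index_digits`` is the fixed index width used by the
    "dedicated" and "replicated" layouts; the "header" layout uses
    minimal-width indices (1 or 2 digits) instead and ignores it.
    """

    alphabet: Alphabet
    capacity: int = 6
    index_digits: int = 2
    length_record: str = "dedicated"
    header_width: int = 4
    length_width: int | None = None

    def __post_init__(self):
        if self.alphabet.base < 2:
            raise ConfigError("encoding needs an alphabet with base >= 2")
        if self.alphabet.spacer is None:
            raise ConfigError("encoding alphabet must include a spacer block")
        if self.length_record not in _LAYOUTS:
            raise ConfigError(f"unknown length_record policy {self.length_record!r}")
        if self.length_record == "header":
            if self.capacity < 3:
                raise ConfigError("header layout needs capacity >= 3")
            if not 1 <= self.header_width < self.alphabet.base:
                raise ConfigError(
                    "header_width must be in 1..base-1 (it is stored as one digit)"
                )
        else:
            if self.index_digits < 1:
                raise ConfigError("index_digits must be >= 1")
            if self.capacity < self.index_digits + 1:
                raise ConfigError("capacity must exceed index_digits")
            if self.length_record == "replicated":
                if self.length_width is None:
                    raise ConfigError("replicated layout requires length_width")
                if self.capacity < self.index_digits + self.length_width + 1:
                    raise ConfigError(
                        "capacity must exceed index_digits + length_width"
                    )

    @property
    def base(self) -> int:
        return self.alphabet.base

    @property
    def payload_width(self) -> int:
        """Payload digits per data fragment."""
        if self.length_record == "dedicated":
            return self.capacity - self.index_digits
        if self.length_record == "replicated":
            return self.capacity - self.index_digits - self.length_width
        return self.capacity - 2

    def describe(self) -> dict:
        return {
            "base": self.base,
            "capacity": self.capacity,
            "index_digits": self.index_digits,
            "length_record": self.length_record,
            "header_width": self.header_width,
            "length_width": self.length_width,
            "spacer_label": self.alphabet.spacer.label,
        }


@dataclass(frozen=True)
class IndexedFragment:
    """A parsed fragment: its index and the raw flag sequence."""

    index: int
    flags: str


@dataclass
class FragmentManifest:
    """The written form of a payload: an unordered multiset of sequences.

    ``sequences`` are label strings resolvable in the encoding alphabet.
    Order carries no information and duplicates are legal (a synthesized
    oligomer may be observed many times); decoding dereplicates first.
    ``meta`` echoes provenance (configuration) and is never consulted by
    :func:`decode`.
    """

    sequences: list[str]
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sequences)

    def census(self) -> dict[int, int]:
        """Fragment counts keyed by oligomer length."""
        return dict(sorted(Counter(len(s) for s in self.sequences).items()))

    def dereplicated(self) -> list[str]:
        """Unique sequences, sorted for determinism."""
        return sorted(set(self.sequences))

    # ---- JSON / CSV twins ----------------------------------------------
    def to_json(self, path, *, model=None, alphabet=None) -> None:
        from .massmodel import oligomer_mass

        records = []
        for seq in sorted(self.sequences):
            rec = {"sequence": seq}
            if model is not None and alphabet is not None:
                rec["precursor_mz"] = oligomer_mass(seq, model, alphabet)
            records.append(rec)
        payload = {"meta": self.meta, "fragments": records}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "FragmentManifest":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        try:
            seqs = [rec["sequence"] for rec in payload["fragments"]]
        except (KeyError, TypeError):
            raise FormatError(f"{path}: not a manifest JSON file") from None
        return cls(sequences=seqs, meta=payload.get("meta", {}))

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("fragment_id,sequence\n")
            for i, seq in enumerate(sorted(self.sequences)):
                fh.write(f"{i},{seq}\n")

    @classmethod
    def from_csv(cls, path) -> "FragmentManifest":
        seqs = []
        with open(path, encoding="utf-8") as fh:
            header = fh.readline()
            if not header.startswith("fragment_id"):
                raise FormatError(f"{path}: missing 'fragment_id,sequence' header")
            for line in fh:
                line = line.strip()
                if not line:
                    continue
                parts = line.split(",")
                if len(parts) != 2:
                    raise FormatError(f"{path}: malformed row {line!r}")
                seqs.append(parts[1])
        return cls(sequences=seqs)


# ---------------------------------------------------------------------------
# encoding

_SPACER = None  # sentinel for a spacer unit inside digit-level fragment lists


def _chunk(digits, width):
    return [digits[i:i + width] for i in range(0, len(digits), width)]


def _pad(chunk, width):
    return chunk + [_SPACER] * (width - len(chunk))


def encode(bits: str, cfg: EncodingConfig) -> FragmentManifest:
    """Encode a bit string as an unordered collection of oligomer sequences.

    Deterministic: identical inputs give identical manifests.
    """
    digits = bits_to_digits(bits, cfg.base)
    n = len(bits)
    if cfg.length_record == "dedicated":
        frag_digits = _encode_dedicated(digits, n, cfg)
    elif cfg.length_record == "replicated":
        frag_digits = _encode_replicated(digits, n, cfg)
    else:
        frag_digits = _encode_header(digits, n, cfg)

    spacer = cfg.alphabet.spacer.label
    seqs = [
        "".join(spacer if d is _SPACER else cfg.alphabet.label_of(d) for d in frag)
        for frag in frag_digits
    ]
    return FragmentManifest(sequences=seqs, meta={"config": cfg.describe()})


def _encode_dedicated(digits, n, cfg):
    B, iw, pw = cfg.base, cfg.index_digits, cfg.payload_width
    chunks = _chunk(digits, pw)
    k_data = len(chunks)
    if k_data + 1 > B ** iw:
        raise CapacityError(
            f"{k_data + 1} fragments exceed the {B}^{iw} index space"
        )
    length_digits = _int_to_digits(n, B)
    if iw + len(length_digits) > cfg.capacity:
        raise CapacityError(
            f"length record ({len(length_digits)} digits) does not fit one "
            f"fragment at capacity {cfg.capacity}; increase capacity or base"
        )
    chunks[-1] = _pad(chunks[-1], pw)
    frags = [
        _int_to_digits(i, B, iw) + chunk for i, chunk in enumerate(chunks)
    ]
    frags.append(_int_to_digits(k_data, B, iw) + length_digits)
    return frags


def _encode_replicated(digits, n, cfg):
    B, iw, lw, pw = cfg.base, cfg.index_digits, cfg.length_width, cfg.payload_width
    if n >= B ** lw:
        raise CapacityError(f"bit count {n} does not fit {lw} base-{B} digit(s)")
    chunks = _chunk(digits, pw)
    if len(chunks) > B ** iw:
        raise CapacityError(
            f"{len(chunks)} fragments exceed the {B}^{iw} index space"
        )
    length_digits = _int_to_digits(n, B, lw)
    chunks[-1] = _pad(chunks[-1], pw)
    return [
        _int_to_digits(i, B, iw) + length_digits + chunk
        for i, chunk in enumerate(chunks)
    ]


def _encode_header(digits, n, cfg):
    B, h, pw = cfg.base, cfg.header_width, cfg.payload_width
    if n >= B ** h:
        raise CapacityError(f"bit count {n} does not fit {h} base-{B} digit(s)")
    chunks = _chunk(digits, pw)
    k = len(chunks)
    if k < h:
        raise CapacityError(
            f"input yields only {k} fragments; the distributed length header "
            f"needs at least header_width={h}"
        )
    if (k - 1) + B * (h - 1) > B * B - 1:
        raise CapacityError(f"{k} fragments exceed the two-digit index space")
    length_digits = _int_to_digits(n, B, h)
    chunks[-1] = _pad(chunks[-1], pw)

    frags = [[h]]  # the header-width monomer
    for i, chunk in enumerate(chunks):
        if i < h:
            frags.append([i, length_digits[i]] + chunk)
        elif i < B:
            frags.append([i] + chunk)
        else:
            v = i + B * (h - 1)
            frags.append([v // B, v % B] + chunk)
    return frags


# ---------------------------------------------------------------------------
# decoding


def decode(manifest: FragmentManifest, cfg: EncodingConfig) -> str:
    """Recover the exact bit string from an unordered fragment collection.

    Dereplicates, parses indices, checks contiguity, extracts the recorded
    bit count, concatenates payloads in index order, trims the spacer
    padding and converts the digits back to bits.  Invariant under any
    permutation or duplication of manifest members.
    """
    seqs = sorted(set(manifest.sequences))
    if not seqs:
        raise FormatError("empty manifest: no length record")
    spacer = cfg.alphabet.spacer.label
    digit_seqs = []
    for seq in seqs:
        units = []
        for lab in seq:
            units.append(_SPACER if lab == spacer else cfg.alphabet.digit(lab))
        digit_seqs.append(units)

    if cfg.length_record == "dedicated":
        n, bodies = _parse_dedicated(digit_seqs, cfg)
    elif cfg.length_record == "replicated":
        n, bodies = _parse_replicated(digit_seqs, cfg)
    else:
        n, bodies = _parse_header(digit_seqs, cfg)

    if n < 1:
        raise CorruptionError("length record decodes to zero bits")
    width = digit_width(n, cfg.base)
    expected_k = math.ceil(width / cfg.payload_width)
    if len(bodies) != expected_k:
        raise CorruptionError(
            f"{len(bodies)} data fragments but the recorded bit count "
            f"implies {expected_k}"
        )
    payload = [d for body in bodies for d in body]
    while payload and payload[-1] is _SPACER:
        payload.pop()
    if any(d is _SPACER for d in payload):
        raise CorruptionError("spacer unit inside the coding region")
    if len(payload) != width:
        raise CorruptionError(
            f"{len(payload)} payload digits but the recorded bit count "
            f"implies {width}"
        )
    return digits_to_bits(payload, cfg.base, n)


def _index_value(units, cfg, where):
    if any(u is _SPACER for u in units):
        raise CorruptionError(f"spacer unit inside the {where} region")
    return _digits_to_int(units, cfg.base)


def _collect(records):
    """records: iterable of (index, body, extra) -> dict index -> (body, extra)."""
    table = {}
    for idx, body, extra in records:
        if idx in table and table[idx] != (body, extra):
            raise ConflictError(f"two distinct fragments share index {idx}")
        table[idx] = (body, extra)
    return table


def _check_contiguous(table):
    top = max(table)
    gaps = set(range(top + 1)) - set(table)
    if gaps:
        raise MissingFragmentError(gaps)
    return top


def _parse_dedicated(digit_seqs, cfg):
    iw = cfg.index_digits
    records = []
    for units in digit_seqs:
        if len(units) <= iw:
            raise FormatError(
                f"fragment of {len(units)} unit(s) is shorter than the index region"
            )
        idx = _index_value(units[:iw], cfg, "index")
        records.append((idx, tuple(units[iw:]), None))
    table = _collect(records)
    top = _check_contiguous(table)
    length_body, _ = table[top]
    if any(u is _SPACER for u in length_body):
        raise CorruptionError("spacer unit inside the length record")
    n = _digits_to_int(length_body, cfg.base)
    bodies = [list(table[i][0]) for i in range(top)]
    for body in bodies:
        if len(body) != cfg.payload_width:
            raise FormatError(
                f"data fragment payload of {len(body)} digit(s); expected "
                f"{cfg.payload_width}"
            )
    return n, bodies


def _parse_replicated(digit_seqs, cfg):
    iw, lw = cfg.index_digits, cfg.length_width
    records = []
    lengths = set()
    for units in digit_seqs:
        if len(units) != cfg.capacity:
            raise FormatError(
                f"fragment of {len(units)} unit(s); replicated layout expects "
                f"{cfg.capacity}"
            )
        idx = _index_value(units[:iw], cfg, "index")
        n = _index_value(units[iw:iw + lw], cfg, "length")
        lengths.add(n)
        records.append((idx, tuple(units[iw + lw:]), n))
    if len(lengths) > 1:
        raise ConflictError(f"length replicas disagree: {sorted(lengths)}")
    table = _collect(records)
    top = _check_contiguous(table)
    bodies = [list(table[i][0]) for i in range(top + 1)]
    return lengths.pop(), bodies


def _parse_header(digit_seqs, cfg):
    B, pw = cfg.base, cfg.payload_width
    monomers = {tuple(u) for u in digit_seqs if len(u) == 1}
    if not monomers:
        raise FormatError("no length record: header-width monomer missing")
    if len(monomers) > 1:
        raise ConflictError("conflicting header-width monomers")
    (h_unit,) = monomers.pop()
    if h_unit is _SPACER:
        raise CorruptionError("header-width monomer is a spacer")
    h = h_unit

    records = []
    for units in digit_seqs:
        if len(units) == 1:
            continue
        if len(units) == 1 + pw:
            idx = _index_value(units[:1], cfg, "index")
            if idx < h:
                raise CorruptionError(
                    f"short fragment with index {idx} inside the header range"
                )
            records.append((idx, tuple(units[1:]), None))
        elif len(units) == 2 + pw:
            d0 = _index_value(units[:1], cfg, "index")
            if d0 < h:
                len_digit = units[1]
                if len_digit is _SPACER:
                    raise CorruptionError("spacer unit inside the length record")
                records.append((d0, tuple(units[2:]), len_digit))
            else:
                idx = _digits_to_int(
                    [d0, _index_value(units[1:2], cfg, "index")], B
                ) - B * (h - 1)
                if idx < B:
                    raise CorruptionError(
                        f"two-digit index decodes to {idx}, below the "
                        f"two-digit range"
                    )
                records.append((idx, tuple(units[2:]), None))
        else:
            raise FormatError(
                f"fragment of {len(units)} unit(s) does not fit the header layout"
            )
    if not records:
        raise FormatError("manifest holds no data fragments")
    table = _collect(records)
    top = _check_contiguous(table)
    length_digits = []
    for i in range(min(h, top + 1)):
        extra = table[i][1]
        if extra is None:
            raise CorruptionError(f"fragment {i} lacks its length-header digit")
        length_digits.append(extra)
    if top + 1 < h:
        raise CorruptionError(
            f"{top + 1} fragments cannot carry a {h}-digit length header"
        )
    n = _digits_to_int(length_digits, B)
    bodies = [list(table[i][0]) for i in range(top + 1)]
    return n, bodies


def census(manifest: FragmentManifest) -> dict[int, int]:
    """Fragment counts keyed by oligomer length (e.g. ``{1:1, 5:11, 6:59}``)."""
    return manifest.census()
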