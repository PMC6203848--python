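"""Chemical alphabets: building blocks as the digits of a numeral system.

A *building block* is one side-chain functionality occupying one position of
a sequence-defined oligomer; its monoisotopic ``unit_mass`` is the mass it
adds to the chain.  An :class:`Alphabet` is an ordered set of such blocks.
Coding blocks double as digits: the digit value of a block is its 0-based
position among the coding blocks, so an alphabet with ``base`` coding blocks
realises a base-``base`` positional numeral system in chemistry.  A block
with role ``"spacer"`` is non-coding and is used only to pad fragments.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

from .errors import ConfigError, FormatError, ResolutionError

ROLE_CODING = "coding"
ROLE_SPACER = "spacer"

# label pool for auto-generated alphabets: uppercase (minus the default
# spacer label Z), then lowercase, then decimal digits
_LABEL_POOL = (
    "ABCDEFGHIJKLMNOPQRSTUVWXY" + string.ascii_lowercase + string.digits
)
DEFAULT_SPACER_LABEL = "Z"


@dataclass(frozen=True)
class BuildingBlock:
    """One monomer unit: a label, its monoisotopic unit mass and its role."""

    label: str
    unit_mass: float
    role: str = ROLE_CODING

    def __post_init__(self):
        if len(self.label) != 1 or not self.label.isprintable():
            raise ConfigError(
                f"block label must be one printable character, got {self.label!r}"
            )
        if not (self.unit_mass > 0):
            raise ConfigError(
                f"block {self.label!r}: unit_mass must be > 0, got {self.unit_mass}"
            )
        if self.role not in (ROLE_CODING, ROLE_SPACER):
            raise ConfigError(f"block {self.label!r}: unknown role {self.role!r}")


@dataclass(frozen=True)
class Alphabet:
    """Ordered collection of building blocks.

    Coding blocks, in order, are the digits 0..base-1.  All unit masses must
    be pairwise distinct (mass is the only observable that identifies a
    block in a spectrum); readers additionally require the minimum pairwise
    gap to exceed twice their mass tolerance, which is checked at read time,
    not here.
    """

    blocks: tuple[BuildingBlock, ...]
    _by_label: dict = field(init=False, repr=False, compare=False)

    def __init__(self, blocks):
        blocks = tuple(blocks)
        labels = [b.label for b in blocks]
        if len(set(labels)) != len(labels):
            raise ConfigError("duplicate block labels in alphabet")
        masses = [b.unit_mass for b in blocks]
        if len(set(masses)) != len(masses):
            raise ConfigError("block unit masses must be pairwise distinct")
        object.__setattr__(self, "blocks", blocks)
        object.__setattr__(self, "_by_label", {b.label: b for b in blocks})

    @property
    def coding_blocks(self) -> tuple[BuildingBlock, ...]:
        return tuple(b for b in self.blocks if b.role == ROLE_CODING)

    @property
    def base(self) -> int:
        """Number of coding blocks = base of the numeral system."""
        return len(self.coding_blocks)

    @property
    def spacer(self) -> BuildingBlock | None:
        for b in self.blocks:
            if b.role == ROLE_SPACER:
                return b
        return None

    def block(self, label: str) -> BuildingBlock:
        try:
            return self._by_label[label]
        except KeyError:
            raise ResolutionError(f"label {label!r} not in alphabet") from None

    def __contains__(self, label: str) -> bool:
        return label in self._by_label

    def mass(self, label: str) -> float:
        return self.block(label).unit_mass

    def digit(self, label: str) -> int:
        """Digit value of a coding block (its 0-based coding position)."""
        blk = self.block(label)
        if blk.role != ROLE_CODING:
            raise ResolutionError(f"label {label!r} is non-coding (role={blk.role})")
        return self.coding_blocks.index(blk)

    def label_of(self, digit: int) -> str:
        coding = self.coding_blocks
        if not 0 <= digit < len(coding):
            raise ResolutionError(f"digit {digit} out of range for base {len(coding)}")
        return coding[digit].label

    def min_mass_gap(self) -> float:
        """Smallest pairwise |Δ unit_mass| across all blocks."""
        masses = sorted(b.unit_mass for b in self.blocks)
        if len(masses) < 2:
            return float("inf")
        return min(b - a for a, b in zip(masses, masses[1:]))

    def validate_sequence(self, seq) -> None:
        for lab in seq:
            self.block(lab)

    # ---- TSV interface: label<TAB>unit_mass<TAB>role, one block per line
    @classmethod
    def from_tsv(cls, path) -> "Alphabet":
        blocks = []
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if ln == 1 and parts[0] == "label":
                    continue  # header
                if len(parts) not in (2, 3):
                    raise FormatError(f"{path}:{ln}: expected 2-3 tab-separated fields")
                label, mass = parts[0], parts[1]
                role = parts[2] if len(parts) == 3 else ROLE_CODING
                try:
                    mass = float(mass)
                except ValueError:
                    raise FormatError(f"{path}:{ln}: bad mass {parts[1]!r}") from None
                blocks.append(BuildingBlock(label, mass, role))
        if not blocks:
            raise FormatError(f"{path}: no blocks found")
        return cls(blocks)

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("label\tunit_mass\trole\n")
            for b in self.blocks:
                fh.write(f"{b.label}\t{b.unit_mass!r}\t{b.role}\n")


def make_alphabet(
    base: int,
    spacing: float = 5.0,
    base_mass: float = 100.0,
    *,
    spacer_label: str | None = DEFAULT_SPACER_LABEL,
    spacer_mass: float | None = None,
    tolerance: float = 0.02,
) -> Alphabet:
    """Arithmetic toy alphabet: ``base`` coding blocks at evenly spaced masses.

    Labels follow the A, B, C, ... convention; masses are
    ``base_mass + k*spacing``.  A non-coding spacer block (default label Z,
    mass ``base_mass - 2*spacing`` unless given) is appended so the alphabet
    can pad encoded fragments.  ``spacing`` must exceed ``2*tolerance`` or
    no reader at that tolerance could distinguish adjacent blocks.
    """
    if base < 1:
        raise ConfigError("base must be >= 1")
    if base > len(_LABEL_POOL):
        raise ConfigError(f"at most {len(_LABEL_POOL)} coding blocks supported")
    if spacing <= 2 * tolerance:
        raise ConfigError(
            f"spacing {spacing} too small for tolerance {tolerance} "
            f"(need > {2 * tolerance})"
        )
    blocks = [
        BuildingBlock(_LABEL_POOL[k], base_mass + k * spacing) for k in range(base)
    ]
    if spacer_label is not None:
        if spacer_mass is None:
            spacer_mass = base_mass - 2 * spacing
        if spacer_mass <= 0:
            raise ConfigError("spacer mass must be positive")
        blocks.append(BuildingBlock(spacer_label, spacer_mass, ROLE_SPACER))
    return Alphabet(blocks)
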