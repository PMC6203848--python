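"""Mass arithmetic for sequence-defined oligo(amide-urethane)s.

An oligomer is a chain ``alpha-end | b_1 b_2 ... b_L | omega-end``: the
α-end is the linker residue the chain was grown from (acid or alcohol), the
ω-end is the thiolactone-derived stop group, and each unit ``b_i`` is one
building block.  Collision-induced dissociation cleaves the backbone
urethane bonds, producing for every internal bond one start-containing
("prefix") and one stop-containing ("suffix") fragment.  Each cleavage adds
a constant mass offset to either side (``delta_left`` on the prefix,
``delta_right`` on the suffix): which chemical moiety (carbamate, amine,
isocyanate, ...) each side retains is instrument/chemistry specific, so
both offsets are free parameters of the model.  All masses are
monoisotopic; ions are cationized (sodium adduct by default in MALDI
positive mode) and the precursor may carry ``charge`` > 1 for ESI data.

The two fragment series form *ladders*: successive prefix masses differ by
the unit masses of the sequence read left→right, successive suffix masses
by the unit masses read right→left.  That is the entire basis of the
read-out: the sequence can be read from both ends independently.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .alphabet import Alphabet
from .errors import ConfigError, FormatError, ResolutionError

#: monoisotopic mass of the sodium cation adduct (Na+ replaces nothing on a
#: neutral analyte; electron mass neglected at 0.02 Da read-out tolerance)
SODIUM_ADDUCT = 22.98922


@dataclass(frozen=True)
class MassModel:
    """End-group, cleavage-offset and adduct masses of the chemistry.

    Parameters
    ----------
    alpha_mass:
        Mass (Da) of the α-end group (linker residue; "start" side).
    omega_mass:
        Mass (Da) of the ω-end group (thiolactone ring; "stop" side).
    delta_left, delta_right:
        Constant mass offsets (Da) gained by the start-/stop-containing
        fragment upon urethane cleavage.  May be negative.
    adduct_mass:
        Cationizing adduct mass (Da); sodium by default.  Both fragment
        series are assumed to carry the same adduct as the precursor.
    charge:
        Precursor charge state; 1 for MALDI.
    """

    alpha_mass: float
    omega_mass: float
    delta_left: float = 0.0
    delta_right: float = 0.0
    adduct_mass: float = SODIUM_ADDUCT
    charge: int = 1

    def __post_init__(self):
        if self.charge < 1:
            raise ConfigError(f"charge must be >= 1, got {self.charge}")
        for name in ("alpha_mass", "omega_mass", "delta_left", "delta_right",
                     "adduct_mass"):
            if not math.isfinite(getattr(self, name)):
                raise ConfigError(f"{name} must be finite")

    @property
    def delta_total(self) -> float:
        """Complementarity constant: for every cleavage site the prefix and
        suffix fragment masses sum to the neutral precursor mass plus
        ``delta_left + delta_right`` (plus one extra adduct, since both
        fragments are cationized)."""
        return self.delta_left + self.delta_right

    # ---- flat key:value config file -------------------------------------
    _FIELDS = ("alpha_mass", "omega_mass", "delta_left", "delta_right",
               "adduct_mass", "charge")

    @classmethod
    def from_file(cls, path) -> "MassModel":
        values = {}
        with open(path, encoding="utf-8") as fh:
            for ln, line in enumerate(fh, 1):
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if ":" not in line:
                    raise FormatError(f"{path}:{ln}: expected 'key: value'")
                key, val = (s.strip() for s in line.split(":", 1))
                if key not in cls._FIELDS:
                    raise FormatError(f"{path}:{ln}: unknown key {key!r}")
                values[key] = int(val) if key == "charge" else float(val)
        missing = {"alpha_mass", "omega_mass"} - values.keys()
        if missing:
            raise FormatError(f"{path}: missing required key(s) {sorted(missing)}")
        return cls(**values)

    def to_file(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for key in self._FIELDS:
                fh.write(f"{key}: {getattr(self, key)!r}\n")


@dataclass(frozen=True)
class FragmentLadder:
    """Theoretical fragment masses of one oligomer.

    ``prefix[i-1]`` is the m/z of the start-containing fragment covering
    units 1..i; ``suffix[j-1]`` covers the last j units.  Both series are
    strictly increasing, and successive differences reproduce the unit
    masses of the sequence (forwards for the prefix series, backwards for
    the suffix series).
    """

    prefix: tuple[float, ...]
    suffix: tuple[float, ...]
    precursor: float

    def __len__(self) -> int:
        return len(self.prefix)


def oligomer_mass(
    seq,
    model: MassModel,
    alphabet: Alphabet,
    *,
    allow_empty: bool = False,
) -> float:
    """Observable m/z of the intact (cationized) oligomer.

    ``(alpha + sum of unit masses + omega + adduct) / charge``.  Mass is a
    function of composition only — any permutation of ``seq`` has the same
    precursor mass, which is precisely why MS1 cannot sequence and the
    fragment ladders can.
    """
    seq = list(seq)
    if not seq and not allow_empty:
        raise ResolutionError("empty sequence (pass allow_empty=True for the bare scaffold)")
    total = model.alpha_mass + model.omega_mass + model.adduct_mass
    for lab in seq:
        total += alphabet.mass(lab)
    return total / model.charge


def fragment_ladders(seq, model: MassModel, alphabet: Alphabet) -> FragmentLadder:
    """Theoretical prefix/suffix fragment ladders for ``seq``.

    prefix_i = alpha + sum(u_1..u_i) + delta_left + adduct
    suffix_j = sum(u_{L-j+1}..u_L) + omega + delta_right + adduct
    """
    seq = list(seq)
    if not seq:
        raise ResolutionError("cannot build fragment ladders for an empty sequence")
    unit = [alphabet.mass(lab) for lab in seq]

    prefix = []
    m = model.alpha_mass + model.delta_left + model.adduct_mass
    for u in unit:
        m += u
        prefix.append(m)

    suffix = []
    m = model.omega_mass + model.delta_right + model.adduct_mass
    for u in reversed(unit):
        m += u
        suffix.append(m)

    return FragmentLadder(
        prefix=tuple(prefix),
        suffix=tuple(suffix),
        precursor=oligomer_mass(seq, model, alphabet),
    )
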