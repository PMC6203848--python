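"""The shipped reference configuration.

The real chemistry's end-group and cleavage-offset masses live in
supplementary instrument data and are therefore *configuration* in this
package (editable TSV / key:value files, see ``oligoscribe/data``).  The
reference configuration below is a documented schematic stand-in with two
deliberate properties:

* the three mass families (prefix fragments, suffix fragments, precursor)
  live on distinct offsets of the 5-Da alphabet lattice, so they can never
  shadow each other during a ladder walk;
* the encoder layout is calibrated so that any 1089-bit payload (a 33x33
  pixel grid) becomes exactly 71 oligomers — 1 monomer, 11 pentamers and
  59 hexamers — the census the 72-slot automated synthesis platform was
  sized against.

Layout arithmetic for 1089 bits, base 15: 279 digits; 4 payload digits per
fragment -> 70 data fragments; the 4-digit length field rides on fragments
0..3 (hexamers), fragments 4..14 keep 1-digit indices (11 pentamers),
fragments 15..69 need 2-digit indices (55 hexamers), and one single-unit
oligomer records the header width (the monomer).
"""

from __future__ import annotations

from importlib import resources

from .alphabet import Alphabet, make_alphabet
from .coder import EncodingConfig
from .massmodel import MassModel, SODIUM_ADDUCT
from .reader import ReaderConfig


def reference_alphabet() -> Alphabet:
    """15 coding blocks A..O at 100..170 Da (5 Da spacing), spacer Z at 90 Da."""
    return make_alphabet(15, spacing=5.0, base_mass=100.0, spacer_label="Z")


def reference_mass_model() -> MassModel:
    """Schematic end-group masses, sodium cationization, singly charged."""
    return MassModel(
        alpha_mass=100.0,
        omega_mass=50.0,
        delta_left=1.0,
        delta_right=2.0,
        adduct_mass=SODIUM_ADDUCT,
        charge=1,
    )


def reference_encoding_config(alphabet: Alphabet | None = None) -> EncodingConfig:
    """Hexamer capacity, distributed 4-digit length header, minimal index."""
    return EncodingConfig(
        alphabet=alphabet or reference_alphabet(),
        capacity=6,
        length_record="header",
        header_width=4,
    )


def reference_reader_config() -> ReaderConfig:
    """The MALDI-TOF/TOF acceptance rule: 0.02 Da window, S/N > 5."""
    return ReaderConfig(tolerance=0.02, snr_min=5.0)


def data_path(name: str):
    """Path to a shipped data file (reference alphabet TSV, mass model)."""
    return resources.files("oligoscribe").joinpath("data", name)
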