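"""Synthetic MS/MS spectra and random payloads: the test harness.

The generator emulates the *structure* of MALDI-MS/MS spectra of
sequence-defined oligo(amide-urethane)s — complete or partially missing
prefix/suffix fragment ladders from urethane-bond cleavage, a precursor
peak, uniform noise peaks and bounded m/z jitter — not their physics.
Intensities are schematic (constant signal height) because the reader uses
intensity only through the signal-to-noise rule; isotope envelopes and
multiply charged species are deliberately absent.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alphabet import Alphabet, make_alphabet
from .bitio import BitMatrix
from .errors import ConfigError
from .massmodel import MassModel, fragment_ladders
from .peaks import PeakList

#: series names accepted in SimulationConfig.delete
PREFIX, SUFFIX, PRECURSOR = "prefix", "suffix", "precursor"


@dataclass(frozen=True)
class SimulationConfig:
    """Controls for the spectrum simulator.

    ``dropout`` is the probability that any one true ladder peak is
    omitted; ``delete`` removes specific peaks instead — entries are
    ``("prefix", i)`` / ``("suffix", j)`` with 1-based rung numbers, or
    ``("precursor", 0)``.  Noise peaks fall uniformly inside the m/z span
    of the true peaks with intensities drawn from
    ``noise_intensity_range`` — below the S/N threshold by default, so a
    "noisy" clean channel stays readable; raise the range above
    ``snr_min * noise_level`` for adversarial spectra.  ``jitter`` is the
    maximum absolute m/z perturbation applied to every emitted peak.
    """

    dropout: float = 0.0
    delete: tuple = ()
    n_noise_peaks: int = 0
    noise_intensity_range: tuple[float, float] = (0.5, 4.5)
    jitter: float = 0.0
    signal_intensity: float = 100.0
    noise_level: float = 1.0
    include_precursor: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.dropout <= 1.0:
            raise ConfigError("dropout must be in [0, 1]")
        if self.jitter < 0:
            raise ConfigError("jitter must be >= 0")
        if self.n_noise_peaks < 0:
            raise ConfigError("n_noise_peaks must be >= 0")
        for entry in self.delete:
            if (
                not isinstance(entry, tuple) or len(entry) != 2
                or entry[0] not in (PREFIX, SUFFIX, PRECURSOR)
            ):
                raise ConfigError(f"bad delete entry {entry!r}")


def simulate_spectrum(
    seq,
    alphabet: Alphabet,
    model: MassModel,
    sim: SimulationConfig | None = None,
) -> PeakList:
    """Simulate the MS/MS spectrum of one oligomer.

    Emits the surviving prefix/suffix ladder peaks plus the precursor,
    jitters every peak uniformly within ±jitter, and adds noise peaks.
    """
    sim = sim or SimulationConfig()
    rng = np.random.default_rng(sim.seed)
    ladder = fragment_ladders(seq, model, alphabet)
    deleted = set(sim.delete)

    peaks: list[tuple[float, float]] = []
    for series, masses in ((PREFIX, ladder.prefix), (SUFFIX, ladder.suffix)):
        for rung, mass in enumerate(masses, start=1):
            # one rng draw per ladder peak regardless of deletion keeps the
            # dropout pattern of the surviving peaks seed-stable
            drop = rng.random() < sim.dropout
            if (series, rung) in deleted or drop:
                continue
            peaks.append((mass, sim.signal_intensity))
    if sim.include_precursor and (PRECURSOR, 0) not in deleted:
        peaks.append((ladder.precursor, sim.signal_intensity))

    if peaks:
        span_lo = min(m for m, _ in peaks)
        span_hi = max(m for m, _ in peaks)
    else:
        span_lo, span_hi = 100.0, 1000.0
    lo, hi = sim.noise_intensity_range
    for _ in range(sim.n_noise_peaks):
        mz = rng.uniform(span_lo, span_hi)
        peaks.append((mz, rng.uniform(lo, hi)))

    mzs = np.array([m for m, _ in peaks])
    intens = np.array([i for _, i in peaks])
    if sim.jitter > 0:
        mzs = mzs + rng.uniform(-sim.jitter, sim.jitter, size=mzs.size)

    precursor_obs = ladder.precursor
    if sim.include_precursor and (PRECURSOR, 0) not in deleted and sim.jitter > 0:
        # report the (jittered) measured precursor as the selection mass
        precursor_obs = float(mzs[len(mzs) - sim.n_noise_peaks - 1])

    return PeakList(
        mzs,
        intens,
        precursor_mz=precursor_obs,
        noise_level=sim.noise_level,
        title="".join(seq),
    )


def simulate_manifest(sequences, alphabet, model, sim=None, *, seed=0):
    """One spectrum per sequence, with per-sequence derived seeds."""
    sim = sim or SimulationConfig()
    out = []
    for i, seq in enumerate(sequences):
        per = _replace_seed(sim, (seed * 100003 + i * 7919 + sim.seed) % (2**31))
        out.append(simulate_spectrum(seq, alphabet, model, per))
    return out


def _replace_seed(sim: SimulationConfig, seed: int) -> SimulationConfig:
    from dataclasses import replace

    return replace(sim, seed=seed)


# ---------------------------------------------------------------------------
# random payloads and alphabets


def random_bits(n: int, seed: int) -> str:
    """Reproducible uniform random bit string of length n."""
    if n < 1:
        raise ConfigError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return "".join("1" if b else "0" for b in rng.integers(0, 2, size=n))


def random_matrix(height: int, width: int, seed: int) -> BitMatrix:
    """Reproducible random bit matrix (a stand-in for a QR-like grid)."""
    bits = random_bits(height * width, seed)
    return BitMatrix.from_bits(bits, height, width)


def random_sequence(length: int, alphabet: Alphabet, rng) -> str:
    """Random coding sequence over the alphabet."""
    coding = alphabet.coding_blocks
    idx = rng.integers(0, len(coding), size=length)
    return "".join(coding[i].label for i in idx)


def toy_alphabet(
    base: int = 15,
    spacing: float = 5.0,
    base_mass: float = 100.0,
    seed: int | None = None,
    *,
    mass_jitter: float = 0.0,
    tolerance: float = 0.02,
    spacer_label: str | None = "Z",
) -> Alphabet:
    """Evenly spaced toy alphabet labelled A, B, C, ...

    With ``mass_jitter`` > 0 and a ``seed``, unit masses are perturbed
    uniformly while preserving a minimum pairwise gap above
    ``2 * tolerance`` (the spacing minus twice the jitter must clear it).
    """
    if mass_jitter:
        if seed is None:
            raise ConfigError("mass_jitter requires a seed")
        if spacing - 2 * mass_jitter <= 2 * tolerance:
            raise ConfigError(
                "spacing minus twice the mass jitter must exceed twice the tolerance"
            )
        plain = make_alphabet(
            base, spacing, base_mass,
            spacer_label=spacer_label, tolerance=tolerance,
        )
        rng = np.random.default_rng(seed)
        from .alphabet import Alphabet as _A, BuildingBlock

        blocks = [
            BuildingBlock(
                b.label,
                b.unit_mass + (rng.uniform(-mass_jitter, mass_jitter)
                               if b.role == "coding" else 0.0),
                b.role,
            )
            for b in plain.blocks
        ]
        return _A(blocks)
    return make_alphabet(
        base, spacing, base_mass, spacer_label=spacer_label, tolerance=tolerance
    )
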