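"""End-to-end write -> simulate -> read -> decode round trips.

The full channel a stored payload travels: encode the bits into an
unordered fragment collection, simulate one MS/MS spectrum per oligomer
(the instrument analyses every oligomer separately), read each sequence
back from its spectrum, and decode the recovered collection into bits.
Per-fragment failures are reported, not fatal to the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .alphabet import Alphabet
from .coder import EncodingConfig, FragmentManifest, decode, encode
from .errors import OligoscribeError
from .massmodel import MassModel
from .reader import ReaderConfig, read_sequence
from .simulate import SimulationConfig, simulate_spectrum


@dataclass
class FragmentReport:
    """Read outcome for one written oligomer."""

    written: str
    status: str
    read: str | None
    reason: str | None = None

    @property
    def correct(self) -> bool:
        return self.status == "unique" and self.read == self.written


@dataclass
class RoundtripReport:
    """Census, per-fragment read status and bit-exactness of a round trip."""

    census: dict[int, int]
    fragments: list[FragmentReport] = field(default_factory=list)
    recovered_bits: str | None = None
    exact: bool = False
    decode_error: str | None = None

    @property
    def n_unique(self) -> int:
        return sum(1 for f in self.fragments if f.status == "unique")

    def summary(self) -> str:
        lines = [
            f"fragments written : {len(self.fragments)}",
            f"length census     : {self.census}",
            f"unique reads      : {self.n_unique}/{len(self.fragments)}",
            f"bit-exact recovery: {self.exact}",
        ]
        if self.decode_error:
            lines.append(f"decode error      : {self.decode_error}")
        return "\n".join(lines)


def roundtrip(
    bits: str,
    enc_cfg: EncodingConfig,
    model: MassModel,
    *,
    reader_cfg: ReaderConfig | None = None,
    sim_cfg: SimulationConfig | None = None,
    seed: int = 0,
) -> RoundtripReport:
    """Run the whole channel on a bit string and report what survived.

    Sequence lengths are supplied to the reader per fragment, as in
    practice: the written collection's lengths are known at synthesis
    time.  ``seed`` derives one independent simulation seed per fragment.
    """
    alphabet = enc_cfg.alphabet
    reader_cfg = reader_cfg or ReaderConfig()
    sim_cfg = sim_cfg or SimulationConfig()

    manifest = encode(bits, enc_cfg)
    report = RoundtripReport(census=manifest.census())

    observed: list[str] = []
    for i, seq in enumerate(manifest.sequences):
        per = replace(sim_cfg, seed=(seed * 100003 + i * 7919 + sim_cfg.seed) % (2**31))
        spectrum = simulate_spectrum(seq, alphabet, model, per)
        try:
            result = read_sequence(spectrum, alphabet, model, len(seq), reader_cfg)
        except OligoscribeError as exc:
            report.fragments.append(
                FragmentReport(written=seq, status="failed", read=None, reason=str(exc))
            )
            continue
        report.fragments.append(
            FragmentReport(
                written=seq,
                status=result.status,
                read=result.sequence,
                reason=result.reason,
            )
        )
        if result.status == "unique":
            observed.append(result.sequence)

    try:
        report.recovered_bits = decode(
            FragmentManifest(sequences=observed), enc_cfg
        )
        report.exact = report.recovered_bits == bits
    except OligoscribeError as exc:
        report.decode_error = str(exc)
    return report
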