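"""Sequence one oligomer de novo from a simulated MS/MS spectrum.

Simulates the fragment spectrum of a hexamer with realistic blemishes
(one missing ladder peak, sub-threshold noise, m/z jitter) and
reconstructs the sequence by walking both fragment ladders.
"""

import oligoscribe as og

alphabet = og.reference_alphabet()
model = og.reference_mass_model()
seq = "CHEMIE"

sim = og.SimulationConfig(
    delete=(("prefix", 3),),   # one interior start-containing peak is absent
    n_noise_peaks=40,          # uniform noise below the S/N threshold
    jitter=0.008,              # m/z error < tolerance/2
    seed=12,
)
spectrum = og.simulate_spectrum(seq, alphabet, model, sim)
print(f"peaks in spectrum : {len(spectrum)} (precursor {spectrum.precursor_mz:.3f})")

result = og.read_sequence(spectrum, alphabet, model, length=6)
print(f"status            : {result.status}")
print(f"sequence          : {result.sequence}")
print(f"evidence          : {result.evidence}")
# 'both' means the position was confirmed by the left (start-containing)
# and right (stop-containing) ladder walks; the position whose prefix peak
# was deleted is still pinned by the intact suffix ladder.
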