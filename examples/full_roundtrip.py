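"""The whole channel: bits -> oligomers -> spectra -> sequences -> bits.

Encodes a random 33x33 bit matrix, simulates one MS/MS spectrum per
oligomer (with jitter and noise), reads every sequence back and decodes
the recovered collection.  Prints the per-stage outcome.
"""

import oligoscribe as og

matrix = og.random_matrix(33, 33, seed=5)
bits = matrix.flatten()

report = og.roundtrip(
    bits,
    og.reference_encoding_config(),
    og.reference_mass_model(),
    sim_cfg=og.SimulationConfig(jitter=0.008, n_noise_peaks=25),
    seed=5,
)
print(report.summary())
# 71/71 unique reads and bit-exact recovery means every oligomer's
# sequence was reconstructed without ambiguity and the reassembled bit
# string equals the original 1089-bit grid.
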