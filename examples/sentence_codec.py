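"""The human-readable codec: one position-prefixed oligomer per word.

Shows why the sentence needs 19 distinct building blocks, and that word
order survives an unordered collection via the position prefixes.
"""

import random

import oligoscribe as og

words = "TO WRITE OR NOT TO WRITE ON OLIGOS?".split()
symbols = og.required_alphabet(words)
print(f"words             : {words}")
print(f"blocks needed     : {len(symbols)} -> {''.join(sorted(symbols))}")

manifest = og.encode_text(words)
print(f"oligomers         : {manifest.sequences}")
print(f"lengths           : {[len(s) for s in manifest.sequences]}")

shuffled = list(manifest.sequences)
random.Random(3).shuffle(shuffled)
decoded = og.decode_text(og.FragmentManifest(sequences=shuffled))
print(f"decoded sentence  : {' '.join(decoded)}")
# Each distinct letter, position digit and the question mark consumes one
# building block, which is why this scheme does not scale past short
# sentences — the bit-level codec exists for everything else.
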