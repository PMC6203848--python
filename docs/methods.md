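# Methods

## Mass and fragmentation model

An oligomer is modelled as `α | b_1 … b_L | ω`: an α-end linker residue
(acid or alcohol, mass `alpha_mass`), `L` building-block units, and an
ω-end thiolactone-derived stop group (`omega_mass`).  All masses are
monoisotopic; an average-mass mode is deliberately absent because the
intended read-out (MALDI-TOF/TOF, positive mode) resolves monoisotopic
peaks.  Ions are singly charged sodium adducts by default; `charge` is a
model parameter so ESI data remain usable, and the observed precursor is
`(alpha + Σ u(b_i) + omega + adduct) / charge`.

Backbone urethane cleavage produces one start-containing and one
stop-containing fragment per internal bond.  Which chemical moiety each
side retains after cleavage is chemistry- and instrument-specific, so the
model carries two free offsets: a start-containing fragment covering
units 1..i has mass `alpha + Σ_{k≤i} u(b_k) + delta_left + adduct`, and
symmetrically for the stop side with `delta_right`.  Both fragment series
are assumed to carry the same adduct as the precursor (per-series adducts
would be a config extension).  Two consequences are load-bearing and are
asserted as properties in the test suite:

- successive prefix differences reproduce the unit masses in order,
  successive suffix differences in reverse order (to 1e-9 Da — the sums
  are floating-point);
- complementarity: `p_i + s_{L−i} − precursor·charge` is the constant
  `delta_left + delta_right + adduct` for every cleavage site.

The true numeric end-group/offset values for any real chemistry live in
instrument calibration data; they are *configuration* here (alphabet TSV +
flat key:value model file, see `oligoscribe/data/`).  The shipped
reference model (`alpha 100, omega 50, delta_left 1, delta_right 2,
Na adduct`) is schematic, with one deliberate property: combined with the
evenly spaced reference alphabet (A..O at 100–170 Da, 5 Da spacing,
spacer Z at 90 Da), the prefix, suffix and precursor mass families fall on
distinct offsets of the 5-Da lattice, so one series can never shadow
another during a ladder walk.

## Reader

Inputs: peak list, alphabet, mass model, and the oligomer length `L`
(known at synthesis time; an experimental length-from-precursor estimator
was considered and rejected to keep the contract honest).  Pipeline:

1. **S/N filter** — keep peaks with `intensity / noise > snr_min`
   (default 5).  If the input format carries no noise estimate, the median
   peak intensity is used and recorded, making the filter idempotent.
2. **Anchors** — peaks matching `alpha + u(b) + delta_left + adduct`
   (left) or `omega + u(b) + delta_right + adduct` (right).  An anchor
   keeps every label whose theoretical mass it matches: ambiguity
   propagates instead of being resolved silently.
3. **Ladder walks** — from the measured anchor peak, repeatedly test
   `m + u(b)` for every block against the peak list within tolerance
   (nearest peak within the window; a near-tie logs a warning).  Each step
   re-anchors on the *measured* peak so jitter does not accumulate.  A
   missing rung is bridged by a two-unit jump `m + u(b1) + u(b2)` when all
   pair hits land on one peak — this usually leaves the order of the two
   spanned positions ambiguous, which the opposite walk resolves.  The
   same bridge recovers a missing *first* rung, so a spectrum lacking its
   smallest fragment peak still anchors that series; that is the package's
   resolution of requiring both anchors while tolerating any single
   missing peak.  At most one consecutive missing rung is bridged
   (`max_missing_per_position = 1`); a longer gap halts the walk —
   partial results are legitimate.
4. **Merge** — positions claimed by both walks must agree exactly (label
   equality, no re-derivation from masses); positions claimed by one walk
   are accepted; uncovered or multi-candidate positions make the read
   `ambiguous` (with candidate sets; a single uncovered position also gets
   candidates inferred from the residual precursor mass).  A unique read
   is finally checked against the precursor m/z within tolerance.

Tolerance is absolute (0.02 Da default), following the instrument
acceptance rule the read-out was operated under; a ppm mode is available.
Soundness needs the alphabet's minimum pairwise mass gap to exceed twice
the tolerance — checked at read time, and the spectrum jitter must stay
within ±tolerance/2 for exact reads (each walk step compares two jittered
peaks).  Intensity is never used beyond S/N: no tie-breaking heuristics.
A read costs O(L·B·log P); the empirical linearity in `L` is asserted in
the suite up to L = 64.

## Encoder layouts

Base conversion is one global big-integer conversion with width fixed by
the bit count (`D = min{d : B^d ≥ 2^n}`), not per-block: leading zeros
survive because `n` is recorded.  Three field layouts share the
dereplicate/sort/verify-contiguity/trim decode path:

- **dedicated** (default): fixed-width index prepended to every data
  fragment; one variable-length trailing fragment at the next index holds
  the digits of `n`.  Stateless parsing; the length record must fit one
  fragment.
- **replicated**: fixed-width index plus a fixed-width copy of `n` in
  every fragment; replicas must agree at decode time.
- **header** (the *reference* layout): every data fragment carries a fixed
  payload of `capacity − 2` digits; indices are minimal-width (one digit
  below the base, two digits above, the two-digit values offset by
  `B·(h−1)` so a fragment's first digit is `< h` exactly when it is a
  header fragment); the `h`-digit length field rides one digit per
  fragment on fragments `0..h−1`; and a single-unit oligomer records `h`
  itself, making the collection self-describing.

The header layout is calibrated so that a 1089-bit payload (33×33 grid)
under the reference configuration (B = 15, capacity 6, h = 4) becomes
exactly 71 oligomers with length census {1: 1, 5: 11, 6: 59} for *any*
input bits: 1089 bits → 279 digits → 70 data fragments of 4 payload
digits (the last padded with one spacer), of which 4 are length-carrying
hexamers, 11 have one-digit indices (pentamers) and 55 have two-digit
indices (hexamers), plus the header monomer.  The published collection
this census mirrors was not accompanied by a field-layout specification,
so the layout above is this package's own design, constrained by that
census rather than derived from it.  Inputs too small to host the header
(fewer than `h` fragments) are rejected; the dedicated layout covers
arbitrary sizes.

Spacer padding uses a dedicated non-coding block so trimming needs no
arithmetic; a spacer anywhere but the payload tail is corruption.  Decode
errors are specific: missing indices are listed, index conflicts, absent
length records and payload values exceeding `2^n` are distinguished.

The text codec (one position-prefixed oligomer per word, single decimal
prefixes) is kept as the human-readable counterpart; >9 words require an
explicit multi-digit option whose known limitation — words starting with
digits parse ambiguously — is documented in the module.

## Synthetic data generator

`simulate_spectrum` emits the theoretical ladder peaks plus precursor,
with (a) per-peak dropout or explicit deletions, (b) uniform noise peaks
inside the spectrum's m/z span, (c) uniform m/z jitter bounded by
±`jitter`, and (d) constant signal intensity — schematic on purpose,
since the reader consumes intensity only through S/N.  Noise intensities
default to below the S/N threshold (0.5–4.5 on a noise floor of 1 against
`snr_min` 5) so the clean-channel guarantee is testable; raising the range
exercises ambiguity reporting.  Everything is deterministic under a seed;
one draw is consumed per ladder peak whether or not it is deleted, so
explicit deletions do not shift the rest of the pattern.

What the generator does *not* emulate — isotope envelopes, multiply
charged species, in-source fragmentation, intensity physics, calibration
drift — bounds what passing tests show about real data: they validate the
algorithms' logic under the stated error model (bounded jitter, missing
peaks, sub-threshold noise), not instrument robustness.

## Problem sizes and numerical choices

The test suite runs the codec exhaustively over all bit strings up to 12
bits for bases 2, 3 and 15, randomized to 10⁴ bits; clean-channel read
correctness over 1000 random oligomers (L 3–8, B 15); single-peak-dropout
robustness over every deletable peak of an octamer; and full 33×33
round trips — sizes chosen to exercise every code path while keeping the
whole suite in the seconds range.  Ties in peak matching take the nearer
peak and log a warning; equal-spacing alphabets make two-unit bridge sums
collide by construction, which is why bridges return candidate *sets* and
the merger insists on cross-walk agreement.  Known limitations: no
mixture/LC-MS/MS deconvolution (one spectrum per oligomer), no
error-correcting redundancy across fragments beyond duplication, and no
recovery when both walks lose two consecutive rungs in the same region.
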