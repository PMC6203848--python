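"""Human-readable text on oligomers: one word per sequence.

Each word of a sentence becomes one oligomer whose flags are the characters
of the word, prefixed by the word's 1-based position in the sentence so the
unordered collection of oligomers can be put back in reading order.  Every
distinct character (letters, position digits, punctuation) needs its own
building block, which is why this scheme does not scale beyond short
sentences — it exists as the simple, human-readable counterpart of the
bit-level codec in :mod:`oligoscribe.coder`.

Position prefixes are single decimal symbols ("1" .. "9") by default;
sentences longer than nine words require ``multidigit=True``, with the
caveat that words *starting* with a digit then become ambiguous.
"""

from __future__ import annotations

from .alphabet import Alphabet
from .coder import FragmentManifest
from .errors import ConflictError, DataError, MissingFragmentError, ResolutionError

_DIGITS = set("0123456789")


def _prefixed(words, multidigit: bool) -> list[str]:
    words = list(words)
    if len(words) > 9 and not multidigit:
        raise DataError(
            f"{len(words)} words exceed single-digit position prefixes; "
            "pass multidigit=True"
        )
    return [f"{k}{word}" for k, word in enumerate(words, start=1)]


def required_alphabet(words, *, multidigit: bool = False) -> set[str]:
    """Distinct symbols needed to write the position-prefixed sentence."""
    return set("".join(_prefixed(words, multidigit)))


def encode_text(
    words,
    char_alphabet: Alphabet | None = None,
    *,
    multidigit: bool = False,
) -> FragmentManifest:
    """One oligomer per word: flags are ``str(position) + word``.

    With ``char_alphabet`` given, every character is checked to have a
    building block; unmapped characters raise naming the character and word.
    """
    prefixed = _prefixed(words, multidigit)
    if char_alphabet is not None:
        for word in prefixed:
            for ch in word:
                if ch not in char_alphabet:
                    raise ResolutionError(
                        f"character {ch!r} of word {word!r} has no building block"
                    )
    return FragmentManifest(sequences=prefixed, meta={"codec": "text"})


def decode_text(
    manifest: FragmentManifest,
    char_alphabet: Alphabet | None = None,
    *,
    multidigit: bool = False,
) -> list[str]:
    """Inverse of :func:`encode_text`: strip prefixes, sort, return words."""
    table: dict[int, str] = {}
    for seq in set(manifest.sequences):
        if char_alphabet is not None:
            for ch in seq:
                if ch not in char_alphabet:
                    raise ResolutionError(
                        f"character {ch!r} of fragment {seq!r} has no building block"
                    )
        if not seq or seq[0] not in _DIGITS:
            raise DataError(f"fragment {seq!r} does not start with a position digit")
        if multidigit:
            i = 0
            while i < len(seq) and seq[i] in _DIGITS:
                i += 1
            pos, word = int(seq[:i]), seq[i:]
        else:
            pos, word = int(seq[0]), seq[1:]
        if pos == 0:
            raise DataError(f"fragment {seq!r} has position 0; positions are 1-based")
        if pos in table and table[pos] != word:
            raise ConflictError(
                f"two different words claim position {pos}: "
                f"{table[pos]!r} and {word!r}"
            )
        table[pos] = word
    if not table:
        return []
    gaps = set(range(1, max(table) + 1)) - set(table)
    if gaps:
        raise MissingFragmentError(gaps)
    return [table[k] for k in sorted(table)]
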