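"""Exception hierarchy.

Two broad classes matter to callers (and to the CLI exit codes): problems
with the *configuration* (bad alphabet, impossible layout) and problems
with the *data* (unreadable manifest, corrupt payload, unmatchable peaks).
"""


class OligoscribeError(Exception):
    """Base class for all package errors."""


class ConfigError(OligoscribeError):
    """Invalid or inconsistent configuration (CLI exit code 2)."""


class DataError(OligoscribeError):
    """Invalid or corrupt input data (CLI exit code 1)."""


class ResolutionError(DataError):
    """A sequence label cannot be resolved in the alphabet."""


class FormatError(DataError):
    """A file or string does not conform to its expected format."""


class CapacityError(DataError):
    """Input too large for the configured index/field space."""


class CorruptionError(DataError):
    """Decoded payload is inconsistent with its length record."""


class MissingFragmentError(DataError):
    """Fragment indices are not contiguous.

    ``gaps`` lists the missing indices.
    """

    def __init__(self, gaps):
        self.gaps = sorted(gaps)
        super().__init__(f"missing fragment index(es): {self.gaps}")


class ConflictError(DataError):
    """Two distinct fragments claim the same index/position."""


class AnchorMissingError(DataError):
    """A required fragment-series anchor is absent from the spectrum.

    ``side`` names the missing series ("left" or "right").
    """

    def __init__(self, side):
        self.side = side
        super().__init__(f"no {side} anchor found in spectrum")
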