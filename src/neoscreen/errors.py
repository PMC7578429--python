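"""Exception hierarchy shared across the package.

Every error raised by neoscreen derives from :class:`NeoscreenError` so that
callers can catch pipeline failures with a single except clause while still
discriminating the specific failure mode.
"""


class NeoscreenError(Exception):
    """Base class for all neoscreen errors."""


class MalformedAllotype(NeoscreenError, ValueError):
    """An HLA allotype name could not be parsed at four-digit resolution."""


class FormatError(NeoscreenError, ValueError):
    """An input table or stream does not conform to the expected dialect."""


class RangeError(NeoscreenError, ValueError):
    """A numeric field is outside its permitted range (e.g. %rank not in [0, 100])."""


class EmptyPanel(NeoscreenError, ValueError):
    """An operation requiring a non-empty haplotype panel received an empty one."""


class UnparseableSubstitution(NeoscreenError, ValueError):
    """An amino-acid change string is not a simple missense substitution."""


class MissingRecord(NeoscreenError, KeyError):
    """A required (peptide, allotype) rank record is absent from the store."""


class MissingAllotypeBR(MissingRecord):
    """A BR value needed for an individual's allotype is absent from the table."""


class UnsupportedAllotype(NeoscreenError, ValueError):
    """Requested allotypes are outside the predictor's supported library."""

    def __init__(self, allotypes):
        self.allotypes = sorted(str(a) for a in allotypes)
        super().__init__(f"allotypes not in predictor library: {', '.join(self.allotypes)}")


class DomainError(NeoscreenError, ValueError):
    """A score input violates its mathematical domain (e.g. non-positive BR)."""


class EmptyInput(NeoscreenError, ValueError):
    """A reduction over an empty collection was requested."""


class DegenerateInput(NeoscreenError, ValueError):
    """A statistical test received data it cannot discriminate (all values equal)."""


class AllZeroDifferences(DegenerateInput):
    """A paired test where every within-pair difference is zero."""


class MissingStratum(NeoscreenError, KeyError):
    """A resampling stratum requested in the target proportions has no source values."""


class InvalidSpectrum(NeoscreenError, ValueError):
    """An allele-frequency spectrum is not a valid per-locus distribution."""
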