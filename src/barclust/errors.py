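"""Exception hierarchy.

Every user-facing validation failure raises a distinct, named error so that
callers (and the CLI) can report precisely what was wrong with an input.
"""


class BarclustError(Exception):
    """Base class for all errors raised by this package."""


class DesignError(BarclustError):
    """Invalid library design."""


class MultiRecordFastaError(DesignError):
    """Reference FASTA must contain exactly one record."""


class IntervalBoundsError(DesignError):
    """A barcode locus or ORF interval falls outside the reference."""


class OrfFrameError(DesignError):
    """ORF length is not divisible by 3."""


class DesignOverlapError(DesignError):
    """Barcode loci and ORF interval must be pairwise disjoint."""


class LocusOrderError(DesignError):
    """With two barcode loci, the upstream locus must start first."""


class ReverseStrandError(DesignError):
    """Only forward-strand ORFs are supported."""


class ConfigError(BarclustError):
    """Invalid run or simulation parameters."""


class FastqFormatError(BarclustError):
    """Malformed FASTQ record; carries the 0-based index of the bad record."""

    def __init__(self, record_index: int, message: str):
        self.record_index = record_index
        super().__init__(f"record {record_index}: {message}")


class SchemaError(BarclustError):
    """A tabular input does not match the documented schema."""


class TwoLociRequiredError(BarclustError):
    """Chimera detection requires a design with two barcode loci."""
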