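"""Exception hierarchy shared across the package."""


class SeedbandError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SeedbandError, ValueError):
    """Malformed input data (FASTA/FASTQ/TSV parsing problems)."""


class ParameterError(SeedbandError, ValueError):
    """A configuration parameter is outside its valid domain."""


class InputError(SeedbandError, ValueError):
    """An argument to an operation violates its contract."""
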