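"""Exception hierarchy shared across the pipeline."""


class S1CensusError(Exception):
    """Base class for all package errors."""


class FormatError(S1CensusError):
    """A file does not conform to its expected format (FASTA/TSV layout)."""


class ValidationError(S1CensusError):
    """Parsed content violates a domain invariant (alphabet, boundaries, config)."""


class InsufficientDataError(S1CensusError):
    """An operation requires more records than the group contains."""
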