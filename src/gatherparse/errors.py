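"""Exception hierarchy."""


class GatherparseError(Exception):
    """Base class for package errors."""


class FormatError(GatherparseError):
    """Input file does not have the expected structure."""


class NetworkError(GatherparseError):
    """A download failed; the operation may be retried."""


class ContractError(GatherparseError):
    """A function precondition was violated."""
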