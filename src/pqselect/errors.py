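"""Exception hierarchy shared across the package.

``PQSError`` is the base for everything the pipeline raises on purpose, so a
caller (notably the CLI) can distinguish data problems from genuine bugs.
"""


class PQSError(Exception):
    """Base class for all pipeline errors."""


class FormatError(PQSError):
    """An on-disk file violates the expected dialect (bad token, duplicate
    accession, negative intensity, ...)."""


class ModelContractError(PQSError):
    """A pluggable cleavage model returned a value outside [0, 1]."""
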