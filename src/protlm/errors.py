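"""Exception hierarchy.

Every error raised deliberately by this package derives from
:class:`ProtlmError`, so callers can catch the package's failures without
swallowing genuine bugs.
"""


class ProtlmError(Exception):
    """Base class for all protlm errors."""


class ParameterError(ProtlmError, ValueError):
    """An argument violates an operation's precondition."""


class FastaFormatError(ProtlmError, ValueError):
    """The input is not well-formed FASTA."""


class DuplicateIdError(FastaFormatError):
    """Two records in one corpus share an identifier."""


class SanitizationError(ProtlmError, ValueError):
    """A residue string cannot be sanitized under the active policy."""


class UndefinedContextError(ProtlmError, LookupError):
    """A conditional probability was requested for a context with zero
    count under pure maximum-likelihood estimation (no smoothing)."""


class TooShortError(ProtlmError, ValueError):
    """A sequence is shorter than the model order and the scoring mode
    provides no lower-order fallback."""


class ModelConfigError(ProtlmError, ValueError):
    """Two models that must agree (order, smoothing, alphabet) do not."""


class SchemaError(ProtlmError, ValueError):
    """A serialized model file is missing fields, carries an unsupported
    schema version, or violates a count invariant."""


class ReducibleChainError(ProtlmError, ValueError):
    """The context process of a Markov chain specification is not
    irreducible over its reachable contexts."""
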