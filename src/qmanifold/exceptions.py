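"""Exception hierarchy for qmanifold."""


class QManifoldError(Exception):
    """Base class for all qmanifold errors."""


class GroupNotFoundError(QManifoldError, KeyError):
    """A requested group label is not present in the response table."""


class EmptyGroupError(QManifoldError, ValueError):
    """A group exists but contains no respondents."""


class SchemaMismatchError(QManifoldError, ValueError):
    """Two objects do not share the same question set / answer alphabets."""


class AnswerDomainError(QManifoldError, ValueError):
    """An answer code is not a member of its question's alphabet."""


class SizeLimitError(QManifoldError, ValueError):
    """Materialising the joint distribution would exceed the configured cap."""


class NumericDomainError(QManifoldError, ValueError):
    """A numeric input lies outside its mathematically valid domain."""


class DimensionError(QManifoldError, ValueError):
    """A requested dimension is incompatible with the data."""


class DegenerateInputError(QManifoldError, ValueError):
    """An input is degenerate (zero variance, NaN probabilities, ...)."""
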