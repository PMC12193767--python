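"""Exception hierarchy for cwqsar."""


class CWQSARError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CWQSARError, ValueError):
    """Input violates a precondition (empty string, too few records, ...)."""


class MalformedSMILESError(CWQSARError, ValueError):
    """SMILES string cannot be tokenized (unbalanced brackets, stray characters)."""


class SchemaError(CWQSARError, ValueError):
    """Input table is missing required columns."""


class DuplicateIDError(CWQSARError, ValueError):
    """Two records share the same identifier."""


class UndefinedStatisticError(CWQSARError, ArithmeticError):
    """A statistic is undefined for the given series (e.g. constant observed values)."""


class OptimizationImpossibleError(CWQSARError, RuntimeError):
    """No non-blocked attributes are available to optimize."""


class GenerationError(CWQSARError, RuntimeError):
    """Synthetic fixture generation cannot satisfy the requested constraints."""
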