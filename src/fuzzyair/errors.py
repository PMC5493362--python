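"""Exception hierarchy for fuzzyair."""


class FuzzyAirError(Exception):
    """Base class for all fuzzyair errors."""


class InvalidInputError(FuzzyAirError, ValueError):
    """A crisp input is non-finite, missing, or out of its valid domain."""


class ConfigurationError(FuzzyAirError, ValueError):
    """A system, variable, rule base or generator spec violates an invariant."""


class DegenerateAggregationError(FuzzyAirError, ArithmeticError):
    """No rule fired: the aggregated output set is identically zero."""


class UndefinedCorrelationError(FuzzyAirError, ArithmeticError):
    """Pearson correlation is undefined (too few pairs or zero variance)."""


class UndefinedROCError(FuzzyAirError, ArithmeticError):
    """ROC analysis is undefined (labels contain a single class)."""
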