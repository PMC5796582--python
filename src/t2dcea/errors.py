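"""Exception types shared across the package."""


class T2DCEAError(Exception):
    """Base class for all package errors."""


class ValidationError(T2DCEAError, ValueError):
    """A configuration or parameter value violates a model invariant.

    The message names the offending field.
    """


class InfeasibleParametersError(T2DCEAError, ValueError):
    """A parameter combination produces an invalid transition matrix
    (e.g. a negative stay-probability when failure + death exceed 1)."""


class ContractError(T2DCEAError, ValueError):
    """An operation was called outside its documented preconditions."""
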