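"""Exception hierarchy shared across springdiv modules."""


class SpringdivError(Exception):
    """Base class for all springdiv errors."""


class InvalidParameterError(SpringdivError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(SpringdivError, ValueError):
    """Input data violates a documented precondition."""


class ConsistencyError(SpringdivError, ValueError):
    """Two inputs that must agree (e.g. records and their assignments) do not."""


class InsufficientDataError(SpringdivError, ValueError):
    """Fewer observations than the statistic requires."""


class DegenerateDesignError(SpringdivError, ValueError):
    """The design matrix of a fit has no usable variation."""


class UndefinedResultError(SpringdivError, ValueError):
    """The requested statistic is undefined for this input (e.g. no alignable pairs)."""


class NewickParseError(SpringdivError, ValueError):
    """Malformed newick input; the message carries position information when known."""
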