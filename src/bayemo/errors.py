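"""Exception hierarchy.

All bayemo errors derive from :class:`BayemoError` so callers can catch the
package's failures with a single ``except`` clause; each subclass also derives
from the closest built-in (``ValueError`` for bad numbers, etc.) so code that
never imports this module still fails in the conventional way.
"""


class BayemoError(Exception):
    """Base class for all bayemo errors."""


class InvalidParameterError(BayemoError, ValueError):
    """A numeric argument violates its domain (e.g. non-positive variance)."""


class DegenerateInputError(BayemoError, ValueError):
    """Inputs are individually valid but jointly degenerate.

    Example: asking for the crossover of two identical uncertainty levels —
    the two gain curves coincide everywhere, so no crossover is defined.
    """


class ConstraintViolationError(BayemoError, ValueError):
    """A valence-parameter constraint is violated; the message names it."""


class ConfigurationError(BayemoError, ValueError):
    """A configuration mapping is inconsistent (ordering constraints etc.)."""


class DegenerateDataError(BayemoError, ValueError):
    """A data slice carries no variance, so the requested test is undefined."""


class UnbalancedDesignError(BayemoError, ValueError):
    """A repeated-measures table is missing subject × cell combinations."""


class EmptyGroupError(BayemoError, ValueError):
    """A grouping operation produced an empty group (e.g. all epochs rejected)."""


class NoUniqueOptimumError(BayemoError, RuntimeError):
    """The objective is flat over the search interval; no argmax is defined."""
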