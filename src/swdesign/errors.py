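"""Exception hierarchy.

All package errors derive from :class:`SWDesignError` so callers (and the CLI,
which maps them to exit codes) can distinguish bad inputs, statistically
degenerate designs, numerical trouble in the incremental caches, and searches
that have run out of moves.
"""


class SWDesignError(Exception):
    """Base class for all swdesign errors."""


class InvalidDesignError(SWDesignError, ValueError):
    """A design or scenario violates a structural constraint."""


class DesignFileError(InvalidDesignError):
    """A design CSV file could not be parsed or failed validation."""


class IdentifiabilityError(SWDesignError, ValueError):
    """The treatment effect is not estimable under this design/model.

    Raised when the GLS information matrix is singular, e.g. because the
    treatment indicator is confounded with the polynomial time effect.
    """


class NumericError(SWDesignError, ArithmeticError):
    """An incremental update produced an impossible quantity (broken cache)."""


class SearchExhaustedError(SWDesignError, RuntimeError):
    """No feasible move remains (design complete/empty or all moves degenerate)."""
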