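"""Exception hierarchy.

All tool-specific failures derive from :class:`TopofillError` so callers (and
the CLI) can distinguish data/validation problems (exit 2) from solver
timeouts (exit 3).
"""


class TopofillError(Exception):
    """Base class for all topofill errors."""


class NetworkParseError(TopofillError):
    """A network file could not be parsed (malformed XML, bad id list)."""


class NetworkValidationError(TopofillError):
    """Parsed content violates a structural invariant."""


class MergeConflictError(TopofillError):
    """Two networks define the same reaction id with different content."""

    def __init__(self, conflicting_ids):
        self.conflicting_ids = sorted(conflicting_ids)
        super().__init__(
            "conflicting definitions for reaction id(s): "
            + ", ".join(self.conflicting_ids)
        )


class SolverTimeout(TopofillError):
    """The completion solver exceeded its time budget.

    ``best_bound`` carries the best lower bound on the optimum found so far
    (None when no bound was established).
    """

    def __init__(self, message, best_bound=None):
        self.best_bound = best_bound
        super().__init__(message)


class NonFunctionalModelError(TopofillError):
    """Reaction classification was requested on a model whose objective
    cannot reach the required flux floor; run ``fba_max`` first."""
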