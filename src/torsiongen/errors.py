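"""Exception hierarchy for the toolkit.

Every error raised by the library derives from :class:`ToolkitError`, so callers
(including the CLI) can distinguish toolkit validation failures from bugs.
"""


class ToolkitError(Exception):
    """Base class for all toolkit errors."""


class FormatError(ToolkitError):
    """A file could not be parsed (carries a line number where possible)."""


class ValidationError(ToolkitError):
    """An input violated a documented invariant (bad index, negative sigma, ...)."""


class ConnectivityError(ToolkitError):
    """The bond graph is not a single connected component."""


class DegenerateGeometryError(ToolkitError):
    """Coincident or collinear atoms where a well-defined axis/plane is required."""


class ConvergenceError(ToolkitError):
    """An iterative solver failed to converge within its budget."""


class SingularityError(ToolkitError):
    """A potential was evaluated at a singular point (r = 0 with no soft core)."""


class ContractError(ToolkitError):
    """An external callable violated its declared interface contract."""


class TrainingDivergenceError(ToolkitError):
    """A training loss or energy became non-finite."""


class UsageError(ToolkitError):
    """Invalid user-facing arguments (unknown fixture kind, bad subcommand...)."""
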