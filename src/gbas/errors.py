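"""Exception hierarchy for the gbas package.

All exceptions derive from :class:`GbasError` so callers can catch the
package's failures with one clause; most also derive from ``ValueError``
because they signal invalid inputs.
"""


class GbasError(Exception):
    """Base class for all gbas errors."""


class InvalidInputError(GbasError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(GbasError, ValueError):
    """Too few samples/replicates to perform the requested computation."""


class MissingDataError(GbasError, ValueError):
    """A required field (e.g. round-1 screening rate) is absent."""


class InvalidScheduleError(GbasError, ValueError):
    """Injection/connection events are out of order or inconsistent."""


class IncompatibleSchedulesError(GbasError, ValueError):
    """Two traces that must share a schedule do not."""


class UndefinedRatioError(GbasError, ValueError):
    """Current ratio requested with a non-positive denominator or numerator."""


class FitError(GbasError, RuntimeError):
    """Nonlinear fit failed to converge or the design is degenerate."""


class DomainError(GbasError, ValueError):
    """Argument outside the mathematical domain of a model equation."""


class NoFuelError(GbasError, ValueError):
    """Fuel-cell limiting current is non-positive (no enzymatic turnover)."""


class AnnotationGapError(GbasError, ValueError):
    """A site position lacks a secondary-structure annotation."""


class ConfigError(GbasError, ValueError):
    """Run configuration is malformed or infeasible."""
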