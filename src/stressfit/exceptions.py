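"""Exception hierarchy for the stressfit pipeline.

Every error raised on purpose by this package derives from
:class:`StressFitError`, so callers (and the CLI) can catch one type.
"""


class StressFitError(Exception):
    """Base class for all stressfit errors."""


class InvalidArgumentError(StressFitError, ValueError):
    """An argument is non-finite, empty, mis-shaped or otherwise unusable."""


class GeometryError(InvalidArgumentError):
    """Specimen geometry is physically impossible (L <= 0, S <= 0, ...)."""


class DegenerateDataError(StressFitError):
    """The data cannot identify the model (constant signal, rank-deficient basis)."""


class FitConvergenceError(StressFitError):
    """Nonlinear least squares failed after all restarts.

    Carries optimizer diagnostics in :attr:`diagnostics`.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NonLinearStretchError(StressFitError):
    """Stretch is not linear in time, so the stretch-domain transform is undefined."""


class DegenerateStretchError(StressFitError):
    """Stretch does not change with time (D1 = 0); no stretch-domain model exists."""


class NoCyclesError(StressFitError):
    """No loading/unloading structure could be detected in the stress trace."""


class TraceFormatError(StressFitError):
    """An input CSV is malformed (missing column, bad dialect)."""


class TraceOrderingError(TraceFormatError):
    """Sample times in an input trace are not strictly increasing."""


class InconsistentSpecError(StressFitError):
    """A synthetic test specification requires a junction offset above the allowed limit."""
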