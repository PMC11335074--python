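"""Exception hierarchy shared by all casite modules."""


class CasiteError(Exception):
    """Base class for all casite errors."""


class InvalidCoordinateError(CasiteError):
    """A coordinate is non-finite or otherwise unusable."""


class EmptyInputError(CasiteError):
    """An operation received an empty bundle, table or series."""


class DomainError(CasiteError):
    """An argument is outside its mathematical domain."""


class UnknownPairError(CasiteError):
    """A requested (ion, group) pair is not present in the bundle."""


class AlignmentError(CasiteError):
    """Two time series that must share frames do not."""


class ConfigurationError(CasiteError):
    """A configuration object is inconsistent or incomplete."""


class LookupError_(CasiteError):
    """An id (ion, group, preset, target) is unknown."""


class FitError(CasiteError):
    """A curve fit failed to converge; carries the best residuals seen."""

    def __init__(self, message, residuals=None):
        super().__init__(message)
        self.residuals = residuals


class UnidentifiableError(FitError):
    """The data cannot constrain the model (e.g. constant response)."""


class DegenerateSeriesError(CasiteError):
    """Normalization is impossible (zero control amplitude)."""


class InsufficientPairsError(CasiteError):
    """Fewer than two oocytes are present in both arms of a paired design."""


class DegenerateTestError(CasiteError):
    """A statistical test has zero variance where variance is required."""


class ScheduleError(CasiteError):
    """A perfusion schedule step is malformed (e.g. negative duration)."""
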