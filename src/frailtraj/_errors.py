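"""Exception hierarchy shared across the package."""


class FrailtrajError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FrailtrajError):
    """Invalid configuration: proportions, hazards, thresholds, paths."""


class IncompleteDataError(FrailtrajError):
    """A required input field is missing (e.g. incomplete risk profile)."""


class DataError(FrailtrajError):
    """A data value is outside its declared domain."""


class ConvergenceError(FrailtrajError):
    """An iterative fit failed to converge; carries the best fit so far."""

    def __init__(self, message, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit
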