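"""Exception hierarchy shared across the package."""


class FjordtrackError(Exception):
    """Base class for all package errors."""


class InputError(FjordtrackError, ValueError):
    """Malformed user input (coordinates out of range, unsorted tracks, ...)."""


class ConfigurationError(FjordtrackError, ValueError):
    """Invalid or incomplete configuration (missing layers, bad thresholds, ...)."""


class DegenerateFitError(FjordtrackError, RuntimeError):
    """A model cannot be estimated from the data provided (constant response, missing cell)."""


class InternalError(FjordtrackError, RuntimeError):
    """Stage outputs that should reconcile do not; indicates a pipeline bug."""
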