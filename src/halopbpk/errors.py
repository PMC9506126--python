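"""Exception hierarchy for halopbpk."""


class HaloPBPKError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HaloPBPKError, ValueError):
    """A numeric input violates its documented domain."""


class ValidationError(HaloPBPKError, ValueError):
    """A composite object (physiology, spec, profile) fails its invariants."""


class ConfigurationError(HaloPBPKError):
    """A model assembly problem: unresolvable pathway product, missing tissue
    composition, unknown scenario id."""


class SolverError(HaloPBPKError):
    """ODE integration failed; the message names the scenario."""


class LambdaZError(HaloPBPKError):
    """Terminal slope could not be estimated (non-decaying tail)."""


class CalibrationError(HaloPBPKError):
    """A calibration target is unreachable within the allowed bracket."""


class PackagingError(HaloPBPKError):
    """Shipped fixture data failed its integrity check."""
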