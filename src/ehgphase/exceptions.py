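"""Exception types raised across the analysis pipeline."""


class EHGPhaseError(Exception):
    """Base class for all package errors."""


class ParameterError(EHGPhaseError, ValueError):
    """An argument violates a precondition (band edges, k < 2, tau < 1, ...)."""


class ParseError(EHGPhaseError, ValueError):
    """A signal file could not be parsed; the message names the offending line."""


class InsufficientLengthError(EHGPhaseError, ValueError):
    """The series is too short for the requested operation."""


class DegenerateSignalError(EHGPhaseError, ValueError):
    """The series carries no usable structure (e.g. constant, all-origin SODP)."""
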