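"""Exception hierarchy used across socekit."""


class SoceKitError(Exception):
    """Base class for all socekit errors."""


class ValidationError(SoceKitError, ValueError):
    """Invalid argument values or malformed input tables."""


class ProtocolError(SoceKitError):
    """A solution protocol lacks a segment an operation requires."""


class SimulationError(SoceKitError):
    """Numerical integration produced non-finite state."""


class WindowError(SoceKitError):
    """An analysis window does not fit into the available segment."""


class InsufficientDataError(SoceKitError):
    """Too few observations for the requested statistical test."""
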