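"""Exception hierarchy for rhythmcontrib."""


class RhythmError(Exception):
    """Base class for all package errors."""


class ParameterError(RhythmError, ValueError):
    """Invalid model parameter (non-positive spread or time constant, ...)."""


class DomainError(RhythmError, ValueError):
    """Function evaluated outside its mathematical domain."""


class IntegrationError(RhythmError):
    """Non-finite state encountered during integration."""

    def __init__(self, message: str, t: float | None = None):
        super().__init__(message)
        self.t = t


class ConvergenceError(RhythmError):
    """Settling reached its hard time cap without converging or losing rhythm."""


class AnalysisError(RhythmError):
    """Trajectory does not contain the structure an analysis needs."""


class ProtocolError(RhythmError):
    """A measurement protocol's precondition failed (e.g. no rhythm at the
    control parameters)."""


class DivergenceError(RhythmError):
    """A perturbed run never reached its phase-terminating crossing."""


class MeasureUndefinedError(RhythmError):
    """A contribution measure is undefined for the given parameters
    (e.g. the correlative index with g = 0, or a combined index whose
    denominator vanishes)."""


class GeometricInapplicableError(RhythmError):
    """The phase-plane measure cannot be evaluated: no knee exists at a
    transition, or the adaptation process is absent (g = 0)."""
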