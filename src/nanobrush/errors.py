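"""Exception types shared across the package."""


class NanobrushError(Exception):
    """Base class for package-specific failures."""


class PackingError(NanobrushError):
    """Random insertion could not place all particles within the retry budget."""


class GeometryError(NanobrushError):
    """A box or cylinder specification cannot hold the requested system."""


class BondOverstretchError(NanobrushError):
    """A FENE bond reached or exceeded its maximum extension r0."""


class IntegrationBlowupError(NanobrushError):
    """The integrator produced a non-finite coordinate or a hard-core breach.

    Carries the global step index at which the failure was detected.
    """

    def __init__(self, message: str, step: int | None = None):
        super().__init__(message)
        self.step = step


class AnalysisError(NanobrushError):
    """An observable was requested on data that cannot support it."""
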