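"""Exception hierarchy for the clperox pipeline.

All errors derive from :class:`ClperoxError` so callers can catch the
package's failures with one handler; the CLI maps data errors to exit
code 1 and configuration errors to exit code 2.
"""


class ClperoxError(Exception):
    """Base class for all clperox errors."""


class SpectralFormatError(ClperoxError, ValueError):
    """A spectral file could not be parsed (empty, malformed, duplicated times)."""


class ValidationError(ClperoxError, ValueError):
    """A constructed object violates an invariant (e.g. non-monotone times)."""


class ConfigurationError(ClperoxError, ValueError):
    """A study or simulation configuration is incomplete or inconsistent."""


class DomainError(ClperoxError, ValueError):
    """An argument is outside the mathematical domain of an operation."""


class InsufficientDataError(ClperoxError, ValueError):
    """Too few data points to perform the requested estimate."""


class WavelengthLookupError(ClperoxError, KeyError):
    """Requested wavelength is outside the recorded spectral range."""


class IntegrationError(ClperoxError, RuntimeError):
    """The kinetic integrator failed; carries the last valid state if any."""

    def __init__(self, message, last_state=None, last_time=None):
        super().__init__(message)
        self.last_state = last_state
        self.last_time = last_time


class StiffnessError(IntegrationError):
    """Trajectories went negative beyond tolerance; advise tighter tolerances."""
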