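"""Exception hierarchy for ecmbind."""


class EcmBindError(Exception):
    """Base class for all ecmbind errors."""


class ConfigurationError(EcmBindError, ValueError):
    """A configuration value or file layout is invalid (missing column, bad
    default, unknown identifier)."""


class ValidationError(EcmBindError, ValueError):
    """Input data violates a contract (negative score, duplicate key,
    malformed numeric cell).  The message names the offending row or field."""


class IntegrationError(EcmBindError, RuntimeError):
    """The ODE integrator failed or produced a trajectory violating the
    conservation/non-negativity tolerances.  Carries solver diagnostics."""
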