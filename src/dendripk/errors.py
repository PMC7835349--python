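"""Exception types shared across the package."""


class DendriPKError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DendriPKError, ValueError):
    """A parameter violates its physical constraints (sign, units, range)."""


class SingularParameterError(DendriPKError, ValueError):
    """A parameter combination makes a closed-form constant undefined."""


class UnidentifiableError(DendriPKError, ValueError):
    """The data carry no information about the parameter being estimated."""


class DataQualityError(DendriPKError, ValueError):
    """Input data violate gross plausibility checks (e.g. large non-monotone drops)."""


class OdeIntegrationError(DendriPKError, RuntimeError):
    """The numeric reference integration failed; message carries solver diagnostics."""
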