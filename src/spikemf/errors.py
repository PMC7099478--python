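"""Exception hierarchy."""


class SpikemfError(Exception):
    """Base class for all package errors."""


class ParameterError(SpikemfError, ValueError):
    """Invalid parameter value (negative rate, bad config, ...)."""


class IntegrationError(SpikemfError, RuntimeError):
    """Numerical integration produced a non-finite state."""


class FitError(SpikemfError, RuntimeError):
    """Transfer-function fit could not be performed."""


class InstabilityError(SpikemfError, RuntimeError):
    """Mean-field integration diverged."""
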