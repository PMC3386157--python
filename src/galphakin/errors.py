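"""Exception hierarchy shared across the package."""


class GalphaError(Exception):
    """Base class for all galphakin errors."""


class ValidationError(GalphaError, ValueError):
    """Invalid input data or parameters."""


class FitError(GalphaError, RuntimeError):
    """A fit could not be performed or did not converge."""


class IntegrationError(GalphaError, RuntimeError):
    """ODE integration failed; message carries solver diagnostics."""
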