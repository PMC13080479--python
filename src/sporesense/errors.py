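"""Exception types shared across the package."""


class SporeSenseError(Exception):
    """Base class for all package errors."""


class ValidationError(SporeSenseError, ValueError):
    """An input violated a documented precondition; the message names the field."""


class NonIdentifiableError(SporeSenseError, ValueError):
    """The data cannot constrain one or more model parameters."""


class ConfigurationError(SporeSenseError, ValueError):
    """A configuration object is internally inconsistent (e.g. unstable scheme)."""


class PlacementError(SporeSenseError, RuntimeError):
    """Synthetic spot placement failed after bounded retries."""
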