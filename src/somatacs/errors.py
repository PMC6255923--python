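"""Exception types shared across the package."""


class SomatacsError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SomatacsError, ValueError):
    """A configuration object violates one of its invariants."""


class EmptySelectionError(SomatacsError, LookupError):
    """A trial selection matched no trials (explicit, never silent)."""


class DegenerateDataError(SomatacsError, ValueError):
    """Input data is degenerate for the requested statistic
    (e.g. all paired differences are zero, or a zero normalization median)."""
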