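"""Exception hierarchy shared across the package."""


class MemtugError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(MemtugError):
    """A configuration file or parameter override is invalid.

    The message always names the offending field.
    """


class RegimeError(MemtugError):
    """A kinetic quantity was requested for a landscape regime that does
    not define it (e.g. an activation barrier without a transition state)."""


class NumericalError(MemtugError):
    """The stationary-point search could not resolve the landscape
    (lost bracket, unclassifiable stationary-point pattern)."""
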