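"""Exception types shared across the toolkit."""


class PaperECGError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(PaperECGError, ValueError):
    """A configuration value is invalid or inconsistent."""


class LayoutError(ConfigurationError):
    """Sheet layout cannot accommodate the requested elements."""


class InputError(PaperECGError, ValueError):
    """An input array or record does not satisfy an operation's contract."""
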