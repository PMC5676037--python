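"""Exception hierarchy shared by all pipeline stages."""


class HupmapError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(HupmapError, ValueError):
    """Input values violate a documented invariant (bad coordinates, strand, ...)."""


class ParseError(HupmapError, ValueError):
    """A tabular input file could not be parsed; the message names the line."""


class ConfigurationError(HupmapError, ValueError):
    """A required parameter is missing or inconsistent (dt <= 0, missing fold, ...)."""


class InsufficientDataError(HupmapError, ValueError):
    """Not enough observations to compute the requested statistic."""
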