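"""Exception hierarchy shared across the package."""


class TrzmirError(ValueError):
    """Base class for all package errors."""


class ConfigError(TrzmirError):
    """Invalid simulator or pipeline configuration."""


class FormatError(TrzmirError):
    """Malformed input file or sequence alphabet."""


class MetadataError(TrzmirError):
    """Sample sheet does not match the expression matrix."""


class DesignError(TrzmirError):
    """Experimental design missing a required arm (line or condition)."""


class ContractError(TrzmirError):
    """Caller violated an operation's precondition."""
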