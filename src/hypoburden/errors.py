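"""Exception types shared across the package."""


class HypoburdenError(Exception):
    """Base class for all package errors."""


class ValidationError(HypoburdenError, ValueError):
    """Raised when input data violate a structural invariant."""


class ConfigError(HypoburdenError, ValueError):
    """Raised when a simulation or rule configuration is inconsistent."""


class MissingChannelError(HypoburdenError, KeyError):
    """Raised when an operation needs an optional channel that is absent.

    The message names the missing channel so callers can report which
    monitor variable the rule required.
    """

    def __init__(self, channel: str, context: str = ""):
        self.channel = channel
        msg = f"required channel {channel!r} is not available"
        if context:
            msg += f" ({context})"
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return self.args[0]
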