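"""Exception types shared across the toolkit."""


class RenseqError(Exception):
    """Base class for all toolkit errors."""


class ParseError(RenseqError):
    """A sequence file or record violates the format contract."""


class ValidationError(RenseqError):
    """A domain object or parameter set violates its invariants."""


class ConfigError(RenseqError):
    """Pipeline configuration is invalid; carries the full error list."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in self.errors))
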