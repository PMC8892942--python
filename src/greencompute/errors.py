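"""Exception types shared across the package."""


class GreenComputeError(Exception):
    """Base class for all package errors."""


class ValidationError(GreenComputeError, ValueError):
    """An input violates a documented precondition."""


class LookupKeyError(GreenComputeError, KeyError):
    """A region/facility/processor key is not in the reference tables.

    The message always lists the valid keys.
    """

    def __init__(self, kind: str, key: str, valid: list[str]):
        self.kind = kind
        self.key = key
        self.valid = sorted(valid)
        super().__init__(
            f"unknown {kind} {key!r}; valid keys: {', '.join(self.valid)}"
        )

    def __str__(self) -> str:  # KeyError quotes its arg by default
        return self.args[0]


class DurationParseError(GreenComputeError, ValueError):
    """A runtime string does not match the duration grammar."""
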