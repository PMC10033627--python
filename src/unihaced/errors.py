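"""Exception hierarchy shared across the package."""


class UnihacedError(Exception):
    """Base class for all package-specific errors."""


class AlphabetError(UnihacedError, ValueError):
    """A sequence contains a character outside the expected alphabet."""


class ContractError(UnihacedError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class ParseError(UnihacedError, ValueError):
    """A file could not be parsed as the expected format."""
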