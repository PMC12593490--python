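"""Exception hierarchy.

``ContractError`` marks violated preconditions (caller bugs, bad parameters);
``FormatError`` marks malformed on-disk artifacts. The CLI maps both to exit
code 2, everything else to 1.
"""


class MnpkitError(Exception):
    """Base class for all package errors."""


class ContractError(MnpkitError):
    """A documented precondition was violated by the caller."""


class FormatError(MnpkitError):
    """An input file does not conform to its declared format."""


class DatabaseVersionError(FormatError):
    """A marker database was written with an unsupported schema version."""
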