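"""Exception hierarchy.

``InputError`` covers user-supplied data that is structurally valid but
unusable (missing files, empty sample intersections, bad preconditions);
``FormatError`` covers files that cannot be parsed as the declared format;
``ConfigError`` covers invalid run or simulation configurations.
"""


class EqtlHotError(Exception):
    """Base class for all package errors."""


class InputError(EqtlHotError):
    """Input data exists but violates a precondition."""


class FormatError(EqtlHotError):
    """A file does not conform to its declared format."""


class ConfigError(EqtlHotError):
    """Invalid configuration."""
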