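"""Exception hierarchy.

``FormatError`` marks malformed input files; ``IntegrityError`` marks
inputs that parse but violate a structural contract (dangling PM/MM
partner, probe missing from an intensity file, ...). The CLI maps
``IQRrayError`` subclasses to exit code 2 and usage problems to 1.
"""


class IQRrayError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(IQRrayError):
    """A file does not conform to its declared format."""


class IntegrityError(IQRrayError):
    """Parsed data violate a structural invariant."""
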