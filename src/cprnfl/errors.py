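"""Exception hierarchy.

The CLI maps :class:`FormatError` to exit status 2 and every other
:class:`CpRnflError` to exit status 3.
"""


class CpRnflError(Exception):
    """Base class for all package errors."""


class ParameterError(CpRnflError, ValueError):
    """Invalid parameter or malformed in-memory input."""


class FormatError(CpRnflError, ValueError):
    """Malformed file input (bad columns, broken grid, checksum mismatch)."""


class ContractError(CpRnflError, RuntimeError):
    """A post-condition or invariant check failed at run time."""


class UnsupportedInputError(CpRnflError):
    """Operation requires information the input does not carry (e.g. latent truth)."""


class UndefinedValueError(CpRnflError):
    """Requested quantity is undefined for this input (e.g. mean of zero samples)."""
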