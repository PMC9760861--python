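"""Exception hierarchy for dermseg.

All package errors derive from :class:`DermsegError` so callers can catch
one base class.  Validation-type errors (bad user input, bad config) are
kept distinct from runtime/numerical failures because the command-line
interface maps them to different exit codes (2 vs 1).
"""


class DermsegError(Exception):
    """Base class for all dermseg errors."""


class InputError(DermsegError):
    """A required input is missing or malformed (missing file, shape mismatch)."""


class FormatError(InputError):
    """An image file has an unsupported bit depth, channel count or encoding."""


class ConfigError(InputError):
    """A configuration value is out of range or an unknown key is present."""


class DegenerateInputError(DermsegError):
    """The input is technically valid but carries no usable signal
    (e.g. a constant image given to a two-class threshold)."""


class InfeasibleError(DermsegError):
    """The requested operation has no solution (e.g. inpainting a mask
    that covers the entire image)."""


class NumericalInstabilityError(DermsegError):
    """A numerical scheme produced non-finite values; usually the time
    step is too large."""
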