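"""Exception hierarchy shared across the package."""


class PollenHoloError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(PollenHoloError, ValueError):
    """An argument violates a documented precondition."""


class DegenerateInputError(PollenHoloError, ValueError):
    """Input is structurally valid but degenerate (all-zero frame, empty mask, ...)."""


class PlacementError(PollenHoloError, RuntimeError):
    """Grain placement failed after the bounded number of retries."""
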