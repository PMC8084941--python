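"""Exception hierarchy shared across the package."""


class FlyBehaveError(Exception):
    """Base class for all package errors."""


class FormatError(FlyBehaveError):
    """A file does not conform to the expected table dialect."""


class IntegrityError(FlyBehaveError):
    """Data violates an internal consistency requirement (frame gaps,
    negative speeds, out-of-arena coordinates beyond tolerance)."""


class InsufficientDataError(FlyBehaveError):
    """Not enough frames / events to compute the requested quantity."""


class ParameterError(FlyBehaveError):
    """Simulation or protocol parameters are infeasible or out of range."""


class DesignError(FlyBehaveError):
    """A statistical design cannot be analyzed (too few groups, zero
    totals, misaligned repeated measures)."""
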