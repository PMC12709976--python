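"""Exception hierarchy for powderflow."""


class PowderflowError(Exception):
    """Base class for all powderflow errors."""


class ContractError(PowderflowError, ValueError):
    """A documented precondition was violated by the caller."""


class FormatError(PowderflowError):
    """An input file exists but is not in a supported layout."""


class DegenerateHistogramError(PowderflowError):
    """All histogram mass sits in a single bin; no threshold exists."""


class GenerationError(PowderflowError):
    """The synthetic generator could not satisfy the requested geometry."""
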