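"""Exception hierarchy for the pipeline."""


class CotupipeError(Exception):
    """Base class for all package errors."""


class ParseError(CotupipeError):
    """A sequence file could not be parsed; the message names the offending position."""


class ValidationError(CotupipeError):
    """A sample sheet / primer table / record violates its invariants."""


class AlphabetError(ValidationError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


class AlignmentShapeError(CotupipeError):
    """Rows of an alignment differ in length."""


class NoCoreError(CotupipeError):
    """No window of consecutive well-covered columns exists; consensus impossible."""


class InsufficientDepthError(CotupipeError):
    """Fewer reads than the minimum depth required for consensus calling."""


class SaturatedDistanceError(CotupipeError):
    """The K2P log arguments are non-positive; the distance is undefined."""
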