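"""Exception hierarchy for missel."""


class MisselError(Exception):
    """Base class for all missel errors."""


class MissingInputError(MisselError):
    """A required input (transcript, mutation table, ...) is absent or empty."""


class DataConsistencyError(MisselError):
    """Inputs contradict each other, e.g. a mutation's reference base does not
    match the transcript sequence at that position."""


class BoundsError(MisselError):
    """A coordinate lies outside the valid range of its sequence or region."""


class DegenerateNullError(MisselError):
    """The neutral null model has no probability mass on the requested
    consequence class, so no test can be formed."""


class DegenerateFeatureError(MisselError):
    """A Boolean feature covers all or none of the null mass (p0 in {0, 1})."""


class EmptyObservationError(MisselError):
    """A test was requested on an observed set with no mutations."""


class DegenerateLayerError(MisselError):
    """An exclusion step emptied the observed set or the null catalogue."""


class CoverageError(MisselError):
    """A residue required for a structural score is absent from the structure."""


class FormatError(MisselError):
    """A file does not conform to its documented dialect.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line
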