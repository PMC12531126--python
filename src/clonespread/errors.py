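"""Exception and warning types shared across the pipeline."""


class ClonespreadError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(ClonespreadError, ValueError):
    """A value violates an operation's precondition."""


class InsufficientAnchorsError(ClonespreadError):
    """Purity estimation was requested without any clonal anchor segments."""


class DegenerateCompositionError(ClonespreadError):
    """The allelic composition makes the mBAF equation degenerate (balanced alleles)."""


class ConfigurationError(ClonespreadError):
    """Missing or inconsistent run configuration (e.g. variants without a BED file)."""


class AmbiguityError(ClonespreadError):
    """Conflicting rows that cannot be merged into a single event."""


class DeconvolutionConflictError(ClonespreadError):
    """No subclone nesting satisfies the pigeonhole constraints.

    Carries the offending cluster fractions so the caller can decide whether to
    relax the tolerance.
    """

    def __init__(self, message, clusters=None):
        super().__init__(message)
        self.clusters = clusters or []


class DataError(ClonespreadError):
    """A data file violates its documented schema."""


class QualityWarning(UserWarning):
    """Raised (as a warning) when a measurement is outside its plausible range."""
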