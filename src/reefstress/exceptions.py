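"""Exception and warning types shared across the pipeline."""


class ReefStressError(Exception):
    """Base class for all package-specific errors."""


class WindowLengthError(ReefStressError, ValueError):
    """An accumulation window did not contain exactly the required number of weeks."""


class MissingDataError(ReefStressError, ValueError):
    """A series contained missing values where the computation forbids silent imputation."""


class CoverageError(ReefStressError, ValueError):
    """Requested date or location falls outside the coverage of the supplied data."""


class SchemaError(ReefStressError, KeyError):
    """A required column or field is absent from the input table."""


class IdentificationError(ReefStressError, ValueError):
    """The model is not identified on the given data (e.g. all observations censored)."""


class ConvergenceWarning(UserWarning):
    """An iterative fit stopped without meeting its convergence tolerance."""
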