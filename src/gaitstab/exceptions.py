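"""Exception hierarchy for the gaitstab pipeline."""


class GaitstabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GaitstabError):
    """Invalid generator or run configuration."""


class SchemaError(GaitstabError):
    """On-disk data does not match the declared tabular schema."""


class InsufficientDataError(GaitstabError):
    """Not enough strides/steps/participants to run the requested stage."""


class CollinearityError(GaitstabError):
    """Regression design matrix is rank deficient."""


class DegenerateGeometryError(GaitstabError):
    """Landmarks do not span a valid foot coordinate frame."""
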