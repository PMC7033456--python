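"""Exception hierarchy.

Three roots map onto CLI exit codes: ConfigError (2), DataError (3),
NumericError (4). Specific subclasses exist where callers need to
distinguish failure modes programmatically.
"""


class ConnPredictError(Exception):
    """Base class for all package errors."""


class ConfigError(ConnPredictError):
    """Invalid configuration (bad item map, missing networks, bad CV plan)."""


class DataError(ConnPredictError):
    """Invalid or inconsistent input data."""


class NumericError(ConnPredictError):
    """Numerical failure (non-finite inputs, failed projection, ...)."""


class SchemaError(DataError):
    """ROI/response table missing required columns."""


class ParseError(DataError):
    """Table cell could not be parsed (e.g. non-numeric coordinate)."""


class InvalidNetworkError(DataError):
    """A network that cannot support at least one edge (n < 2)."""


class DuplicateRoiError(DataError):
    """Pooling networks with overlapping ROI membership."""


class SamplingError(DataError):
    """Sham sampling request exceeds the pool."""


class ExtractionError(DataError):
    """An ROI sphere contains no voxel centers."""


class OrientationError(DataError):
    """4D volume lacks a usable MNI-space affine."""


class UndefinedCorrelationError(NumericError):
    """Zero-variance time course makes Pearson correlation undefined."""


class UndefinedReliabilityError(NumericError):
    """Cronbach's alpha undefined (zero total-score variance)."""


class CovariateError(DataError):
    """Residualization covariate is degenerate (single-sex cohort)."""


class PartitionError(ConfigError):
    """Cross-validation fold size incompatible with cohort size."""
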