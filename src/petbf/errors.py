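"""Typed exceptions used across the package.

Metric-undefined conditions (zero liver mean, degenerate normalization, ...)
raise rather than returning sentinel values so that failures stay visible in
batch runs.
"""


class PetbfError(Exception):
    """Base class for all package errors."""


class FormatError(PetbfError):
    """Input file exists but has the wrong structure (e.g. 4D payload)."""


class GeometryError(PetbfError):
    """Shape/spacing/orientation mismatch between volumes or masks."""


class ValidationError(PetbfError):
    """Value-level invariant violation (NaNs, empty mask, bad parameter)."""


class MetricUndefinedError(PetbfError):
    """A metric's denominator or domain condition is violated."""


class OptimizationError(PetbfError):
    """Grid search could not produce a valid optimum."""


class ConfigurationError(PetbfError):
    """Model/spec configuration incompatible with the requested input."""


class TrainingError(PetbfError):
    """Training diverged (non-finite loss) or was otherwise unusable."""
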