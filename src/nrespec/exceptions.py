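"""Exception hierarchy for the pipeline.

Every error raised on bad scientific input derives from :class:`NrespecError`
so callers can distinguish pipeline-domain failures from programming errors.
"""


class NrespecError(Exception):
    """Base class for all pipeline-domain errors."""


class GridMismatchError(NrespecError):
    """Wavelength grids of two spectral objects differ."""


class DegenerateReferenceError(NrespecError):
    """White reference does not exceed the dark reference in some band."""


class EmptyRoiError(NrespecError):
    """A region-of-interest mask selects no pixels."""


class ComponentRangeError(NrespecError):
    """Requested latent-component count is outside the valid range."""


class DegenerateModelError(NrespecError):
    """A fitted model carries no explained variance (all SS_k zero)."""


class SampleSizeError(NrespecError):
    """Too few samples for the requested operation."""


class ThresholdError(NrespecError):
    """A selection threshold leaves no variables."""


class UndefinedMetricError(NrespecError):
    """A requested metric is undefined for the given inputs (e.g. zero variance)."""


class DomainError(NrespecError):
    """A physical quantity is outside its valid domain (e.g. non-positive mass)."""


class LabelError(NrespecError):
    """Organ/stage labels are inconsistent (mismatch or duplicate)."""


class ConfigError(NrespecError):
    """A configuration value violates the schema or its invariants."""


class DependencyError(NrespecError):
    """A pipeline stage is missing an upstream artifact."""
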