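"""Exception hierarchy shared across the package."""


class ConcordError(Exception):
    """Base class for all package-specific errors."""


class InvalidPolygonError(ConcordError):
    """Polygon has fewer than 3 vertices or is self-intersecting."""


class EmptyInputError(ConcordError):
    """An operation requiring at least one element received none."""


class InvalidCircleError(ConcordError):
    """Circle with a negative radius or non-finite parameters."""


class UndefinedRatioError(ConcordError):
    """A ratio whose denominator is identically zero (e.g. JI of two empty sets)."""


class InsufficientLandmarksError(ConcordError):
    """Fewer landmark pairs than a similarity transform needs."""


class DegenerateConfigurationError(ConcordError):
    """Landmark configuration that does not determine a transform (all coincident)."""


class AnnotationSchemaError(ConcordError):
    """Annotation record violating the JSON schema or the label vocabulary."""


class InconsistentGroupError(ConcordError):
    """Annotations mixed across eyes, modalities, graders or labels where one group is required."""


class EmptyAnnotationError(ConcordError):
    """Agreement requested for an empty region."""


class UndefinedReferenceAreaError(ConcordError):
    """Area-relation classification with a zero reference (ICGA) area."""


class InsufficientDataError(ConcordError):
    """A statistical test or summary with too few observations."""


class DegenerateTableError(ConcordError):
    """2x2 contingency table with a zero margin."""


class DegenerateAnnotationError(ConcordError):
    """Simulated grader perturbation could not produce a simple polygon."""


class ConfigError(ConcordError):
    """Synthetic-data configuration that cannot be realised (e.g. lesion outside the field of view)."""
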