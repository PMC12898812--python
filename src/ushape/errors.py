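"""Exception hierarchy shared across the package."""


class UshapeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(UshapeError):
    """Input file lacks required columns or cannot be parsed at all."""


class ValidationError(UshapeError):
    """Input rows violate dataset invariants (duplicates, bad codes, >2 feet)."""


class ConfigurationError(UshapeError):
    """Invalid generator or run configuration."""


class SeparationError(UshapeError):
    """Perfect/quasi separation or one-class outcome; estimates diverge."""


class CurvatureError(UshapeError):
    """Quadratic term non-positive: the fitted logit has no interior minimum."""


class ComparisonError(UshapeError):
    """Fits being compared were not estimated on the same rows."""


class ReliabilityError(UshapeError):
    """Too few successful bootstrap replicates to trust the intervals."""


class ScenarioError(UshapeError):
    """More than half of a scenario's replicates failed to fit."""
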