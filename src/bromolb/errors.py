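"""Exception types shared across the package."""


class BromOlbError(Exception):
    """Base class for package errors."""


class GeometryError(BromOlbError):
    """Phantom geometry cannot satisfy the requested constraints
    (e.g. no lesion position with the required pleural margin fits the grid)."""


class RoiPlacementError(BromOlbError):
    """No admissible ROI placement exists; the message names the violated rule."""


class SeparationError(BromOlbError):
    """Complete or quasi-complete separation detected in a logistic fit."""


class ValidationError(BromOlbError):
    """A data table or record violates its schema."""


class ConfigError(BromOlbError):
    """A run configuration is malformed."""
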