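"""Exception hierarchy shared across the pipeline stages."""


class VillimorphError(Exception):
    """Base class for all package-specific errors."""


class BoundsError(VillimorphError):
    """A geometric primitive or crop window exceeds the array bounds."""


class GeometryError(VillimorphError):
    """A phantom spec or label topology is geometrically inconsistent."""


class FeasibilityError(VillimorphError):
    """A requested target (e.g. SA:V) is unattainable at the given resolution."""


class ConfigurationError(VillimorphError):
    """A configuration is incomplete or internally inconsistent."""


class ConvergenceError(VillimorphError):
    """The nonlinear membrane solve failed to reach the requested tolerance."""

    def __init__(self, message: str, residual: float | None = None,
                 iterations: int | None = None):
        super().__init__(message)
        self.residual = residual
        self.iterations = iterations


class SchemaError(VillimorphError):
    """An input table is missing required columns or carries wrong dtypes."""


class InsufficientDataError(VillimorphError):
    """Too few observations for the requested statistical comparison."""
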