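"""Exception hierarchy shared across the package."""


class ScgnmfError(Exception):
    """Base class for all package-specific errors."""


class MalformedInputError(ScgnmfError):
    """An input table contains a missing, negative or non-numeric cell."""


class DuplicateIdentifierError(ScgnmfError):
    """Gene or sample identifiers are not unique."""


class StateError(ScgnmfError):
    """An operation was applied to an object in the wrong state."""


class DimensionError(ScgnmfError):
    """Matrix shapes are incompatible for the requested operation."""


class LineSearchError(ScgnmfError):
    """Backtracking exhausted its budget without satisfying sufficient decrease."""


class NumericalError(ScgnmfError):
    """NaN or Inf appeared in an iterate."""


class DegenerateCurvatureError(ScgnmfError):
    """Both branch denominators of the spectral parameters vanished.

    Callers respond with a steepest-descent restart.
    """


class GradientVanishedError(ScgnmfError):
    """Curvature quantities requested at a point with zero gradient."""


class DegenerateStartError(ScgnmfError):
    """The random initialization is already a KKT point (zero residual)."""


class UndefinedMembershipError(ScgnmfError):
    """A sample has zero reconstruction for every gene; membership undefined."""


class UnassignableSampleError(ScgnmfError):
    """A sample column is all zero and cannot be assigned a class."""
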