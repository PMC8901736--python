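"""Exception hierarchy shared across the package."""


class PaleohabError(Exception):
    """Base class for all package-specific errors."""


class InvalidConfigError(PaleohabError, ValueError):
    """A configuration value violates its documented constraints."""


class OutOfRangeError(PaleohabError, ValueError):
    """A requested age or coordinate falls outside the data span."""


class ModeMismatchError(PaleohabError, ValueError):
    """An interpolation mode incompatible with the variable kind."""


class EmptyBufferError(PaleohabError, ValueError):
    """No unmasked cells inside the requested buffer."""


class DegenerateScalingError(PaleohabError, ValueError):
    """Zero variance where scaling or correlation is required."""


class InvalidMatrixError(PaleohabError, ValueError):
    """A distance matrix breaks symmetry, labelling or the zero diagonal."""


class InvalidRegionError(PaleohabError, ValueError):
    """An empty or malformed region mask."""


class UndefinedStatisticError(PaleohabError, ValueError):
    """A test statistic is undefined for the given counts."""


class InfeasiblePlacementError(PaleohabError, ValueError):
    """More occupations requested than available land cells."""


class DesignError(PaleohabError, ValueError):
    """A regression design matrix is rank deficient or malformed."""
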