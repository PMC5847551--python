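"""Exception hierarchy for the nightrange pipeline."""


class NightRangeError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(NightRangeError, ValueError):
    """Invalid generator or configuration parameters."""


class InputError(NightRangeError, ValueError):
    """Malformed or incomplete input data (missing years, empty collections...)."""


class GridMismatchError(NightRangeError, ValueError):
    """Two grids that must share a GridSpec do not."""


class SchemaError(NightRangeError, ValueError):
    """A vector feature is missing a required property."""


class EmptyMaskError(NightRangeError, ValueError):
    """A geometry produced no pixels on the grid."""


class InsufficientDataError(NightRangeError, ValueError):
    """Too few usable pixels/points for a fit."""


class RankError(NightRangeError, ValueError):
    """Degenerate design matrix (e.g. all target DN values equal)."""


class DomainError(NightRangeError, ValueError):
    """Value outside its mathematical domain (e.g. proportion not in [0, 1])."""
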