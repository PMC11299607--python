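"""Exception hierarchy for the indexer."""


class ToroError(Exception):
    """Base class for all errors raised by this package."""


class InvalidCellError(ToroError, ValueError):
    """Unit-cell parameters do not define a positive-definite metric."""


class SingularBasisError(ToroError, ValueError):
    """A basis matrix is singular (or numerically so)."""


class InvalidGeometryError(ToroError, ValueError):
    """Detector geometry is inconsistent or a peak maps to a degenerate ray."""


class ParameterError(ToroError, ValueError):
    """An algorithm parameter is out of its valid range."""


class DegenerateAssignmentError(ToroError, ValueError):
    """Active Miller indices span rank < 3; the basis is unidentifiable."""


class SimulationError(ToroError, ValueError):
    """The requested synthetic frame cannot be generated."""


class CellFileError(ToroError, ValueError):
    """A unit-cell / geometry / peak file could not be parsed."""
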