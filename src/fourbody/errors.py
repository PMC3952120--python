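"""Exception hierarchy shared across the package."""


class FourbodyError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(FourbodyError):
    """Raised when PDB-format input cannot be parsed into coordinates."""


class FilterError(FourbodyError):
    """Raised when atom filtering leaves nothing to work with."""


class SelectionError(FourbodyError):
    """Raised when a ligand selector matches zero atoms or the whole structure."""


class ClassificationError(FourbodyError):
    """Raised for elements outside the supported alphabet (H/D, unknowns)."""


class DegeneracyError(FourbodyError):
    """Raised when point configurations cannot be tessellated (coplanar, < 4 points)."""


class PotentialError(FourbodyError):
    """Raised for inconsistent potential tables or mismatched provenance."""


class EvaluationError(FourbodyError):
    """Raised for degenerate inputs to the agreement statistics."""


class FixtureError(FourbodyError):
    """Raised when a synthetic-structure specification is infeasible."""
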