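"""Exception hierarchy for switchmd.

All errors derive from :class:`SwitchMDError` so callers can catch the
package's failures with a single except clause while per-metric isolation
in the activation battery records them individually.
"""


class SwitchMDError(Exception):
    """Base class for all switchmd errors."""


class ParseError(SwitchMDError):
    """A coordinate file could not be parsed; message names the line."""


class StructureError(SwitchMDError):
    """Parsed file violates a structural invariant (e.g. atom counts differ
    between models)."""


class GeometryError(SwitchMDError):
    """Degenerate geometry: collinear dihedral points, <3 fit atoms, etc."""


class MappingError(SwitchMDError):
    """A Ballesteros-Weinstein label cannot be resolved."""


class MissingAtomError(SwitchMDError):
    """A required atom is absent from a residue."""


class UnsupportedResidueError(SwitchMDError):
    """Residue type cannot support the requested metric (e.g. chi1 of Gly)."""


class DegenerateInputError(SwitchMDError):
    """Input is formally valid but carries no information (empty window,
    zero time variance, all-zero covariance)."""


class GenerationError(SwitchMDError):
    """Synthetic-structure generation produced infeasible geometry."""
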