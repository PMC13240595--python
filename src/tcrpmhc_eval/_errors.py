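"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`TcrEvalError`,
so callers (and the CLI's per-row failure isolation) can catch one base class.
"""


class TcrEvalError(Exception):
    """Base class for all errors raised by tcrpmhc_eval."""


class FormatError(TcrEvalError):
    """Unparseable or unusable structure file (e.g. no C-alpha atoms)."""


class RoleError(TcrEvalError):
    """Missing or duplicated mandatory chain role."""


class MappingError(TcrEvalError):
    """Role map does not match the chains actually present."""


class NumberingError(TcrEvalError):
    """Bad residue-numbering table (unknown residue, duplicate row)."""


class EmptyRegionError(TcrEvalError):
    """A region selection produced no residues."""


class CorrespondenceError(TcrEvalError):
    """Native and prediction cannot be paired residue-by-residue."""


class GeometryError(TcrEvalError):
    """Too few or degenerate (collinear) points for superposition."""


class ShapeError(TcrEvalError):
    """Coordinate arrays with mismatched lengths."""


class SplitError(TcrEvalError):
    """Receptor/ligand body split is invalid (empty or overlapping bodies)."""


class UndefinedInterfaceError(TcrEvalError):
    """Native complex has no cross-body contacts; DockQ is undefined."""


class DomainError(TcrEvalError):
    """Metric input outside its mathematical domain."""


class ConfidenceError(TcrEvalError):
    """Missing or out-of-range confidence values."""


class RerankError(TcrEvalError):
    """Requested ranking signal missing on a candidate."""


class CorrelationError(TcrEvalError):
    """Correlation undefined (too few points or zero variance)."""


class TableError(TcrEvalError):
    """Malformed curation/similarity table."""


class ConfigError(TcrEvalError):
    """Invalid generator or pipeline configuration."""
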