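"""Exception hierarchy.

Every error carries an ``exit_code`` so the CLI can map failures to
distinct, stable process exit codes.
"""


class PosestabError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class PDBParseError(PosestabError):
    """A PDB record could not be parsed; message names the line."""

    exit_code = 2


class EmptyStructureError(PosestabError):
    """No atoms remain after solvent/ion filtering."""

    exit_code = 2


class TrajectoryError(PosestabError):
    """Unreadable frame or atom-count mismatch against the topology."""

    exit_code = 2


class IOFormatError(PosestabError):
    """Unwritable path or unsupported file format."""

    exit_code = 2


class SelectionError(PosestabError):
    """Selection expression failed to parse."""

    exit_code = 3


class NoNativeContactsError(PosestabError):
    """Zero native contacts: the R-value is undefined."""

    exit_code = 4


class WindowError(PosestabError):
    """Equilibration window leaves a replica with no frames."""

    exit_code = 5


class SuperpositionError(PosestabError):
    """Fewer than three fit atoms, or degenerate geometry."""

    exit_code = 5


class CorrespondenceError(PosestabError):
    """Ligand atom identities do not match 1:1 between structures."""

    exit_code = 5


class ClassificationError(PosestabError):
    """Non-finite pose metrics cannot be classified."""

    exit_code = 5


class MetricError(PosestabError):
    """Ensemble metrics require a designated docking-top pose."""

    exit_code = 5


class DomainError(PosestabError):
    """Input outside the mathematical domain (e.g. Kd <= 0)."""

    exit_code = 5


class UndefinedCorrelationError(PosestabError):
    """Zero variance or fewer than three points."""

    exit_code = 5


class ComparabilityError(PosestabError):
    """Results computed with different contact-model parameters."""

    exit_code = 5


class SchemaError(PosestabError):
    """Tabular input is missing required columns; message names them."""

    exit_code = 6


class GenerationError(PosestabError):
    """Synthetic-fixture request is geometrically infeasible."""

    exit_code = 5
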