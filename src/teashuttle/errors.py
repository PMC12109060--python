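"""Exception hierarchy shared across the pipeline stages."""


class TeaShuttleError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(TeaShuttleError):
    """A simulation or pipeline configuration violates its invariants."""


class InsufficientStandardsError(TeaShuttleError):
    """A calibration fit needs at least three distinct standard levels."""


class DegenerateDesignError(TeaShuttleError):
    """All standards share one concentration; the slope is unidentifiable."""


class DegenerateCurveError(TeaShuttleError):
    """A calibration curve with zero slope cannot be inverted."""


class UndefinedControlError(TeaShuttleError):
    """Control and blank absorbances coincide; %RSA is undefined."""


class NonResponsiveSampleError(TeaShuttleError):
    """The dose-response slope is non-positive; no IC50 crossing exists."""


class NoDataError(TeaShuttleError):
    """A requested analysis window contains no samples."""


class MissingReferenceError(TeaShuttleError):
    """The blank condition needed for amplification ratios is absent."""


class MalformedCycleError(TeaShuttleError):
    """A voltammetry cycle lacks one of the two sweep directions."""


class NoOverlapError(TeaShuttleError):
    """Forward and reverse sweeps share no voltage range."""


class IncompleteRecordError(TeaShuttleError):
    """A compound record is missing descriptors or absorption scores."""


class SmilesParseError(TeaShuttleError):
    """RDKit could not parse a SMILES string."""

    def __init__(self, smiles: str):
        self.smiles = smiles
        super().__init__(f"unparseable SMILES: {smiles!r}")


class InsufficientReplicatesError(TeaShuttleError):
    """A contrasted expression class has fewer than two samples."""


class EdgeListParseError(TeaShuttleError):
    """A PPI edge-list row is malformed; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


class ResourceLimitError(TeaShuttleError):
    """Graph too large for exhaustive clique enumeration."""


class InvalidDBError(TeaShuttleError):
    """A gene-set database has an empty universe."""


class StageDependencyError(TeaShuttleError):
    """A pipeline stage requires output from a stage that did not run."""
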