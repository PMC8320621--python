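"""Exception hierarchy for the bioassay pipeline."""


class LungSurfError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(LungSurfError, ValueError):
    """A physical or protocol parameter violates its constraints."""


class GeometryError(LungSurfError):
    """A drop profile cannot be realized (e.g. never reaches the pedestal)."""


class IdentifiabilityError(LungSurfError):
    """The inverse problem carries no information about the parameter.

    At zero Bond number (density difference = 0) every surface tension
    produces the same spherical shape, so gamma cannot be inferred.
    """


class FitFailureError(LungSurfError):
    """The shape optimizer failed to converge; diagnostics attached."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InsufficientDataError(LungSurfError, ValueError):
    """Too few points/cycles/replicates for the requested operation."""


class SegmentationError(LungSurfError):
    """No complete compression-expansion cycle found in the trace."""


class ConsistencyError(LungSurfError, ValueError):
    """Requested confusion-table margins are mutually infeasible."""


class NoCallError(LungSurfError):
    """No QC-passing replicate is available to classify a chemical."""


class DoseNotEstimableError(LungSurfError):
    """Inhibitory dose cannot be computed for this call."""


class SchemaError(LungSurfError, ValueError):
    """Malformed input file; message names the offending row/column."""
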