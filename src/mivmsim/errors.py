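"""Exception hierarchy for the simulation pipeline."""


class MivmError(Exception):
    """Base class for all package errors."""


class GeometryError(MivmError):
    """Scenario geometry is inconsistent (e.g. insert does not fit the chamber)."""


class ResolutionError(MivmError):
    """Mesh resolution too coarse to resolve the smallest required feature."""


class PlacementError(MivmError):
    """COC sphere packing failed within the attempt budget."""


class ConfigurationError(MivmError):
    """Solver asked to do something the scenario does not support."""


class SolverError(MivmError):
    """Iterative solver failed to converge."""


class StepSizeError(MivmError):
    """Transient step produced values outside the physical bounds."""
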