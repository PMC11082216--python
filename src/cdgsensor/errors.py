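"""Exception and warning types shared across the package."""


class CdgsensorError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(CdgsensorError, ValueError):
    """A model parameter is non-finite, non-positive where positivity is required,
    or otherwise outside its domain."""


class DegenerateFitError(CdgsensorError, RuntimeError):
    """The data carry no usable signal for the requested fit (e.g. a flat
    dose-response whose range is indistinguishable from noise)."""


class ConvergenceError(CdgsensorError, RuntimeError):
    """A nonlinear fit failed to converge after multi-start initialization."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class NoBreakpointError(CdgsensorError, RuntimeError):
    """Two-segment fit is not significantly better than a single line."""


class WrongDirectionError(CdgsensorError, ValueError):
    """A trace runs in the opposite direction to the requested model
    (e.g. an increasing trace passed to the dissociation fitter)."""


class NormalizationError(CdgsensorError, ValueError):
    """Plate normalization impossible (missing or degenerate saturated control)."""


class CensoredEC50Error(CdgsensorError, RuntimeError):
    """No half-maximal transition inside the observation window; carries the
    usable bound on EC50."""

    def __init__(self, message, bound=None):
        super().__init__(message)
        self.bound = bound


class InvalidDesignError(CdgsensorError, ValueError):
    """Assay design violates a model precondition (e.g. PDE assay started below
    the sensor Kd, where the activity formula is undefined)."""


class InvalidProtocolError(CdgsensorError, ValueError):
    """ITC protocol is inconsistent (e.g. cumulative injected volume exceeds
    the cell volume)."""


class MalformedLineageError(CdgsensorError, ValueError):
    """Parent links are inconsistent (more than two children per parent)."""


class UnderIdentifiedWarning(UserWarning):
    """A fit was requested with too little design variation to identify all
    parameters (e.g. association kinetics at a single ligand concentration)."""


class TieBreakWarning(UserWarning):
    """A deterministic tie-break was applied (e.g. equal sister-cell means)."""
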