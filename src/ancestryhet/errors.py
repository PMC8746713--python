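"""Structured exceptions raised across the package."""


class AncestryHetError(Exception):
    """Base class for all package errors."""


class ValidationError(AncestryHetError):
    """Raised when an input table or configuration violates its contract."""


class PedigreeError(AncestryHetError):
    """Raised when a cross lacks the founder/F1 records an operation requires."""


class FilterError(AncestryHetError):
    """Raised when marker/individual filtering removes everything.

    Carries the name of the binding constraint (``min_loci`` or
    ``min_individuals``).
    """

    def __init__(self, message: str, binding_constraint: str | None = None):
        super().__init__(message)
        self.binding_constraint = binding_constraint


class ModelError(AncestryHetError):
    """Raised when a statistical model cannot be fitted as requested."""


class SimulationError(AncestryHetError):
    """Raised by simulators for unattainable targets or invalid setups."""
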