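"""Exception hierarchy shared across the package."""


class CropDivError(Exception):
    """Base class for all package errors."""


class SchemaError(CropDivError):
    """Input file lacks a required column or has an unusable layout."""


class ValidationError(CropDivError):
    """Input violates a data invariant (negative area, duplicate key, ...)."""


class PanelLookupError(CropDivError, KeyError):
    """Region or year not covered by the panel (distinct from an empty community)."""


class UnknownTaxaError(CropDivError, KeyError):
    """Taxa requested that are not tips of the tree; offenders listed."""

    def __init__(self, offenders):
        self.offenders = sorted(offenders)
        super().__init__(f"unknown taxa: {', '.join(self.offenders)}")


class UndatedTreeError(CropDivError):
    """Operation requires node ages but the tree has not been dated."""


class CalibrationError(CropDivError):
    """Node-age table conflicts with tree topology (ancestor younger than descendant)."""


class UndefinedValueError(CropDivError):
    """Metric undefined for this input (e.g. diversity of an empty community)."""


class InsufficientDataError(CropDivError):
    """Too few points for the requested fit or test."""


class ConvergenceError(CropDivError):
    """No admissible converged solution found; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class InstabilityError(CropDivError):
    """Bootstrap or summary failed its stability requirements."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DegenerateSolutionError(CropDivError):
    """Ordination input admits no informative solution (all dissimilarities equal)."""


class ConfigError(CropDivError):
    """Invalid run configuration value."""
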