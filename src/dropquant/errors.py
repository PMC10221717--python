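"""Typed errors for the quantification pipeline.

Saturation and empty-well conditions are raised, never returned as ±inf,
so that downstream titer arithmetic cannot silently propagate non-finite
values.
"""


class DropquantError(Exception):
    """Base class for all package errors."""


class ConfigError(DropquantError, ValueError):
    """Invalid assay, prep, or scenario configuration."""


class DomainError(DropquantError, ValueError):
    """Argument outside the mathematical domain of an estimator."""


class SaturationError(DropquantError):
    """All droplets positive: the Poisson occupancy is not estimable."""


class EstimationError(DropquantError):
    """An estimator's preconditions are not met by the data (e.g. no
    cell-marker-positive droplets at all)."""


class InputError(DropquantError, ValueError):
    """Malformed or empty input table."""
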