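"""Infectious-titer estimators for the single-cell duplex assay.

Both estimators turn an infected-cell fraction into a titer via

    titer [iu/mL] = infected_fraction × N_cells × dilution / V

where N_cells is the total cell count of the infection well, dilution is
the fold-dilution of the inoculum and V its volume in mL. They differ in
how the infected fraction is read off the duplex well:

* ``double_positive`` — double-positive droplets divided by cell-marker
  (β-actin) positive droplets. Free-floating viral RNA co-encapsulated
  with uninfected cells creates spurious double positives, so this
  estimator overestimates when cells lyse during processing.
* ``linkage`` — excess double positives (linkage, copies/µL) divided by
  the cell-marker concentration (copies/µL). Free viral RNA cancels out
  of the linkage numerator; free cell-marker RNA still inflates the
  denominator, giving a mild underestimate instead.

Both are implemented exactly as stated (no subtraction of the random
double-positive expectation in the first; no Poisson correction of the
fraction by default) — their divergence under contamination is the point.
A Poisson multiple-infection correction of the fraction→iu step is
available behind an explicit flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .duplex import DuplexResult
from .errors import DomainError, EstimationError
from .quant import TwoChannelCounts

__all__ = [
    "TiterResult",
    "MoiSpec",
    "titer_eq1",
    "titer_eq2",
    "moi_from_titer",
    "infected_fraction_to_iu",
]


@dataclass(frozen=True)
class TiterResult:
    """Infectious titer with the quantities that produced it."""

    titer_iu_per_ml: float
    method: str  # "double_positive" | "linkage"
    infected_fraction: float
    numerator: float  # double-positive count, or linkage copies/µL
    actin_reference: float  # β-actin positive count, or copies/µL
    n_cells_total: int
    dilution_factor: float
    inoculum_volume_ml: float

    def __post_init__(self) -> None:
        if self.titer_iu_per_ml < 0:
            raise DomainError("titer must be >= 0")
        if self.method not in ("double_positive", "linkage"):
            raise DomainError(f"unknown method {self.method!r}")


@dataclass(frozen=True)
class MoiSpec:
    """Multiplicity of infection: infectious units delivered per cell."""

    moi: float

    @classmethod
    def from_titer(
        cls,
        titer_iu_per_ml: float,
        inoculum_volume_ml: float,
        dilution_factor: float,
        n_cells_total: int,
    ) -> "MoiSpec":
        return cls(
            moi_from_titer(titer_iu_per_ml, inoculum_volume_ml, dilution_factor, n_cells_total)
        )


def _check_assay_params(n_cells_total: int, dilution_factor: float, volume_ml: float) -> None:
    if n_cells_total < 1:
        raise DomainError("n_cells_total must be >= 1")
    if dilution_factor < 1:
        raise DomainError("dilution_factor must be >= 1")
    if volume_ml <= 0:
        raise DomainError("inoculum volume must be > 0")


def titer_eq1(
    counts: TwoChannelCounts,
    n_cells_total: int,
    dilution_factor: float,
    inoculum_volume_ml: float,
) -> TiterResult:
    """Double-positive-count titer estimator.

    titer = (double-positives / β-actin-positives) × N_cells × dilution / V
    """
    _check_assay_params(n_cells_total, dilution_factor, inoculum_volume_ml)
    n_actin_pos = counts.n_pos_a
    if n_actin_pos < 1:
        raise EstimationError("no cell-marker-positive droplets: no cells detected")
    fraction = counts.n_double_pos / n_actin_pos
    titer = fraction * n_cells_total * dilution_factor / inoculum_volume_ml
    return TiterResult(
        titer_iu_per_ml=titer,
        method="double_positive",
        infected_fraction=fraction,
        numerator=counts.n_double_pos,
        actin_reference=n_actin_pos,
        n_cells_total=n_cells_total,
        dilution_factor=dilution_factor,
        inoculum_volume_ml=inoculum_volume_ml,
    )


def titer_eq2(
    duplex: DuplexResult,
    n_cells_total: int,
    dilution_factor: float,
    inoculum_volume_ml: float,
) -> TiterResult:
    """Linkage titer estimator.

    titer = (linkage / c_β-actin) × N_cells × dilution / V, with linkage
    and the β-actin concentration in the same copies/µL units so the
    quotient is the infected-cell fraction.
    """
    _check_assay_params(n_cells_total, dilution_factor, inoculum_volume_ml)
    c_actin = duplex.conc_a.copies_per_ul_reaction
    if c_actin <= 0:
        raise EstimationError("zero cell-marker concentration: no cells detected")
    fraction = duplex.linkage_copies_per_ul / c_actin
    titer = fraction * n_cells_total * dilution_factor / inoculum_volume_ml
    return TiterResult(
        titer_iu_per_ml=titer,
        method="linkage",
        infected_fraction=fraction,
        numerator=duplex.linkage_copies_per_ul,
        actin_reference=c_actin,
        n_cells_total=n_cells_total,
        dilution_factor=dilution_factor,
        inoculum_volume_ml=inoculum_volume_ml,
    )


def moi_from_titer(
    titer_iu_per_ml: float,
    inoculum_volume_ml: float,
    dilution_factor: float,
    n_cells_total: int,
) -> float:
    """MOI = titer × V / (dilution × N_cells)."""
    if n_cells_total < 1:
        raise DomainError("n_cells_total must be >= 1")
    if titer_iu_per_ml < 0:
        raise DomainError("titer must be >= 0")
    return titer_iu_per_ml * inoculum_volume_ml / (dilution_factor * n_cells_total)


def infected_fraction_to_iu(
    fraction: float, n_cells_total: int, poisson_correct: bool = False
) -> float:
    """Infectious units from an infected-cell fraction.

    Uncorrected (default): iu = fraction × N_cells — each infected cell
    counts as one infectious unit, undercounting multiple infection at
    high MOI. With ``poisson_correct``, iu = N_cells × (−ln(1−fraction)),
    inverting P(infected) = 1 − e^(−MOI); requires fraction < 1.
    """
    if not 0 <= fraction <= 1:
        raise DomainError("fraction must be in [0, 1]")
    if n_cells_total < 1:
        raise DomainError("n_cells_total must be >= 1")
    if not poisson_correct:
        return fraction * n_cells_total
    if fraction >= 1:
        raise DomainError("fraction must be < 1 with Poisson correction")
    return n_cells_total * (-math.log(1.0 - fraction))
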