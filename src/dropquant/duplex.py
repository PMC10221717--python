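"""Two-target droplet analysis: duplex quantification and linkage.

Marginal concentrations in a duplex well are each estimated from that
channel's positive fraction alone, so quantifying a two-virus mixture
reduces to two independent single-channel problems.

The linkage statistic measures double-positive droplets in excess of the
random co-encapsulation expectation. Under a three-species Poisson model
(free A at λ_a, free B at λ_b, linked AB entities at λ_L, all partitioned
independently):

    P(A−) = e^−(λ_a+λ_L),  P(B−) = e^−(λ_b+λ_L),  P(A− ∧ B−) = e^−(λ_a+λ_b+λ_L)

so   λ_L = λ_A + λ_B − λ_union,   with λ_union = −ln(n_double_neg / n_total).

This is the plug-in MLE of the linked-species mean occupancy; divided by
the droplet volume it is a concentration in copies/µL. Entities carrying
both targets here are infected cells (β-actin and viral RNA in the same
droplet because they sit in the same cell), and the statistic is immune
to free-floating RNA of either target, which inflates the marginals and
the union rate equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import math

from .errors import DomainError, SaturationError
from .quant import ConcentrationEstimate, TwoChannelCounts, estimate_concentration

__all__ = [
    "LinkageEstimate",
    "DuplexResult",
    "duplex_concentrations",
    "expected_double_positives",
    "linkage",
    "linked_fraction",
    "analyze_duplex",
]

#: Below this count in any quadrant the droplet clusters are usually not
#: cleanly separable on a real reader; estimates are still returned.
SPARSE_QUADRANT_WARN = 10


@dataclass(frozen=True)
class LinkageEstimate:
    """Linkage in copies/µL; the raw signed λ is retained because the
    closed form can go negative by sampling noise (reported clipped)."""

    copies_per_ul: float
    lambda_linked_raw: float
    lambda_a: float
    lambda_b: float
    lambda_union: float


@dataclass(frozen=True)
class DuplexResult:
    """Everything a duplex well yields."""

    conc_a: ConcentrationEstimate
    conc_b: ConcentrationEstimate
    observed_double_pos: float
    expected_double_pos: float
    linkage_copies_per_ul: float
    linkage_lambda_raw: float


def _warn_sparse(counts: TwoChannelCounts) -> None:
    quads = {
        "A-only": counts.n_pos_a_only,
        "B-only": counts.n_pos_b_only,
        "double-pos": counts.n_double_pos,
        "double-neg": counts.n_double_neg,
    }
    sparse = [k for k, v in quads.items() if v < SPARSE_QUADRANT_WARN]
    if sparse:
        warnings.warn(
            f"sparse quadrant(s) {sparse} (<{SPARSE_QUADRANT_WARN} droplets): "
            "cluster separation may not be reliable on real data",
            stacklevel=3,
        )


def duplex_concentrations(
    counts: TwoChannelCounts,
    droplet_volume_nl: float,
    confidence_level: float = 0.95,
) -> tuple[ConcentrationEstimate, ConcentrationEstimate]:
    """Marginal per-target concentrations of a duplex well."""
    conc_a = estimate_concentration(counts.channel_a(), droplet_volume_nl, confidence_level)
    conc_b = estimate_concentration(counts.channel_b(), droplet_volume_nl, confidence_level)
    return conc_a, conc_b


def expected_double_positives(counts: TwoChannelCounts) -> float:
    """Expected double-positive droplets under channel independence:
    n_total × (A-positive fraction) × (B-positive fraction)."""
    n = counts.n_total
    return n * (counts.n_pos_a / n) * (counts.n_pos_b / n)


def linkage(counts: TwoChannelCounts, droplet_volume_nl: float) -> LinkageEstimate:
    """Excess double-positive (linked-species) concentration, copies/µL.

    Raises
    ------
    SaturationError
        If no droplet is double-negative (union saturated).
    """
    if counts.n_double_neg < 1:
        raise SaturationError("no double-negative droplets; linkage not estimable")
    n = counts.n_total
    frac_a_neg = (n - counts.n_pos_a) / n
    frac_b_neg = (n - counts.n_pos_b) / n
    if frac_a_neg <= 0 or frac_b_neg <= 0:
        raise SaturationError("a channel is saturated; linkage not estimable")
    _warn_sparse(counts)
    lam_a = -math.log(frac_a_neg)
    lam_b = -math.log(frac_b_neg)
    lam_union = -math.log(counts.n_double_neg / n)
    lam_linked = lam_a + lam_b - lam_union
    return LinkageEstimate(
        copies_per_ul=max(lam_linked, 0.0) / (droplet_volume_nl / 1000.0),
        lambda_linked_raw=lam_linked,
        lambda_a=lam_a,
        lambda_b=lam_b,
        lambda_union=lam_union,
    )


def linked_fraction(
    linkage_copies_per_ul: float, c_reference_copies_per_ul: float
) -> float:
    """Linkage divided by a reference concentration (the cell-marker
    channel), i.e. the estimated fraction of reference entities carrying
    both targets.

    Values > 1 are returned but flagged: the numerator cannot be inflated
    by free-floating RNA while the denominator can, so a quotient above 1
    indicates a model violation rather than a computational fault.
    """
    if c_reference_copies_per_ul <= 0:
        raise DomainError("reference concentration must be > 0")
    if linkage_copies_per_ul < 0:
        raise DomainError("linkage must be >= 0")
    frac = linkage_copies_per_ul / c_reference_copies_per_ul
    if frac > 1:
        warnings.warn(
            f"linked fraction {frac:.3g} > 1: inconsistent with the "
            "three-species model (check reference channel)",
            stacklevel=2,
        )
    return frac


def analyze_duplex(
    counts: TwoChannelCounts,
    droplet_volume_nl: float,
    confidence_level: float = 0.95,
) -> DuplexResult:
    """Marginals, independence expectation and linkage in one pass."""
    conc_a, conc_b = duplex_concentrations(counts, droplet_volume_nl, confidence_level)
    link = linkage(counts, droplet_volume_nl)
    return DuplexResult(
        conc_a=conc_a,
        conc_b=conc_b,
        observed_double_pos=counts.n_double_pos,
        expected_double_pos=expected_double_positives(counts),
        linkage_copies_per_ul=link.copies_per_ul,
        linkage_lambda_raw=link.lambda_linked_raw,
    )
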