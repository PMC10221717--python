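"""Single-target concentration and titer estimation from droplet counts.

The core of digital PCR: with copies Poisson-partitioned across droplets,
the fraction of negative droplets estimates e^(−λ), so

    λ̂ = −ln(n_negative / n_total)

is the maximum-likelihood estimate of the mean copies per droplet.
Confidence intervals use the Wilson score interval on the negative
fraction, mapped through −ln (well-behaved at extreme fractions), then
scaled to copies/µL via the droplet volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .errors import ConfigError, DomainError, InputError, SaturationError
from .sim import AssayConfig, DropletBatch

__all__ = [
    "ChannelCounts",
    "TwoChannelCounts",
    "ConcentrationEstimate",
    "SampleTiter",
    "classify_events",
    "counts_from_batch",
    "estimate_lambda",
    "estimate_concentration",
    "concentration_from_lambda",
    "sample_titer",
    "genome_to_infectious_ratio",
]


@dataclass(frozen=True)
class ChannelCounts:
    """Positive/total droplet counts for one fluorescence channel."""

    n_total: int
    n_positive: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise ConfigError("n_total must be >= 1")
        if not 0 <= self.n_positive <= self.n_total:
            raise ConfigError("need 0 <= n_positive <= n_total")


@dataclass(frozen=True)
class TwoChannelCounts:
    """The 2×2 quadrant table of a duplex well — the sufficient statistic
    for all two-channel estimation."""

    n_total: int
    n_pos_a_only: float
    n_pos_b_only: float
    n_double_pos: float
    n_double_neg: float

    def __post_init__(self) -> None:
        cats = (self.n_pos_a_only, self.n_pos_b_only, self.n_double_pos, self.n_double_neg)
        if any(c < 0 for c in cats):
            raise ConfigError("quadrant counts must be >= 0")
        if abs(sum(cats) - self.n_total) > 1e-6 * max(1, self.n_total):
            raise ConfigError("quadrant counts must sum to n_total")

    @property
    def n_pos_a(self) -> float:
        """All channel-A positives (single + double)."""
        return self.n_pos_a_only + self.n_double_pos

    @property
    def n_pos_b(self) -> float:
        return self.n_pos_b_only + self.n_double_pos

    def channel_a(self) -> ChannelCounts:
        return ChannelCounts(self.n_total, int(round(self.n_pos_a)))

    def channel_b(self) -> ChannelCounts:
        return ChannelCounts(self.n_total, int(round(self.n_pos_b)))

    def swapped(self) -> "TwoChannelCounts":
        """Channel labels exchanged (A↔B)."""
        return TwoChannelCounts(
            n_total=self.n_total,
            n_pos_a_only=self.n_pos_b_only,
            n_pos_b_only=self.n_pos_a_only,
            n_double_pos=self.n_double_pos,
            n_double_neg=self.n_double_neg,
        )


@dataclass(frozen=True)
class ConcentrationEstimate:
    """λ and copies/µL of reaction with a confidence interval."""

    lambda_mean_copies_per_droplet: float
    copies_per_ul_reaction: float
    ci_low: float
    ci_high: float
    confidence_level: float
    n_total: int
    n_positive: int

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.copies_per_ul_reaction <= self.ci_high):
            raise ConfigError("CI must bracket the point estimate")


@dataclass(frozen=True)
class SampleTiter:
    """Copies per mL of the original (undiluted) sample."""

    copies_per_ml_sample: float
    ci_low: float
    ci_high: float
    reaction_volume_ul: float
    sample_volume_ul: float
    dilution_factor: float


def counts_from_batch(batch: DropletBatch) -> TwoChannelCounts:
    """Quadrant counts from a simulated batch's latent channel states."""
    a = batch.ch1_positive
    b = batch.ch2_positive
    return TwoChannelCounts(
        n_total=batch.n_droplets,
        n_pos_a_only=int(np.sum(a & ~b)),
        n_pos_b_only=int(np.sum(~a & b)),
        n_double_pos=int(np.sum(a & b)),
        n_double_neg=int(np.sum(~a & ~b)),
    )


def classify_events(
    events: pd.DataFrame,
    threshold_ch1: float,
    threshold_ch2: float,
) -> TwoChannelCounts:
    """Threshold a two-channel event table into quadrant counts.

    A droplet is positive in a channel iff its amplitude exceeds that
    channel's threshold (replacing the reader software's gating).
    """
    if not (math.isfinite(threshold_ch1) and math.isfinite(threshold_ch2)):
        raise InputError("thresholds must be finite")
    if len(events) == 0:
        raise InputError("empty event table")
    for col in ("ch1_amplitude", "ch2_amplitude"):
        if col not in events.columns:
            raise InputError(f"event table lacks column {col!r}")
    a = events["ch1_amplitude"].to_numpy() > threshold_ch1
    b = events["ch2_amplitude"].to_numpy() > threshold_ch2
    return TwoChannelCounts(
        n_total=len(events),
        n_pos_a_only=int(np.sum(a & ~b)),
        n_pos_b_only=int(np.sum(~a & b)),
        n_double_pos=int(np.sum(a & b)),
        n_double_neg=int(np.sum(~a & ~b)),
    )


def estimate_lambda(
    counts: ChannelCounts, confidence_level: float = 0.95
) -> tuple[float, float, float]:
    """Poisson MLE of mean copies per droplet, with CI.

    Returns ``(lambda_hat, lambda_low, lambda_high)``. The Wilson score
    interval on the negative fraction is transformed through −ln; a
    zero-positive well yields λ̂ = 0 with a one-sided interval.

    Raises
    ------
    SaturationError
        If every droplet is positive (λ not estimable).
    """
    if counts.n_positive == counts.n_total:
        raise SaturationError(
            f"all {counts.n_total} droplets positive; concentration not estimable"
        )
    n_neg = counts.n_total - counts.n_positive
    lam = -math.log(n_neg / counts.n_total)
    p_neg_low, p_neg_high = proportion_confint(
        n_neg, counts.n_total, alpha=1 - confidence_level, method="wilson"
    )
    # negative-fraction bounds map to lambda bounds in reverse order
    lam_low = -math.log(min(p_neg_high, 1.0)) if p_neg_high > 0 else math.inf
    lam_high = -math.log(p_neg_low) if p_neg_low > 0 else math.inf
    # clamp: float round-off in the Wilson bounds must not push the
    # interval off the point estimate (notably at n_positive == 0)
    lam_low = min(max(lam_low, 0.0), lam)
    lam_high = max(lam_high, lam)
    return lam, lam_low, lam_high


def concentration_from_lambda(lam: float, droplet_volume_nl: float) -> float:
    """copies/µL = λ / (droplet volume in µL)."""
    if droplet_volume_nl <= 0:
        raise ConfigError("droplet_volume_nl must be > 0")
    if lam < 0:
        raise DomainError("lambda must be >= 0")
    return lam / (droplet_volume_nl / 1000.0)


def estimate_concentration(
    counts: ChannelCounts,
    droplet_volume_nl: float,
    confidence_level: float = 0.95,
) -> ConcentrationEstimate:
    """Full single-channel quantification: λ̂ with CI, scaled to copies/µL."""
    lam, lam_low, lam_high = estimate_lambda(counts, confidence_level)
    to_conc = lambda l: concentration_from_lambda(l, droplet_volume_nl)  # noqa: E731
    return ConcentrationEstimate(
        lambda_mean_copies_per_droplet=lam,
        copies_per_ul_reaction=to_conc(lam),
        ci_low=to_conc(lam_low),
        ci_high=to_conc(lam_high) if math.isfinite(lam_high) else math.inf,
        confidence_level=confidence_level,
        n_total=counts.n_total,
        n_positive=counts.n_positive,
    )


def sample_titer(conc: ConcentrationEstimate, cfg: AssayConfig) -> SampleTiter:
    """Back-calculate copies/mL of the original sample from the reaction
    concentration: conc × (reaction/sample volume) × dilution × 1000."""
    if cfg.sample_volume_ul <= 0:
        raise ConfigError("sample_volume_ul must be > 0")
    scale = (cfg.reaction_volume_ul / cfg.sample_volume_ul) * cfg.dilution_factor * 1000.0
    return SampleTiter(
        copies_per_ml_sample=conc.copies_per_ul_reaction * scale,
        ci_low=conc.ci_low * scale,
        ci_high=conc.ci_high * scale,
        reaction_volume_ul=cfg.reaction_volume_ul,
        sample_volume_ul=cfg.sample_volume_ul,
        dilution_factor=cfg.dilution_factor,
    )


def genome_to_infectious_ratio(
    genome_titer_copies_per_ml: float,
    infectious_titer_iu_per_ml: float,
    genome_ci: tuple[float, float] | None = None,
) -> float | tuple[float, float, float]:
    """Genome-titer : infectious-titer quotient of a prep.

    With ``genome_ci`` supplied, returns ``(ratio, lo, hi)`` by scaling
    the genome-titer interval (the infectious titer is treated as a
    known constant here).
    """
    if infectious_titer_iu_per_ml <= 0:
        raise DomainError("infectious titer must be > 0")
    if genome_titer_copies_per_ml < 0:
        raise DomainError("genome titer must be >= 0")
    ratio = genome_titer_copies_per_ml / infectious_titer_iu_per_ml
    if genome_ci is None:
        return ratio
    lo, hi = genome_ci
    return ratio, lo / infectious_titer_iu_per_ml, hi / infectious_titer_iu_per_ml
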