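"""Synthetic droplet-reaction generator.

Emulates the statistical structure of a droplet digital PCR (ddPCR)
experiment: a reaction partitioned into ~20,000 nanolitre water-in-oil
droplets, with target molecules partitioned Poisson, whole cells
encapsulated according to a Poisson or an empirically measured occupancy
distribution, cell infection at a given multiplicity of infection (MOI),
and free-floating RNA contamination partitioned independently of cells.

Latent per-droplet contents (copies, cells, infected cells) are kept
separate from the observed channel states so that estimators can be
validated against ground truth. Channel positivity is deterministic given
the latent contents: a channel is positive iff the droplet holds at least
one detectable template for that channel's target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DomainError

__all__ = [
    "EMPIRICAL_OCCUPANCY_PROBS",
    "AssayConfig",
    "VirusPrep",
    "CellAssayConfig",
    "AmplitudeModel",
    "DropletBatch",
    "sample_copies_per_droplet",
    "simulate_virus_assay",
    "sample_cell_occupancy",
    "infect_cells",
    "simulate_cell_assay",
    "render_amplitudes",
    "midpoint_thresholds",
]

#: Cell-occupancy distribution measured by droplet microscopy of 20,000
#: encapsulated BHK-21 cells: fractions of droplets holding 0, 1, 2 and 3
#: cells. Renormalised at use.
EMPIRICAL_OCCUPANCY_PROBS: tuple[float, ...] = (0.604, 0.283, 0.085, 0.028)


@dataclass(frozen=True)
class AssayConfig:
    """Physical layout of one ddPCR reaction well.

    Parameters
    ----------
    n_droplets
        Number of accepted droplets (fixed; reader-to-reader variation in
        accepted-droplet counts is not modelled).
    droplet_volume_nl
        Volume of a single droplet in nanolitres. All copies/µL
        conversions route through this constant.
    reaction_volume_ul
        Total assembled reaction volume in microlitres.
    sample_volume_ul
        Volume of (diluted) virus or cell suspension added to the
        reaction, in microlitres.
    dilution_factor
        Fold-dilution of the sample before addition; ≥ 1.
    """

    n_droplets: int = 20000
    droplet_volume_nl: float = 0.85
    reaction_volume_ul: float = 20.0
    sample_volume_ul: float = 2.0
    dilution_factor: float = 1.0
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ConfigError("n_droplets must be >= 1")
        for name in ("droplet_volume_nl", "reaction_volume_ul", "sample_volume_ul"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if self.dilution_factor < 1:
            raise ConfigError("dilution_factor must be >= 1")
        if self.n_droplets * self.droplet_volume_nl > self.reaction_volume_ul * 1000:
            raise ConfigError(
                "partitioned volume exceeds reaction volume: "
                f"{self.n_droplets} x {self.droplet_volume_nl} nL > "
                f"{self.reaction_volume_ul} uL"
            )


@dataclass(frozen=True)
class VirusPrep:
    """One virus preparation added to a (possibly duplex) reaction.

    ``genome_per_infectious_ratio`` is the genome-titer to
    infectious-titer quotient of the prep (damaged/non-infectious
    particles make it > 1); ``free_rna_fraction`` adds non-encapsidated
    RNA copies as a fraction of the particle genome copies.
    """

    label: str  # channel identifier, "FAM" or "HEX"
    infectious_titer_iu_per_ml: float
    genome_per_infectious_ratio: float = 1.0
    free_rna_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.label not in ("FAM", "HEX"):
            raise ConfigError(f"label must be 'FAM' or 'HEX', got {self.label!r}")
        if self.infectious_titer_iu_per_ml < 0:
            raise ConfigError("infectious_titer_iu_per_ml must be >= 0")
        if self.genome_per_infectious_ratio < 1:
            raise ConfigError("genome_per_infectious_ratio must be >= 1")
        if self.free_rna_fraction < 0:
            raise ConfigError("free_rna_fraction must be >= 0")

    def genome_titer_copies_per_ml(self) -> float:
        """Total detectable RNA copies per mL of undiluted prep."""
        return (
            self.infectious_titer_iu_per_ml
            * self.genome_per_infectious_ratio
            * (1.0 + self.free_rna_fraction)
        )


@dataclass(frozen=True)
class CellAssayConfig:
    """Everything the single-cell titer experiment needs.

    ``n_cells_total`` is the cell count of the infection well (N_cells in
    the titer equations); ``n_cells_loaded`` is the 1000–2000 cells added
    to the ddPCR reaction. ``free_actin_rna_rate`` and
    ``free_viral_rna_rate`` are expected free-floating RNA copies released
    per loaded (respectively, per loaded infected) cell — lysis debris
    during trypsinisation and droplet generation.
    """

    n_cells_total: int
    n_cells_loaded: int
    moi: float
    inoculum_volume_ml: float
    dilution_factor: float = 1.0
    occupancy_model: str = "empirical"
    occupancy_probs: tuple[float, ...] = EMPIRICAL_OCCUPANCY_PROBS
    free_actin_rna_rate: float = 0.0
    free_viral_rna_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cells_total < 1:
            raise ConfigError("n_cells_total must be >= 1")
        if not (0 <= self.n_cells_loaded <= self.n_cells_total):
            raise ConfigError("need 0 <= n_cells_loaded <= n_cells_total")
        if self.moi < 0:
            raise ConfigError("moi must be >= 0")
        if self.inoculum_volume_ml <= 0:
            raise ConfigError("inoculum_volume_ml must be > 0")
        if self.dilution_factor < 1:
            raise ConfigError("dilution_factor must be >= 1")
        if self.occupancy_model not in ("poisson", "empirical"):
            raise ConfigError("occupancy_model must be 'poisson' or 'empirical'")
        if self.occupancy_model == "empirical":
            if not self.occupancy_probs:
                raise ConfigError("empirical occupancy requires occupancy_probs")
            total = float(sum(self.occupancy_probs))
            if abs(total - 1.0) > 1e-6:
                raise ConfigError("occupancy_probs must sum to 1 (renormalised at use)")
        if self.free_actin_rna_rate < 0 or self.free_viral_rna_rate < 0:
            raise ConfigError("free RNA rates must be >= 0")


@dataclass(frozen=True)
class AmplitudeModel:
    """Two-channel Gaussian fluorescence cluster model.

    Per channel: negative and positive cluster means and a shared cluster
    standard deviation (arbitrary units). ``rain_fraction`` of positive
    droplets is drawn uniformly between the cluster means, mimicking
    partial-amplification "rain".
    """

    negative_mean: tuple[float, float] = (1000.0, 1000.0)
    positive_mean: tuple[float, float] = (8000.0, 8000.0)
    cluster_sd: tuple[float, float] = (300.0, 300.0)
    rain_fraction: float = 0.0

    def __post_init__(self) -> None:
        for ch in (0, 1):
            if self.positive_mean[ch] <= self.negative_mean[ch]:
                raise ConfigError("positive_mean must exceed negative_mean")
            if self.cluster_sd[ch] <= 0:
                raise ConfigError("cluster_sd must be > 0")
        if not (0 <= self.rain_fraction < 1):
            raise ConfigError("rain_fraction must be in [0, 1)")


@dataclass
class DropletBatch:
    """Latent and observed per-droplet state for one reaction well.

    ``ch1_copies`` / ``ch2_copies`` count free template copies (virion
    genomes or free-floating RNA) per droplet; cells and infected cells
    are carried separately. Channel 1 is the FAM target (β-actin in the
    cell assay), channel 2 the HEX target (viral gene).
    """

    ch1_copies: np.ndarray
    ch2_copies: np.ndarray
    cells: np.ndarray
    infected_cells: np.ndarray
    ch1_positive: np.ndarray
    ch2_positive: np.ndarray
    channel_targets: tuple[str, str] = ("FAM", "HEX")
    provenance: dict = field(default_factory=dict)

    @classmethod
    def from_latent(
        cls,
        ch1_copies: np.ndarray,
        ch2_copies: np.ndarray,
        cells: np.ndarray | None = None,
        infected_cells: np.ndarray | None = None,
        channel_targets: tuple[str, str] = ("FAM", "HEX"),
        provenance: dict | None = None,
    ) -> "DropletBatch":
        n = len(ch1_copies)
        if cells is None:
            cells = np.zeros(n, dtype=np.int64)
        if infected_cells is None:
            infected_cells = np.zeros(n, dtype=np.int64)
        # positivity rule: >=1 detectable template of the channel's target
        ch1_positive = (ch1_copies >= 1) | (cells >= 1)
        ch2_positive = (ch2_copies >= 1) | (infected_cells >= 1)
        return cls(
            ch1_copies=np.asarray(ch1_copies, dtype=np.int64),
            ch2_copies=np.asarray(ch2_copies, dtype=np.int64),
            cells=np.asarray(cells, dtype=np.int64),
            infected_cells=np.asarray(infected_cells, dtype=np.int64),
            ch1_positive=ch1_positive,
            ch2_positive=ch2_positive,
            channel_targets=channel_targets,
            provenance=provenance or {},
        )

    @property
    def n_droplets(self) -> int:
        return len(self.ch1_copies)


def _require_rng(rng: np.random.Generator) -> np.random.Generator:
    if not isinstance(rng, np.random.Generator):
        raise ConfigError("rng must be a numpy.random.Generator")
    return rng


def sample_copies_per_droplet(
    concentration_copies_per_ul: float,
    cfg: AssayConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partition a well-mixed target into droplets.

    Each droplet's copy count is Poisson(λ) with
    λ = concentration × droplet_volume_nl / 1000 — the standard digital
    PCR partitioning assumption.
    """
    if concentration_copies_per_ul < 0:
        raise DomainError("concentration must be >= 0")
    _require_rng(rng)
    lam = concentration_copies_per_ul * cfg.droplet_volume_nl / 1000.0
    return rng.poisson(lam, size=cfg.n_droplets).astype(np.int64)


def reaction_concentration_copies_per_ul(prep: VirusPrep, cfg: AssayConfig) -> float:
    """Detectable copies per µL of assembled reaction contributed by one prep."""
    copies_per_ml_diluted = prep.genome_titer_copies_per_ml() / cfg.dilution_factor
    copies_added = copies_per_ml_diluted * cfg.sample_volume_ul / 1000.0
    return copies_added / cfg.reaction_volume_ul


def simulate_virus_assay(
    preps: Sequence[VirusPrep],
    cfg: AssayConfig,
    rng: np.random.Generator,
) -> DropletBatch:
    """Simulate a singleplex or duplex virus-suspension well.

    Each prep's genome copies are partitioned independently; a channel is
    positive iff the droplet carries ≥1 copy of that channel's target.
    Double positives arise purely from random co-encapsulation.
    """
    if not 1 <= len(preps) <= 2:
        raise ConfigError("simulate_virus_assay takes 1 or 2 preps")
    labels = [p.label for p in preps]
    if len(set(labels)) != len(labels):
        raise ConfigError(f"duplicate channel labels: {labels}")
    _require_rng(rng)

    zeros = np.zeros(cfg.n_droplets, dtype=np.int64)
    copies = {"FAM": zeros, "HEX": zeros.copy()}
    for prep in preps:
        conc = reaction_concentration_copies_per_ul(prep, cfg)
        copies[prep.label] = sample_copies_per_droplet(conc, cfg, rng)

    return DropletBatch.from_latent(
        ch1_copies=copies["FAM"],
        ch2_copies=copies["HEX"],
        channel_targets=("FAM", "HEX"),
        provenance={
            "kind": "virus_assay",
            "assay": asdict(cfg),
            "preps": [asdict(p) for p in preps],
        },
    )


def sample_cell_occupancy(
    cell_cfg: CellAssayConfig,
    cfg: AssayConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw cells-per-droplet for every droplet.

    ``poisson``: homogeneous loading at λ_cell = n_cells_loaded /
    n_droplets. ``empirical``: i.i.d. draws from the measured occupancy
    category distribution (which encodes the non-homogeneous clumping
    seen under the microscope).
    """
    _require_rng(rng)
    if cell_cfg.n_cells_loaded == 0:
        return np.zeros(cfg.n_droplets, dtype=np.int64)
    if cell_cfg.occupancy_model == "poisson":
        lam = cell_cfg.n_cells_loaded / cfg.n_droplets
        return rng.poisson(lam, size=cfg.n_droplets).astype(np.int64)
    probs = np.asarray(cell_cfg.occupancy_probs, dtype=float)
    probs = probs / probs.sum()
    return rng.choice(len(probs), size=cfg.n_droplets, p=probs).astype(np.int64)


def infect_cells(n_cells: int, moi: float, rng: np.random.Generator) -> np.ndarray:
    """Flag each cell independently infected with P = 1 − e^(−MOI)."""
    if moi < 0:
        raise DomainError("moi must be >= 0")
    if n_cells < 0:
        raise DomainError("n_cells must be >= 0")
    _require_rng(rng)
    p = 1.0 - np.exp(-moi)
    return rng.random(n_cells) < p


def simulate_cell_assay(
    cell_cfg: CellAssayConfig,
    cfg: AssayConfig,
    rng: np.random.Generator,
) -> DropletBatch:
    """Simulate a single-cell duplex well (β-actin-FAM / viral-HEX).

    Droplets receive whole cells per the occupancy model; each
    encapsulated cell is independently infected with P = 1 − e^(−MOI).
    Free-floating RNA from cell damage is partitioned independently of
    the cells: β-actin copies Poisson with reaction-wide mean
    n_cells_loaded × free_actin_rna_rate, viral copies Poisson with mean
    (realised infected loaded cells) × free_viral_rna_rate. Channel 1 is
    positive iff the droplet holds ≥1 cell or ≥1 free β-actin copy;
    channel 2 iff ≥1 infected cell or ≥1 free viral copy.
    """
    _require_rng(rng)
    cells = sample_cell_occupancy(cell_cfg, cfg, rng)
    p_inf = 1.0 - np.exp(-cell_cfg.moi)
    infected = rng.binomial(cells, p_inf).astype(np.int64)

    lam_actin = cell_cfg.n_cells_loaded * cell_cfg.free_actin_rna_rate / cfg.n_droplets
    n_infected_loaded = int(rng.binomial(cell_cfg.n_cells_loaded, p_inf))
    lam_viral = n_infected_loaded * cell_cfg.free_viral_rna_rate / cfg.n_droplets

    free_actin = rng.poisson(lam_actin, size=cfg.n_droplets).astype(np.int64)
    free_viral = rng.poisson(lam_viral, size=cfg.n_droplets).astype(np.int64)

    return DropletBatch.from_latent(
        ch1_copies=free_actin,
        ch2_copies=free_viral,
        cells=cells,
        infected_cells=infected,
        channel_targets=("FAM", "HEX"),
        provenance={
            "kind": "cell_assay",
            "assay": asdict(cfg),
            "cell": asdict(cell_cfg),
            "n_infected_loaded": n_infected_loaded,
        },
    )


def midpoint_thresholds(model: AmplitudeModel) -> tuple[float, float]:
    """Per-channel midpoint between the negative and positive cluster means."""
    return (
        0.5 * (model.negative_mean[0] + model.positive_mean[0]),
        0.5 * (model.negative_mean[1] + model.positive_mean[1]),
    )


def render_amplitudes(
    batch: DropletBatch,
    model: AmplitudeModel,
    rng: np.random.Generator,
    well_id: str = "A01",
) -> pd.DataFrame:
    """Render latent channel states into a two-channel amplitude table.

    Negative droplets draw from the negative Gaussian cluster, positives
    from the positive cluster; a ``rain_fraction`` of positives draws
    uniformly between the cluster means instead. Returns the event table
    (columns well_id, droplet_index, ch1_amplitude, ch2_amplitude).
    """
    _require_rng(rng)
    n = batch.n_droplets
    amps = {}
    for ch, positive in ((0, batch.ch1_positive), (1, batch.ch2_positive)):
        neg_mu, pos_mu = model.negative_mean[ch], model.positive_mean[ch]
        sd = model.cluster_sd[ch]
        amp = rng.normal(neg_mu, sd, size=n)
        amp_pos = rng.normal(pos_mu, sd, size=n)
        amp = np.where(positive, amp_pos, amp)
        if model.rain_fraction > 0:
            rain = positive & (rng.random(n) < model.rain_fraction)
            amp = np.where(rain, rng.uniform(neg_mu, pos_mu, size=n), amp)
        amps[ch] = amp
    return pd.DataFrame(
        {
            "well_id": well_id,
            "droplet_index": np.arange(n, dtype=np.int64),
            "ch1_amplitude": amps[0],
            "ch2_amplitude": amps[1],
        }
    )
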