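"""Simulator statistics: Poisson partitioning, occupancy, infection,
amplitude rendering, and seed determinism."""

import dataclasses
import math

import numpy as np
import pytest

from dropquant import (
    AmplitudeModel,
    AssayConfig,
    CellAssayConfig,
    ConfigError,
    DomainError,
    EMPIRICAL_OCCUPANCY_PROBS,
    VirusPrep,
    infect_cells,
    midpoint_thresholds,
    render_amplitudes,
    sample_cell_occupancy,
    sample_copies_per_droplet,
    simulate_cell_assay,
    simulate_virus_assay,
)
from dropquant.presets import infectious_titer_for_lambda, reference_cell_config


def lam_to_conc(lam: float, assay: AssayConfig) -> float:
    return lam / (assay.droplet_volume_nl / 1000.0)


class TestPartitioning:
    def test_zero_concentration_gives_empty_reaction(self, assay, rng):
        copies = sample_copies_per_droplet(0.0, assay, rng)
        assert copies.shape == (assay.n_droplets,)
        assert not copies.any()

    def test_negative_concentration_rejected(self, assay, rng):
        with pytest.raises(DomainError):
            sample_copies_per_droplet(-1.0, assay, rng)

    @pytest.mark.parametrize(
        "lam, expected_zero_frac",
        [(0.5, math.exp(-0.5)), (1.0, math.exp(-1.0))],
    )
    def test_zero_fraction_matches_poisson(self, assay, rng, lam, expected_zero_frac):
        copies = sample_copies_per_droplet(lam_to_conc(lam, assay), assay, rng)
        zero_frac = np.mean(copies == 0)
        sd = math.sqrt(expected_zero_frac * (1 - expected_zero_frac) / assay.n_droplets)
        assert abs(zero_frac - expected_zero_frac) < 3 * sd

    def test_high_occupancy_nearly_all_positive(self, assay, rng):
        copies = sample_copies_per_droplet(lam_to_conc(5.0, assay), assay, rng)
        assert np.mean(copies > 0) >= 0.99

    def test_partition_conserves_total_copies(self, assay, rng):
        lam = 0.7
        copies = sample_copies_per_droplet(lam_to_conc(lam, assay), assay, rng)
        expected_total = lam * assay.n_droplets
        assert abs(copies.sum() - expected_total) < 3 * math.sqrt(expected_total)


class TestVirusAssay:
    def test_zero_titers_all_double_negative(self, assay, rng):
        preps = [
            VirusPrep(label="FAM", infectious_titer_iu_per_ml=0.0),
            VirusPrep(label="HEX", infectious_titer_iu_per_ml=0.0),
        ]
        batch = simulate_virus_assay(preps, assay, rng)
        assert not batch.ch1_positive.any() and not batch.ch2_positive.any()

    def test_duplicate_labels_rejected(self, assay, rng):
        preps = [
            VirusPrep(label="FAM", infectious_titer_iu_per_ml=1.0),
            VirusPrep(label="FAM", infectious_titer_iu_per_ml=1.0),
        ]
        with pytest.raises(ConfigError):
            simulate_virus_assay(preps, assay, rng)

    def test_single_prep_positive_fraction(self, assay, rng):
        titer = infectious_titer_for_lambda(1.0, 1.0, assay)
        batch = simulate_virus_assay(
            [VirusPrep(label="FAM", infectious_titer_iu_per_ml=titer)], assay, rng
        )
        expected = 1 - math.exp(-1.0)
        sd = math.sqrt(expected * (1 - expected) / assay.n_droplets)
        assert abs(batch.ch1_positive.mean() - expected) < 3 * sd
        assert not batch.ch2_positive.any()

    def test_double_positive_fraction_under_independence(self, assay, rng):
        titer = infectious_titer_for_lambda(0.1, 1.0, assay)
        preps = [
            VirusPrep(label="FAM", infectious_titer_iu_per_ml=titer),
            VirusPrep(label="HEX", infectious_titer_iu_per_ml=titer),
        ]
        batch = simulate_virus_assay(preps, assay, rng)
        dp_frac = np.mean(batch.ch1_positive & batch.ch2_positive)
        expected = (1 - math.exp(-0.1)) ** 2  # ~0.00906
        sd = math.sqrt(expected * (1 - expected) / assay.n_droplets)
        assert abs(dp_frac - expected) < 2.58 * sd

    def test_free_rna_fraction_raises_genome_copies(self, assay, rng):
        base = VirusPrep(label="FAM", infectious_titer_iu_per_ml=1e5,
                         genome_per_infectious_ratio=10.0)
        inflated = dataclasses.replace(base, free_rna_fraction=0.5)
        assert inflated.genome_titer_copies_per_ml() == pytest.approx(
            1.5 * base.genome_titer_copies_per_ml()
        )


class TestCellOccupancy:
    def test_no_cells_loaded_all_empty(self, assay, rng):
        cfg = reference_cell_config(with_free_rna=False)
        cfg = dataclasses.replace(cfg, n_cells_loaded=0)
        assert not sample_cell_occupancy(cfg, assay, rng).any()

    def test_poisson_empty_fraction(self, assay, rng):
        cfg = reference_cell_config(with_free_rna=False, occupancy_model="poisson")
        cells = sample_cell_occupancy(cfg, assay, rng)
        expected = math.exp(-cfg.n_cells_loaded / assay.n_droplets)  # e^-0.1
        sd = math.sqrt(expected * (1 - expected) / assay.n_droplets)
        assert abs(np.mean(cells == 0) - expected) < 3 * sd
        assert cells.mean() == pytest.approx(cfg.n_cells_loaded / assay.n_droplets, rel=0.1)

    def test_empirical_frequencies_match_measured_distribution(self, assay, rng):
        cfg = reference_cell_config(with_free_rna=False, occupancy_model="empirical")
        cells = sample_cell_occupancy(cfg, assay, rng)
        for k, p in enumerate(EMPIRICAL_OCCUPANCY_PROBS):
            freq = np.mean(cells == k)
            sd = math.sqrt(p * (1 - p) / assay.n_droplets)
            assert abs(freq - p) < 2.81 * sd  # simultaneous 99% (Bonferroni over 4)

    def test_empirical_model_requires_probs(self):
        with pytest.raises(ConfigError):
            CellAssayConfig(
                n_cells_total=10_000,
                n_cells_loaded=2000,
                moi=0.1,
                inoculum_volume_ml=0.01,
                occupancy_model="empirical",
                occupancy_probs=(),
            )


class TestInfection:
    def test_moi_zero_infects_nobody(self, rng):
        assert not infect_cells(5000, 0.0, rng).any()

    @pytest.mark.parametrize("moi, expected", [(11.0, 1 - math.exp(-11)),
                                               (0.074, 1 - math.exp(-0.074))])
    def test_infected_fraction(self, rng, moi, expected):
        n = 200_000
        flags = infect_cells(n, moi, rng)
        sd = math.sqrt(expected * (1 - expected) / n) if expected < 1 else 1e-4
        assert abs(flags.mean() - expected) < max(3 * sd, 1e-4)

    def test_negative_moi_rejected(self, rng):
        with pytest.raises(DomainError):
            infect_cells(10, -0.1, rng)


class TestCellAssay:
    def test_no_infection_no_viral_channel(self, assay, rng):
        cfg = dataclasses.replace(reference_cell_config(False), moi=0.0)
        batch = simulate_cell_assay(cfg, assay, rng)
        assert not batch.ch2_positive.any()

    def test_viral_channel_equals_infected_droplets_without_free_rna(self, assay, rng):
        cfg = reference_cell_config(with_free_rna=False)
        cfg = dataclasses.replace(cfg, moi=0.5)
        batch = simulate_cell_assay(cfg, assay, rng)
        assert batch.ch2_positive.sum() == (batch.infected_cells >= 1).sum()

    def test_free_actin_rna_inflates_apparent_copies_tenfold(self, assay, rng):
        # 9 free copies per loaded cell: total actin templates ~= 10x cells
        cfg = dataclasses.replace(
            reference_cell_config(with_free_rna=False), free_actin_rna_rate=9.0
        )
        batch = simulate_cell_assay(cfg, assay, rng)
        total_templates = batch.cells.sum() + batch.ch1_copies.sum()
        assert total_templates == pytest.approx(10 * cfg.n_cells_loaded, rel=0.05)


class TestAmplitudes:
    def test_round_trip_classification_is_exact_without_rain(self, assay, rng):
        titer = infectious_titer_for_lambda(0.5, 1.0, assay)
        batch = simulate_virus_assay(
            [VirusPrep(label="FAM", infectious_titer_iu_per_ml=titer)], assay, rng
        )
        model = AmplitudeModel()  # >10 sd separation, no rain
        events = render_amplitudes(batch, model, rng)
        t1, t2 = midpoint_thresholds(model)
        recovered = events["ch1_amplitude"].to_numpy() > t1
        assert np.array_equal(recovered, batch.ch1_positive)

    def test_all_negative_batch_stays_in_negative_cluster(self, assay, rng):
        batch = simulate_virus_assay(
            [VirusPrep(label="FAM", infectious_titer_iu_per_ml=0.0)], assay, rng
        )
        model = AmplitudeModel()
        events = render_amplitudes(batch, model, rng)
        assert events["ch1_amplitude"].max() < model.negative_mean[0] + 6 * model.cluster_sd[0]

    def test_rain_fraction_lands_between_clusters(self, assay, rng):
        titer = infectious_titer_for_lambda(1.0, 1.0, assay)
        batch = simulate_virus_assay(
            [VirusPrep(label="FAM", infectious_titer_iu_per_ml=titer)], assay, rng
        )
        model = AmplitudeModel(rain_fraction=0.05)
        events = render_amplitudes(batch, model, rng)
        amp = events.loc[batch.ch1_positive, "ch1_amplitude"]
        # rain is uniform between the cluster means: the expected fraction
        # of positives landing >6 sd away from both means follows directly
        lo = model.negative_mean[0] + 6 * model.cluster_sd[0]
        hi = model.positive_mean[0] - 6 * model.cluster_sd[0]
        span = model.positive_mean[0] - model.negative_mean[0]
        expected = 0.05 * (hi - lo) / span
        rain_frac = ((amp > lo) & (amp < hi)).mean()
        n_pos = int(batch.ch1_positive.sum())
        sd = math.sqrt(expected * (1 - expected) / n_pos)
        assert abs(rain_frac - expected) < 3 * sd


class TestDeterminism:
    def test_same_seed_reproduces_batch_and_event_table(self, assay):
        cfg = reference_cell_config(with_free_rna=True)

        def run():
            rng = np.random.default_rng(42)
            batch = simulate_cell_assay(cfg, assay, rng)
            events = render_amplitudes(batch, AmplitudeModel(), np.random.default_rng(7))
            return batch, events.to_csv(index=False)

        b1, csv1 = run()
        b2, csv2 = run()
        assert np.array_equal(b1.cells, b2.cells)
        assert np.array_equal(b1.ch2_positive, b2.ch2_positive)
        assert csv1 == csv2


class TestConfigValidation:
    def test_partitioned_volume_cannot_exceed_reaction(self):
        with pytest.raises(ConfigError):
            AssayConfig(n_droplets=30_000, droplet_volume_nl=0.85, reaction_volume_ul=20)

    def test_amplitude_model_requires_separated_clusters(self):
        with pytest.raises(ConfigError):
            AmplitudeModel(negative_mean=(1000, 1000), positive_mean=(900, 8000))
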