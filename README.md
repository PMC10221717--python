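# dropquant

Droplet digital PCR (ddPCR) quantification of recombinant RNA virus
preparations — genome titers, two-virus mixtures, and infectious titers
measured by single-cell droplet PCR — together with a synthetic droplet
simulator that generates the data these estimators consume.

## The problem

A ddPCR reaction is partitioned into ~20,000 nanolitre droplets; each
droplet reports only whether its target amplified. With copies
Poisson-distributed across droplets, the negative fraction estimates
e^(−λ), so the mean copies per droplet is

    λ̂ = −ln(n_negative / n_total)

and concentration follows from the droplet volume. This gives absolute
genome titers (vp/mL) without a standard curve — but genome titer and
infectious titer (iu/mL) differ prep by prep, because preparations carry
damaged particles and non-encapsidated RNA.

To measure *infectious* titer, whole infected cells are encapsulated in
the droplets and a duplex assay reads a cell-marker channel (β-actin)
and a viral channel. The infected-cell fraction can be estimated two
ways:

1. **Double-positive counting**: `titer = (N⁺⁺ / N_actin⁺) × N_cells ×
   dilution / V`. Free-floating viral RNA from lysed cells lands in
   droplets with uninfected cells and inflates N⁺⁺, so this
   overestimates.
2. **Linkage**: the concentration of entities carrying *both* targets,
   `λ_linked = λ_A + λ_B − λ_union`, i.e. double positives beyond the
   random co-encapsulation expectation. `titer = (linkage / c_actin) ×
   N_cells × dilution / V`. Free viral RNA cancels out of the linkage
   numerator, making this estimator far closer to the truth under
   contamination.

The package implements the partition-Poisson estimator (with Wilson
score confidence intervals mapped through −ln), duplex marginals, the
three-species-Poisson linkage statistic, both titer equations, MOI
bookkeeping, and a simulator for droplet reactions with virus
partitioning, empirical or Poisson cell occupancy, Poisson infection at
a given MOI, and free-RNA contamination.

## Worked example

```python
import numpy as np
from dropquant import (AssayConfig, VirusPrep, simulate_virus_assay,
                       counts_from_batch, estimate_concentration, sample_titer)

assay = AssayConfig()          # 20,000 droplets of 0.85 nL, 20 µL reaction
prep = VirusPrep(label="FAM", infectious_titer_iu_per_ml=1.75e5,
                 genome_per_infectious_ratio=20.16)

batch = simulate_virus_assay([prep], assay, np.random.default_rng(1))
counts = counts_from_batch(batch)
conc = estimate_concentration(counts.channel_a(), assay.droplet_volume_nl)
titer = sample_titer(conc, assay)
print(f"lambda = {conc.lambda_mean_copies_per_droplet:.4f}")
print(f"genome titer = {titer.copies_per_ml_sample:.3e} copies/mL")
print(f"genome:infectious = {titer.copies_per_ml_sample / 1.75e5:.2f}")
```

prints

```
lambda = 0.3008
genome titer = 3.539e+06 copies/mL
genome:infectious = 20.22
```

— a single well at mean occupancy λ ≈ 0.3 recovers the configured
genome:infectious ratio of 20.16 to within sampling error (averaging
wells tightens it; see `analysis/01_single_virus_quantification.py`).

## Analysis scripts

Numbered drivers under `analysis/` run the three in-silico experiments
end to end and write tables under `results/`:

* `01_single_virus_quantification.py` — gradient linearity (slope ≈ 1,
  R² > 0.999) and recovery of the 20.16 and 3.53 genome:infectious
  ratios.
* `02_duplex_mixture.py` — both marginal titers of a two-virus mix
  recovered within a few percent; the focal estimate is stable under a
  740-fold partner variation; extreme virus:virus ratios inflate the
  minor target's variability.
* `03_single_cell_titer.py` — with free-RNA contamination the
  double-positive estimator overshoots the reference titer severalfold
  while the linkage estimator stays close; linkage increases
  monotonically with MOI.

A `dropquant` console script exposes the same pipeline stages
(`simulate`, `quantify`, `duplex`, `titer`, `run-scenario`,
`summarize`); see `dropquant --help`.

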