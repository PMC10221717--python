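# Methods

## Partition model and concentration estimation

A reaction of volume `reaction_volume_ul` is partitioned into
`n_droplets` droplets of `droplet_volume_nl` each. A well-mixed target
at concentration c copies/µL yields per-droplet copy counts that are
independent Poisson with mean λ = c × v, v the droplet volume in µL.
Droplets report a binary outcome per channel (≥1 detectable template ⇒
positive), so the sufficient statistic per channel is (n_total,
n_positive) and per duplex well the 2×2 quadrant table.

The concentration estimator is the Poisson maximum-likelihood estimate
from the negative fraction, λ̂ = −ln(n_neg/n_total); it maximises the
binomial likelihood with success probability 1 − e^(−λ) (verified in
the tests against brute-force likelihood maximisation). Confidence
intervals: Wilson score interval on the negative fraction, endpoints
mapped through −ln and scaled by 1/v. The Wilson interval was chosen
for its behaviour at extreme fractions — at zero positives it
degenerates gracefully to a one-sided interval with λ̂ = 0, and it
never produces negative bounds. Saturated wells (all droplets positive)
raise a typed error rather than returning infinity, so titer arithmetic
downstream can never silently propagate non-finite values. Real
droplet readers report per-well intervals by their own (undisclosed)
convention; the Wilson choice is this package's own.

Droplet volume defaults to 0.85 nL, the nominal partition volume of the
instrument class modelled; it is configurable and every copies/µL
conversion routes through this single constant.

## Duplex marginals and linkage

Each marginal of a duplex well is estimated from that channel's total
positive count (single-positive + double-positive) alone; partner
concentration affects it only through co-encapsulation, which the
marginal count already includes, so the estimate of one virus is
invariant to the other's abundance.

Linkage quantifies double positives beyond the random co-encapsulation
expectation. Under a three-species Poisson model — free-A entities at
mean occupancy λ_a, free-B at λ_b, linked AB entities at λ_L, all
partitioned independently —

    λ_A = λ_a + λ_L,   λ_B = λ_b + λ_L,   λ_union = λ_a + λ_b + λ_L

with λ_union = −ln(n_doubleneg/n_total), hence λ_L = λ_A + λ_B −
λ_union. This is the plug-in MLE of the linked-species occupancy;
divided by the droplet volume it is a concentration (copies/µL). On
quadrant counts built from the model's exact probabilities the closed
form returns λ_L to machine precision. Sampling noise can make the raw
value negative under the null; the reported value is clipped at 0 and
the signed value retained for calibration. Commercial analysis software
computes a statistic of the same name; equivalence with any vendor
implementation is not claimed — this closed form is the unique
consistent estimator under the stated random-encapsulation model.

In the single-cell assay the "linked species" is the infected cell:
β-actin and viral RNA co-occur in a droplet because they sit in the
same cell. Free-floating RNA of either target adds equally to the
corresponding marginal and to the union rate, so it cancels out of λ_L
exactly — the mechanism that makes the linkage titer robust where the
double-positive titer is not.

When any quadrant holds fewer than 10 droplets a warning is emitted
(real readers often cannot separate clusters in that regime) but the
estimate is still returned; suppression would hide exactly the cases a
user needs to see.

## Titer equations

Both estimators convert an infected-cell fraction f into
titer = f × N_cells × dilution / V (V the inoculum volume in mL,
N_cells the total cells in the infection well):

* double-positive: f = N⁺⁺ / N_actin⁺ — implemented exactly as stated,
  with no subtraction of the expected random double positives, because
  reproducing its contamination bias is the point;
* linkage: f = linkage / c_actin, both in copies/µL.

Both count infected *cells*, not infectious units; at MOI ≤ 0.1 the two
agree within 5% under Poisson infection. An optional Poisson correction
iu = N_cells × (−ln(1−f)) inverts multiple infection at higher MOI; it
is off by default, matching the equations as used.

## The synthetic droplet generator

The simulator emulates, per droplet: target genome copies (Poisson,
independent per target — duplex double positives arise purely from
random co-encapsulation), whole-cell occupancy, per-cell Bernoulli
infection with P = 1 − e^(−MOI), free-RNA contamination, and Gaussian
two-channel fluorescence clusters with optional uniform "rain" between
the cluster means. Latent contents and observed channel states are kept
separate so estimators can be scored against ground truth. A single
seeded generator drives each simulation call and the seed is recorded
in the batch provenance; identical configuration and seed reproduce the
exported event table byte for byte.

Cell occupancy offers two models. The *empirical* model draws from the
measured 0/1/2/3-cell droplet fractions (60.4 / 28.3 / 8.5 / 2.8%,
renormalised), reproducing the clumping observed under the microscope
at 20,000 loaded cells; the distribution is used as given, including
its truncation at three cells. The *Poisson* model (λ_cell =
n_cells_loaded/n_droplets) fits the 1000–2000-cells-per-reaction regime
the titer assay actually uses, where the empirical table's absolute
loading would not apply; the titer analyses therefore default to
Poisson occupancy with 2000 loaded cells.

Free-floating RNA is modelled as reaction-wide Poisson counts
partitioned independently of cells — the simplest mechanism for lysis
debris. Default contamination rates in the single-cell scenario: 1
free β-actin copy per loaded cell, doubling the apparent cell count
(the low end of the observed 2–10× inflation), and 75 free viral
copies per loaded infected cell, reflecting replicon-amplified
transcripts released by a lysed cell and reproducing a severalfold
double-positive-titer overestimate.

Infection is Poisson at the cell level (P(infected) = 1 − e^(−MOI));
the underlying assays report only MOI, so this standard model is a
package choice. The reference single-cell configuration (2×10⁶ cells
infected with 0.01 mL of inoculum at 1.73×10⁷ iu/mL) gives MOI ≈ 0.087,
inside the low-MOI regime the estimators assume.

What the generator does **not** emulate: PCR chemistry and
reverse-transcription efficiency, annealing-temperature effects on
cluster separation, variable accepted-droplet counts, droplet-size
dispersion, cell-size-dependent encapsulation, or correlated lysis
(free RNA concentrated near its source cell). Passing tests therefore
demonstrate correctness of the estimators under the stated statistical
model, not robustness to every instrument artefact.

## Scenario sizes and numerical choices

Analyses run 20,000-droplet wells: ratio recovery averages 10 wells at
λ ≈ 0.3 (the clean-separation operating point); titer comparisons
average 20 wells; duplex recovery uses 3–5 wells with the mixture
diluted so both targets sit at λ ≈ 0.1–0.6; the estimator-consistency
check uses one 200,000-droplet well. Null calibration of linkage and
CI coverage each use 500 wells, drawing quadrant/positive counts
directly from the model's exact multinomial/binomial marginals, which
is distributionally identical to materialising the droplets.
Summaries report mean ± SEM over replicate wells; SEM is omitted below
two replicates.

Degenerate inputs are typed errors, not sentinel values: saturated
channels, empty event tables, zero cell-marker signal, fraction ≥ 1
under Poisson correction. Linked fractions above 1 are returned with a
warning (free marker RNA inflates the denominator, never the
numerator, so >1 signals a model violation worth surfacing).

The sample volume added per reaction is a free configuration parameter
(default 2 µL of a 20 µL reaction); no reference value exists for it,
and all recoveries are invariant to it because simulation and
estimation share the same unit chain.

## Known limitations

* The linkage estimator's variance grows quickly as the union approaches
  saturation or the double-negative count shrinks; at high MOI its
  point estimate is noisy (visible in the MOI sweep's SEM).
* The empirical occupancy distribution is tied to the loading density
  at which it was measured; using it at other densities changes only
  the shape, not the total cell count, of the simulated wells.
* Eq.-style titers assume the infected:uninfected ratio is unaffected
  by cell degradation. Simulation supports this only for moderate,
  proportional lysis (doubling both free-RNA rates from a low base
  moves the linkage titer < 10%); heavy marker-RNA release degrades it.
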