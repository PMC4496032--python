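# Methods

`thermogerm` models the germination response of Kentucky bluegrass
(*Poa pratensis* L.) seed to diurnal temperature regimes and turns fitted
response surfaces into monthly sowing-suitability maps. This note
documents the models, the data conventions, the numerical choices, and
the known limitations — including two inconsistencies in the reference
data that the test suite deliberately leaves failing.

## The assay and its data model

A diurnal regime holds seeds for 16 h at a cool-period temperature T1 and
8 h at a warm-period temperature T2, with both on the 5–40 °C grid in
5 °C steps and T2 ≥ T1 — 36 regimes on the half grid, constant regimes on
the diagonal. Each regime is scored as cumulative germination percentage
at the 15–20-day endpoint over three replicates of 50 seeds. Percentages
are stored as printed (one decimal); all model fitting uses fractions in
[0, 1].

The packaged reference tables for the five cultivars ('Midnight II',
'Diva', 'Rugby II', 'Leopard', 'Sapphire') are transcribed from a
published assay. The source's per-cultivar table captions are internally
inconsistent with its own summary statistics and narrative: the table
printed under one cultivar's name reproduces a different cultivar's
summary column exactly (a three-way label cycle among 'Rugby II',
'Leopard' and 'Sapphire'), and the narrative's statement that 'Leopard'
had the highest maximum (87.3 %) identifies the correct owner of that
table body. The packaged fixtures follow the summary/narrative
assignment, which two of the three reassigned cultivars match to every
printed decimal. The third ('Sapphire') still disagrees with the source's
summary in two of five metrics (profile mean 28.9 vs 28.6; mean of some
germination 47.3 vs 46.8); a single ~11-point cell misprint would explain
both, but the true value is unrecoverable, so those two comparisons are
left failing in the acceptance tests rather than papered over.

### Replicate reconstruction

The source prints only cell means and SDs. When replicate-level fitting
is requested, each cell is expanded to the triple {m − s, m, m + s},
whose mean and sample SD (ddof = 1) equal the printed values exactly,
then clamped to [0, 100] and rounded to the nearest 2 % (one seed in 50).
This is an explicit approximation: it reproduces the first two moments
but not the (unknown) empirical replicate spread shape. Mean-level
fitting needs no reconstruction and is the default elsewhere.

### Optimum-germination rule

"Optimum" regimes are those within h of the maximum cell mean. The CI
behind h is under-specified in the source (SD vs SE, t vs z), so the rule
is pluggable: the default is h = t(0.975, n−1)·sd_max/√n (the half-width
of the maximum cell's 95 % CI with n = 3 replicates); a z·sd variant and
a fixed-count rule are provided. No single rule reproduces the source's
"mean of optima" row for all cultivars, and the package reports that
metric under its documented default without claiming agreement.

## Response-surface models

* **Generalized quadratic** — Y = A0 + A1·T1 + A2·T2 + A3·T1² + A4·T2² +
  A5·T1·T2, fit by OLS. Six coefficients cannot bend around the sharp
  optimum ridge; in-sample RMSE plateaus near 0.19 for every cultivar.
* **General quintic** — all 21 bivariate monomials of total degree ≤ 5
  (fixed order: intercept, then m = 1..5 with n = 0..m for T1ⁿT2^(m−n)),
  fit by OLS; full-rank on the 36-point half grid.
* **BP-refined polynomials** — gradient descent on MSE from the OLS
  start, on z-scored features (raw quintic monomials span ~10 orders of
  magnitude), with guarded steps (a step that raises MSE is undone and
  the learning rate halved). Starting from the OLS optimum of a
  linear-in-parameters model, refinement cannot reduce in-sample MSE
  further, so these variants tie their OLS parents up to numerical noise;
  they are retained to make the model family comparison explicit.
* **BP-ANN** — a 2 → H → 1 network, sigmoid hidden and output units with
  per-unit thresholds (biases entering as w·x − θ), inputs scaled by
  1/40 so the assay grid maps to [0.125, 1]. The sigmoid output unit
  confines predictions to (0, 1) by construction. Training is full-batch
  gradient descent on MSE with a classic momentum term (0.9) and an
  adaptive "bold driver" step: a failed step is undone, the rate halved
  and the velocity reset; a successful step grows the rate by 5 %.
  Momentum is part of the design because plain guarded descent converged
  an order of magnitude too slowly on this problem, stalling well short
  of the loss levels a quasi-Newton probe showed to be attainable.

Polynomial predictions are clamped to [0, 1] only at the prediction
interface (`predict`), never during fitting; `evaluate` exposes the raw
surface. Baseline RMSE figures quoted for the quadratic are the raw
in-sample residual RMSE of the OLS fit; the deployed (clamped)
predictions score ~0.015 lower because the clamp pulls the negative
corner predictions toward the zero observations there.

## The GA-BP-ANN hybrid

The hybrid is a genetic algorithm over network genomes with BP as
Lamarckian local search — a memetic algorithm. A genome is the
architecture H plus the flat 4H + 1 parameter vector; genomes and
networks convert losslessly. Per generation: evaluate (fitness =
training RMSE), BP-refine the current top k (refined weights kept only
when they improve — monotone), carry elites over unchanged, select
parents by tournament (without replacement, size 3), recombine, mutate.
Crossover blends same-architecture parents arithmetically with a shared
α ~ U(0, 1) and swaps hidden-unit blocks across architectures; mutation
perturbs genes with probability 0.05 by N(0, 0.1) and changes H by ±1
with probability 0.05 (new units enter with small weights). Ties on
fitness resolve to the lower index; a single seeded generator drives
every draw, so identical (data, config, seed) reproduce the full run
including histories.

Defaults: population 50, ≤ 200 generations with early stop after 30
stagnant ones, crossover 0.8, elites 2, H ∈ [3, 12], BP refinement of the
top 5 with 150 epochs at rate 0.5. The refinement budget is the
load-bearing choice: the hybrid behaves like a population of restarted
BP runs whose initializations are under selection, and with too few
refinement epochs per generation it underfits every cultivar; 150 epochs
brings training RMSE within a few thousandths of the quasi-Newton
optimum at about seven seconds per run on one core. Fitness is training
RMSE only; held-out RMSE is reported, never optimized.

## Evaluation protocol

Replicate-level data (108 pairs) are split 90/18. The test set holds one
replicate from each of 18 designated regimes: all 8 constant (diagonal)
regimes — which include the severe 5/5 and 40/40 and the moderate 25/25 —
plus 10 fluctuating regimes drawn by a seeded stratified draw across the
ΔT = T2 − T1 strata (round-robin over ΔT in increasing order). Every
regime therefore keeps at least two replicates in training.

RMSE is √(mean squared error) on fractions. Because the evaluation set
behind published single-number model comparisons is rarely stated, the
comparison table reports three RMSEs per model (training pairs, held-out
pairs, all 36 regime means) and flags rather than hides ordering
violations. The expected-accuracy ordering (hybrid best, quadratic
worst) is checked on the all-means column so all five models are
measured on the same evaluation set; comparing the hybrid's held-out
replicate-level RMSE against a polynomial's in-sample mean-level RMSE
would mix conventions differing by the replicate sampling noise itself.

Held-out hybrid RMSE lands at 0.05–0.09 per cultivar (median over
seeds). Its floor is not model error: a held-out replicate differs from
its cell mean by ± one printed SD under the reconstruction, and several
cells carry SDs of 10–25 percentage points, so even a perfect surface
would score ~0.04–0.06 on the held-out set.

## Synthetic ground truth

The synthetic surface is g_max·exp(−(T̄−μ_T)²/2σ_T²)·exp(−(Δ−μ_D)²/2σ_D²)
with T̄ the 16:8-hour weighted mean temperature (matching the
experimental photoperiod duty cycle), Δ the diurnal differential, and a
hard viability window [t_base, t_ceiling]. Defaults (g_max 0.85, μ_T
22 °C, σ_T 6 °C, μ_D 8 °C, σ_D 6 °C, window 5–37 °C) mimic the observed
cultivar profiles: grid optimum at 20/30 °C, constant regimes suppressed,
no germination at the hot corner. Assays are simulated as
Binomial(n_seeds, surface) per replicate with per-regime substreams, so
tables are reproducible regardless of evaluation order. The generator
emulates sampling noise only — no dormancy, no viability loss, no
between-replicate overdispersion — so recovery tests bound estimation
error under ideal counting statistics, not field behaviour.

The synthetic station network assigns each station a latitude-linear
annual mean (32 − 0.55·lat °C), a seasonal cosine peaking in July with
amplitude 2 + 0.45·lat, station noise (SD 1 °C), and a uniform 4–14 °C
diurnal range. It reproduces the gross structure a national network
shows (colder and more seasonal poleward, tmax ≥ tmin) and nothing else —
no elevation, no monsoon asymmetry, no coastlines.

## Suitability mapping

Monthly station climatologies of mean daily minimum and maximum
temperature are interpolated to a regular lon/lat grid by Cressman
successive correction: background = station mean; per pass with radius R
(defaults 1000, 700, 400, 200 km, great-circle distances), each cell is
corrected by Σwᵢeᵢ/Σwᵢ over stations with dᵢ < R, wᵢ = (R²−dᵢ²)/(R²+dᵢ²),
where eᵢ is the station's residual against the current analysis
(evaluated by bilinear interpolation, so a station on a grid node drives
that node to the station value exactly). Cells never inside any radius
keep the background and are flagged.

The fitted model is evaluated per cell with the monthly mean daily
minimum as T1 and maximum as T2. The source text mapping its three
temperature summaries onto the two model inputs is garbled; this
assignment is the one consistent with the assay's cool-16 h/warm-8 h
convention. Cells outside the 5–40 °C calibration envelope are clamped
to it and flagged as extrapolated; the extrapolated fraction is carried
in the map's provenance. Suitability is the raw predicted germination
fraction; any binning is presentation, not data.

## Reference-value reconciliation

Of the published values the pipeline is checked against:

* 18 of 20 profile-summary values match to one decimal; the two
  'Sapphire' misses are the source inconsistency described above.
* The quadratic baseline lands at 0.189–0.195 across cultivars against
  printed values of 0.21 (four cultivars, within the ±0.03 band) and
  0.23 ('Leopard', outside any band we can justify; no fitting or
  evaluation convention tried — mean-level, replicate-level,
  df-corrected — reaches 0.23 on any of the five table bodies). The
  'Leopard' check is left failing. Incidentally, the df-corrected
  residual SE (×√(36/30)) lands almost exactly on 0.21 for the four
  agreeing cultivars, suggesting that convention produced the published
  figures; the package still reports plain RMSE as defined.
* The hybrid's held-out RMSE satisfies the published ≤ 0.09 worst-case
  claim in median over seeds.

## Problem sizes

Default runs use the full experimental design throughout: 36 regimes ×
3 replicates per cultivar, populations of 50 for ≤ 200 generations, five
seeds for the stochastic claims, and a 1° mapping grid with 313
synthetic stations (the published network's size). The acceptance sweep
(5 cultivars × 5 seeds) completes in a few minutes on one core.

## Known limitations

* Replicate reconstruction fabricates a maximally symmetric triple; real
  replicate spread shapes are lost, and split-based results inherit that
  approximation.
* The GA searches architectures only through ±1 structural mutations;
  H bounds are fixed a priori.
* The Cressman analysis has no elevation term and treats months
  independently; it is an interpolator, not a climate model.
* Suitability maps on the synthetic network demonstrate the mechanism,
  not any real region's sowing calendar.
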