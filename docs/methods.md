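# Methods

## The model

`routesim` simulates the frequencies of the allelic lineages of one
immune-gene (HLA) locus in a spatially structured population, forward in
time, and uses Approximate Bayesian Computation (ABC) to compare three
colonization scenarios of East Asia and to estimate their parameters.

### Landscape

The study region is a rectangular stepping-stone lattice of square demes.
Each cell has a zone code: 0 (permanently uninhabitable; a western margin
stands in for the Himalayas/Tibetan plateau), 1 (northern area, NEA),
2 (southern area, SEA), 3 (the 29–33°N band — Qinling–Huaihe line /
Yangtze) and 4 (the 41–45°N band). The packaged default map is 24×18
demes spanning 18–55°N (row 0 northernmost); a half-resolution 12×9 map
with identical zone structure is packaged for desk-scale runs. The true
coastline is not digitized: the model's behavior is driven by the
latitude bands and the north/south split, not by coastline detail.
Neighborhood is von Neumann (4 orthogonal neighbors), matching the
classical stepping-stone model; an 8-neighbor option exists in
`landscape.neighbors`.

### Demography

Each deme holds `N` diploid individuals (`2N` gene copies). Per
generation, in order:

1. **Migration** — each deme emits `E = round(m_z · mult_z(g) · N)`
   individuals, divided as equally as possible among its habitable
   orthogonal neighbors. `m_z` is the zone's migration rate and
   `mult_z(g)` the barrier multiplier (below).
2. **Logistic regulation** — `N' = round(N + r N (1 − N/K))`, clamped to
   `[0, K]`, with zone-wise growth rate `r` and carrying capacity `K`.
3. **Balancing selection** — deterministic reweighting of the pooled
   lineage frequencies (below).
4. **Wright–Fisher resampling** — the next generation's `2N'` copies are
   drawn multinomially from the post-selection frequencies.

The within-generation order (migration → regulation → selection →
resampling) is a convention of this package. Founding demes start at
carrying capacity; founder effects during range expansion arise from the
small size of colonizing propagules. No mutation is simulated: all
variation descends from `A` ancestral lineages seeded at the origin
deme(s), mirroring the fact that HLA *lineages* (first-field allele
groups) are ancient and essentially not created on this time scale.

### Selection models

With `s` the balancing-selection coefficient and `p` the lineage
frequencies of a deme:

* **SOS** (symmetric overdominance): homozygotes have fitness `1−s`,
  heterozygotes 1; under random mating
  `p_i' = p_i (1 − s p_i) / (1 − s Σ p_j²)`.
* **LOS** (latitudinal overdominance): same update with `s` scaled by
  `2 (lat_max − lat) / (lat_max − lat_min)` — twice as strong at the
  southern map edge, zero at the northern edge, mean ≈ `s` over the map.
  The direction (stronger in the pathogen-rich south) is a package
  convention.
* **NFDS** (negative frequency dependence):
  `w_i = max(0, 1 − s (p_i − 1/k))` with `k` the number of segregating
  lineages, then `p_i' ∝ p_i w_i`. The functional form is a package
  convention chosen to be symmetric and neutral at the uniform point.

`s = 0` reduces all three to neutrality.

### Scenarios and barriers

* **Southern-origin** (one route): expansion from the southwestern-most
  habitable deme; zone 3 is a complete barrier until `t1`
  (0 < t1 < 2000); 2,500 generations.
* **Pincer** (two routes): expansions from the southwestern-most and
  northwestern-most demes, seeded from a common ancestral pool; zone 3
  closed until `t1` (0 < t1 < 2500); 2,500 generations.
* **Overlapping** (two routes): expansions from the southeastern-most and
  northeastern-most demes; zone 4 closed until `t1` (0 < t1 < 2500);
  zone 3 becomes a partial barrier (migration rate `0.1 m`) at `t2`
  (2500 < t2 < 3000); 3,000 generations.

A complete barrier (multiplier 0) blocks both settlement and
through-migration; a partial multiplier scales the emigration rate of the
zone's own cells. The admixture duration is `T = 2500 − t1` (Pincer) or
`T = t2 − t1` (Overlapping). Zone 1 uses the "NEA" parameter set, zone 2
"SEA"; the scenario's barrier zone(s) use the "barrier" set (zone 3 for
Southern/Pincer; zones 3 and 4 for Overlapping, with zone 4 the ancient
barrier). Under Southern/Pincer the 41–45°N band is ordinary northern
habitat. One generation is reported as 25 years.

### Priors (all uniform)

| parameter | meaning | prior |
|---|---|---|
| `A` | ancestral lineages | 10 – 50 |
| `s` | balancing selection | 0 – 0.025 |
| `N` (×3 zones) | deme carrying capacity | 0 – 5,000 |
| `m` (×3 zones) | emigration rate / generation | 0.01 – 0.20 |
| `r` (×3 zones) | logistic growth rate | 0.01 – 0.20 |
| `t1` | barrier release | scenario-dependent (above) |
| `t2` | partial-barrier onset (Overlapping) | 2,500 – 3,000 |

Draws whose simulation leaves a sampled deme empty (no colonization,
typically `m·N < 1`) cannot produce data and are discarded and redrawn;
the reference table is thus implicitly conditioned on colonization of the
sampling sites, identically for all scenarios.

## Summary statistics

Nineteen populations are sampled at the end of a run (`2n` gene copies
drawn with replacement from the deme's final frequencies — real sample
sizes can exceed the deme census). Twelve statistics summarise them:
mean/SD of the lineage count, mean/SD of Nei's unbiased gene diversity
`H = n/(n−1) (1 − Σ p̂²)` overall and separately for NEA and SEA, the
Pearson correlation of `H` with latitude, and the three F-statistics of a
hierarchical allele-identity AMOVA with the NEA/SEA grouping
(`F_CT` among groups, `F_SC` among populations within groups, `F_ST`
overall; negative variance components floored at zero, so
`1−F_ST = (1−F_CT)(1−F_SC)` holds exactly). Optionally the absolute
Pearson correlation between the first principal coordinate (classical
metric scaling of the pairwise two-population AMOVA `F_ST` matrix) and
latitude is appended. The bias correction of `H` and the use of pairwise
`F_ST` as the PCoA distance are package conventions.

## ABC

Statistics are standardized by their pooled reference-table SD (zero-SD
statistics dropped), distances are Euclidean. Model choice retains the
`δ` closest records (ceil, ties by record index) and reports per-model
proportions; δ defaults to {0.25%, 0.5%, 1%}. Bayes factors are ratios of
model marginal densities at the observed statistics. Parameter estimation
uses the ABC-GLM adjustment: OLS fit of (optionally PLS-projected)
statistics on parameters over the retained set, Gaussian residual
covariance (with a tiny diagonal jitter for rank-deficient cases), and a
1,000-point posterior grid per parameter with the remaining parameters
integrated by Monte Carlo over the retained draws; the marginal density
`fM(obs)` is the mean retained likelihood of the observation, and the fit
p-value is the fraction of retained records whose own marginal density is
at most `fM(obs)`. PLS uses NIPALS components on standardized statistics
(no Box–Cox transform), with RMSEP per component count from 10-fold
cross-validation. Calibration is checked by posterior quantiles of
pseudo-observations (default 100) against Uniform(0,1) with a
Kolmogorov–Smirnov test. Because the marginal-density estimator is a
package convention, absolute densities are not comparable across
implementations — only their ratios (Bayes factors) on the same reference
table are.

The derived quantities `T`, `N·m` (NEA) and `N·m` (SEA) are carried as
extra columns of every reference table, so posteriors can be estimated
for them directly (the GLM does not require an invertible
parametrization).

## Numerical and performance choices

* Gene copies are integers throughout; rounding is half-up; copy counts
  are conserved exactly through migration.
* Emigrant copies are drawn from the source deme by a capped conditional
  binomial chain (effectively without replacement, so counts stay
  non-negative). For flows above 64 copies the expected composition with
  randomized-remainder rounding is used instead — the sampling noise of a
  draw that size is negligible next to the Wright–Fisher resampling that
  follows. Small flows (colonizing propagules), whose noise drives serial
  founder effects, are always drawn exactly, with each copy assigned to a
  random neighbor quota slot.
* The per-neighbor split of emigrants is as equal as possible, with a
  parity repair so every neighbor receives whole diploid immigrants.
* The Wright–Fisher multinomial uses a conditional binomial chain; when a
  draw's conditional variance exceeds 30 (sd > 5.5 copies) a
  moment-matched Gaussian draw (inverse-CDF, error < 1.2e-9) replaces the
  binomial. Lineage loss and low-count dynamics always use exact
  binomials. The neutral calibration test verifies mean gene diversity
  decays as `H0 (1 − 1/2N)^t` within Monte-Carlo error.
* Kernels are numba-compiled with on-disk caching; each simulation is
  seeded from a master `SeedSequence`, so runs are reproducible.

## Problem sizes

Full-scale reproduction (100,000 simulations per scenario on the real
East Asia map) is cluster-scale. The packaged desk-scale study uses the
24×18 default map with 200 Southern-origin simulations for the
diversity-gradient fraction and 100 simulations per scenario for the
pooled model-choice table (`scripts/acceptance.py`); the test suite
shares a pooled default-map table of 80 simulations per scenario and an
Overlapping-scenario table of 300 simulations on the 12×9 map for
posterior-estimation checks. GLM estimation at desk scale retains
15–30% of a single-model table (the published 0.25–1% retentions assume
100,000-record tables; a GLM needs tens of retained records to be
identifiable), and qualitative parameter estimation follows the
published procedure of a GLM on 6 PLS components, with `t2` re-expressed
as the admixture duration `T` so the parameter basis is non-collinear.

## What the synthetic panel does and does not emulate

The packaged 19-population panel reproduces the real panel's summary
structure — latitudes spread over ~18–53°N on both sides of the two
barrier bands, NEA/SEA split at the 29–33°N band, sample sizes 52–9,678
with mean 2,662 — but its coordinates and sizes are synthetic stand-ins:
the real panel's per-population data are not packaged. The published
12-statistic vectors for HLA−A, −B and −DRB1 are the authoritative
observed inputs of every ABC comparison. Consequently, passing tests
show that the *method* behaves correctly on data of realistic shape, not
that the synthetic panel reproduces per-population observations.

## Known limitations

* **Lattice scale.** The fraction of Southern-origin simulations with a
  negative diversity–latitude correlation grows with lattice size
  (~0.55–0.67 on the 12×9 map, ~0.84–0.89 on the 24×18 map in our runs):
  serial founder effects strengthen, and reversal of the gradient by
  fast regional drift in a small southern region weakens, as the deme
  count grows. The published >95% refers to the full-resolution East
  Asia lattice and is not reached at desk scale.
* **Model separation at desk scale.** For the same reason, desk-scale
  Southern-origin draws with a small southern carrying capacity can
  mimic the observed north-rich diversity pattern and enter the retained
  set for HLA−A and −DRB1; the published ≥96%/<4% two-route/one-route
  split requires the full-scale lattice, where Southern draws
  essentially never yield a positive diversity–latitude correlation.
* With few retained records (desk-scale tables at δ=0.5%), model-choice
  proportions are coarse (steps of 1/retained), and the selection
  coefficient is only weakly identified (posteriors lean on the prior;
  orderings between loci are noisy).
* Allele-level (second-field) evolution, new-variant generation,
  sea-level change, and real coastline geometry are out of scope.
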