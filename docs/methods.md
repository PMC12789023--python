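# Methods

## The partition

For two community samples of the same plot — a *baseline* and a *comparison* —
let each detected species `i` contribute `z_i >= 0` mg to the community
function (total dry biomass by default).  With `s`, `s'` the two species
richnesses, `s_c` the shared richness, `T = sum z_i`, `T' = sum z'_i` the
totals and `z̄ = T/s`, `z̄' = T'/s'` the community means, the change
`ΔT = T' − T` decomposes additively into

| component | formula | meaning |
|---|---|---|
| richness loss  | `−(s − s_c)·z̄`        | expected loss if lost species were average |
| identity loss  | `Σ_C z_i − s_c·z̄`      | deviation of actually-lost species from average |
| richness gain  | `(s' − s_c)·z̄'`        | expected gain if gained species were average |
| identity gain  | `s_c·z̄' − Σ_C z'_i`    | deviation of actually-gained species from average |
| persisting (CDE) | `Σ_C (z'_i − z_i)`   | function change of shared species |

(`C` is the shared species set.)  The five terms sum to `ΔT` exactly; the
implementation keeps this identity to < 1e−9 relative error and is verified
against an independent brute-force reference that recomputes every term from
explicit lost/shared/gained set loops.

Because each species carries a constant literature-style body length, the
persisting-species term isolates abundance change.  A second mode replaces
`z_i = n_i·m_i` by `z_i = m_i` (mean individual biomass), removing abundance
effects entirely; in that mode the persisting term is identically zero.

Empty samples use the convention `z̄ = 0`, which loads all change on the
non-empty side's terms and keeps the sum identity exact; an empty-vs-empty
pair is an all-zero partition.

## Comparison design

Samples are pooled over seasons per (plot, year, replicate).  Temporal pairs
join equal replicate labels within a plot under three schemes: fixed baseline
(first sampled year vs all later years), moving average (all ordered year
pairs, pooled by span), and the default restricted moving average (baselines
limited to the first five sampled years of the design).  For the
moving-average schemes a span is retained only if at least two distinct
(baseline year, comparison year) combinations represent it; this is what
caps the retained span at 7 years for the gappy 2010–2020 sampling calendar
and at 9 years for an annual 2008–2018 calendar.  The fixed-baseline scheme
keeps all spans (each occurs once by construction).  Controls — replicate A
vs B of one plot and year, span 0 — quantify the species turnover and
biomass change expected from detection noise alone and anchor the models at
span 0.

Every sample takes part in many pairs, so fitting all pairs at once would
pseudoreplicate.  Model subsets are drawn so that no (plot, year) sampling
event enters twice: per plot, a maximum-cardinality matching of the temporal
pair graph is drawn by shuffled greedy acceptance (restarted until the
matching size, computed once per plot with networkx, is reached), and every
event not consumed by a temporal pair contributes its control in one random
direction.  The temporal subset size is therefore a design invariant.  Where
the design mixes controls and temporal pairs the sampler maximizes temporal
pairs first — the design choice we adopted for the ambiguous mixed case.

Covariates are the plot's sown plant species richness (PSR, experiment
designs) or land-use intensity (LUI, real-world designs).  LUI is smoothed as
the mean of the sampling year and the two preceding years (window truncated
at the series start) and averaged over the two endpoint years of each pair.
The covariate is z-scored once on the full pair table so conditional slopes
are comparable across resampled fits.

## Trend models and ensemble inference

Each of the nine responses (five components, total change, species lost,
gained, net richness change) is transformed by the signed square root
`f(y) = sign(y)·sqrt(|y|)` — responses are symmetric around zero with a few
extreme values — and modelled per subset as

    f(y) ~ 1 + span + covariate_z + span:covariate_z

with crossed random intercepts for plot, baseline year and comparison year
(REML).  For the fixed-baseline scheme, where contributing years are unique
within a subset, the same fixed effects are fitted by OLS.  The mixed-model
backend is a dedicated profiled-REML solver for this crossed-intercept
structure: the fixed effects and residual variance are profiled out and the
variance-ratio vector is optimised on the log scale (Powell), with the
Woodbury identity keeping each objective evaluation O(q³) in the number of
random-effect levels.  It reproduces lme4 fixed effects to ~1e−7 on test
fixtures (a live cross-check against lme4 via Rscript is part of the suite)
and reports boundary fits as exact zero variance components rather than
failing.  Rank-deficient subsets (possible in tiny designs where all span
variation collapses into one plot) raise a fit error and are redrawn; more
than 5% redraws aborts the ensemble.

An ensemble of `n_models` subsets (1000 in the emulated studies; smaller in
tests, see below) yields per-model coefficients, conditional time slopes
`β_span + β_interaction·z(x)` at chosen covariate levels (defaults PSR 1/60,
LUI 0.5/3.5), and predictions on a (span × covariate level) grid
back-transformed by `f⁻¹(u) = sign(u)·u²`.  Summaries are medians and
2.5/97.5 percentiles; the empirical two-sided P is twice the minority-side
share of the estimates (exact zeros split evenly between sides, so P stays
symmetric and ≤ 1), with resolution floor 2/n reported alongside.  Medians
commute with the monotone back-transform, so summarizing after
back-transformation equals back-transforming the summaries — a property the
suite asserts.

Component contributions at a horizon `h` divide, per model, each grouping's
combined back-transformed prediction (richness = both richness terms,
identity = both identity terms, turnover = all four, CDE) by the predicted
total change; medians and percentile CIs are taken across models.  Shares
may exceed 100% or be negative when components oppose the total.  Because
each response is back-transformed separately, grouped component predictions
need not sum exactly to the predicted total: predictions of mixed-sign
responses (the total) attenuate more under the signed-sqrt transform than
single-signed components, an intrinsic property of this transform-ensemble
procedure that grows with detection noise.  Percentage decline divides the
predicted loss at the last span by the mean community function over the
baseline-window samples; annualization is linear (total/h) by default, with
a geometric option.

Variance inflation factors of (span, covariate_z, interaction) are computed
on the full pair table and reported; VIF ≥ 2 is flagged.  Note that with
span ≥ 0 the interaction column is inevitably correlated with the covariate
column, so the flag commonly fires for the interaction even in clean designs.

## Synthetic communities

The generator emulates the two study designs: 80 plots allocated
14/16/16/16/14/4 over PSR levels {1,2,4,8,16,60} with sampling years
2010–2020 minus {2011, 2013, 2015, 2018}, or 150 plots with per-year LUI in
[0.5, 3.5], sampled annually 2008–2018; two seasons and two replicates per
plot throughout.

Key defaults and their rationale:

* `n_species = 300` regional pool; log-normal relative abundances
  (`σ = 1.3`) and log-normal body lengths (median 4 mm, `σ_log = 0.6`) with
  correlation −0.4 between log abundance and log length: rare species tend
  to be large-bodied, the premise behind identity effects.
* local pool inclusion rises from 30% to 65% of the regional pool across the
  covariate gradient (richer/less intensive plots hold more species).
* `richness_decline = 0.06`/yr baseline local extinction hazard, weighted by
  rarity rank (`rarity_exponent = 1`, rarest species most at risk) and mildly
  by body size (`size_bias = 0.25`); the covariate modulates the hazard
  (higher PSR protects, higher LUI accelerates, `covariate_effect = 0.5`).
* `abundance_decline = 0.02`/yr intensity decay of persisting species.
* detection: counts per plot × season × replicate are Poisson in
  `effort × intensity` with `effort = 1.0`, giving on the order of 100
  individuals per replicate and year — chosen to match the sampling
  intensity of the emulated programmes (hundreds of thousands of individuals
  over ~2000 replicate-year units).

The generator writes the latent truth (which species were really present,
with what intensity) to a side table, so tests can separate real extinctions
from detection failures — something field data cannot.  What the generator
does *not* emulate: climate forcing, spatial autocorrelation between plots,
within-season phenology, observer effects, and abundance-dependent body
size.  Passing recovery tests therefore demonstrates that the pipeline
recovers known decline structure under realistic detection noise, not that
any particular field system behaves this way.

`expected_components` is a Monte-Carlo oracle: it simulates independent
(baseline, baseline + h) plot trajectories, partitions each pair, and
averages — giving the expected components and component shares under a
configuration, with bootstrap standard errors for the shares.  Under a
stationary configuration the expected total change and persisting-species
term are zero and the loss terms mirror the gain terms; the individual
loss/gain expectations remain nonzero at any finite effort because rare
species blink in and out of detection.

## Problem sizes in the test suite

The resampling checks run at reduced size so the full suite stays
lightweight on one CPU: parameter-recovery runs use 24 plots, a 100-species
pool and 120-model ensembles over 20 replicate datasets per configuration
(coverage of the oracle share asserted at ≥ 18/20, i.e. the 90% proportion
kept from the full-size protocol); null calibration uses 10 plots, 5 sampled
years and 60-model ensembles over 50 replicate datasets (≤ 15% rejections at
0.05).  Percentile-CI width grows with ensemble size, so small ensembles
understate tail width; 120 models was chosen as the point where CI width is
close to the 1000-model regime while keeping the suite fast.
`scripts/acceptance.py` runs both emulated designs at full plot counts with
150-model ensembles.

## Numerical choices

* Variance ratios below 1e−7 are reported as exact zeros (boundary fits).
* The Poisson split truncates draws above the sample size N (preserving
  feasibility of sampling without replacement); the bootstrap replicate's
  draw size is Poisson with mean N by default (configurable to N/2).
* Occupancy filtering uses a ceiling plot-count cutoff (10% of 80 plots → at
  least 8 plots) per year, replicates and seasons pooled.
* Sample coverage defaults to the frequency-count estimator
  `1 − (f1/n)·(n−1)f1/((n−1)f1 + 2f2)`, falling back to Good–Turing
  `1 − f1/n` when there are no doubletons; the estimator used is recorded
  per sample.
* Duplicate (event, species) observation rows are summed with a logged
  warning; inconsistent per-species attributes are an error, never
  first-row-wins.

## Known limitations

* Species losses and gains are detection events; at field sample sizes they
  cannot be equated with true extinction or immigration.  The generator's
  truth table makes the distinction available for testing only.
* The identity components aggregate away species identities; no trait-level
  attribution is attempted.
* The ensemble CI reflects subset-resampling variability around one
  dataset's estimate, not between-dataset sampling variability.
* Between-plot (spatial) partitions and model selection are out of scope.
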