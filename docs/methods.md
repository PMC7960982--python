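# Methods

This note documents the models and numerical choices behind
`aquathreat`: what each stage computes, which parameters matter, what
the synthetic world does and does not emulate, and where the design was
genuinely open.

## Extreme indicators

Each cell-scenario pair is summarised by five long-term indicators
computed from weekly series of N years × M weeks (defaults 30 × 52):
the mean over years of the yearly minimum and maximum weekly flow
(`q_min`, `q_max`, m³/s), of the yearly count of zero-flow weeks
(`q_zf`, weeks/yr), and of the yearly minimum and maximum weekly water
temperature (`t_min`, `t_max`, °C). Years are exactly M model weeks;
no calendar handling (aggregation over model-native weeks adds nothing
the indicators can detect). A week is zero-flow when its flow is
≤ `zero_flow_tolerance` (default 0; a small positive tolerance is
exposed because routed flows from numerical models rarely reach exactly
zero). Non-finite values are rejected outright, naming the offending
cell/year/week — silent gap-filling would bias extremes toward the
fill. Incomplete trailing weeks would be dropped, never padded.

## Species thresholds

A species' tolerance window is the empirical 2.5th percentile of
within-range `q_min` and `t_min`, the 97.5th percentile of `t_max` and
`q_zf`, and the plain within-range maximum of `q_max` (its within-range
distribution is strongly right-skewed, so a percentile would discard
the main stem of large rivers from the window).

Percentile convention. The default is the **outer order statistic**:
the high threshold is the smallest within-range value with at most 2.5%
of the range strictly above it (mirror-image for the low threshold).
This makes the property the percentiles exist for — at most 2.5% of the
range sits beyond its threshold at baseline — hold *exactly for every
range size*. Interpolated percentiles do not have this property: two
of fifty distinct values lie strictly above their interpolated (type 7)
97.5th percentile, i.e. 4% of the range. Type-7 linear interpolation
remains available as `method="linear"` for compatibility with R/numpy
defaults. In the pipeline the quantiles are weighted by cell area
(`area_weighted_thresholds=True`), so the 2.5% margin is guaranteed in
km² — the unit in which exposure is measured; on equal-area grids this
reduces to plain cell counting. Single-cell ranges collapse all
thresholds to that cell's values.

## Exposure and variable groups

Exceedance is strict: a projected indicator equal to its threshold is
within current experience, not beyond it (ties are measure-zero for
continuous model output; the convention only matters for constructed
inputs). Flags are grouped as flow = q_min ∨ q_max ∨ q_zf,
temperature = t_min ∨ t_max, any = flow ∨ temperature, and
both = flow ∧ temperature evaluated cell-wise (the same cell must be
beyond both a flow and a temperature threshold). RT is area-weighted:
RT = 100·AT/A in km².

## Dispersal

Sub-basin units are the edge-connected components of cells sharing a
(basin, ecoregion) pair. Units below `min_unit_area` (default
1,000 km²) are merged smallest-first into the edge-adjacent neighbour
sharing the longest boundary; ties go to the larger, then the
lower-numbered unit; units with no neighbour stay as they are.
Corner contact does not count as adjacency. Under maximal dispersal a
species may additionally occupy any cell of every unit containing at
least one range cell, provided the cell's *baseline* indicators violate
none of the five thresholds (same strict convention). The metric
becomes RT = 100·AT/(A + (AE − AET)): the numerator counts threatened
area within the original range only, while habitable expansion area
grows the denominator and threatened expansion area (AET) is discounted
from it — the algebra implies AE = 0 and AET = AE both reduce exactly
to the no-dispersal metric, and RT(maximal) ≤ RT(no dispersal) always.

## Aggregation

The headline summary is the share of species with RT(any) strictly
above 50%, with mean and sample SD (ddof = 1, configurable) across the
ensemble members of each warming level; a single-member ensemble
reports SD 0 with a warning. PAF per cell is the median across members
of the fraction of the cell's species pool (current ranges, or expanded
ranges under maximal dispersal) whose thresholds are exceeded *in that
cell*; the within-cell reading is chosen because the map describes
local threat. Even member counts take the midpoint of the two middle
values. Cells with an empty pool are no-data (NaN), never 0.
Watershed summaries are unweighted means of PAF over each basin's data
cells.

## Phylogenetic regression

Threat level is log-transformed as log10(RT% + s) with offset s = 0.01
so wholly unthreatened species (RT = 0) remain in the fit; s is a
configuration value reported in output metadata. Range size and body
length enter as log10; categorical covariates use treatment contrasts
with the most frequent level as reference. The residual covariance is
V(λ) = λ(C − diag C) + diag C, where C is the shared-branch-length
matrix of the tree (root edge excluded, the convention of ape/nlme).
λ is estimated by profile maximum likelihood with bounded scalar
minimisation on [0, 1] (xatol 1e-6); both endpoints are evaluated
explicitly and reported when they beat the interior optimum.
Coefficient standard errors use the unbiased residual variance
(n − p denominator) with t tests on n − p degrees of freedom, matching
generalized-least-squares conventions; the implementation agrees with
R's `nlme::gls` + `ape::corPagel` to ~1e-3 on shared fixtures (a test
runs that comparison). A Spearman (≥ 0.4) and VIF (≥ 1.5) screen warns
about collinear covariates but never blocks the fit; rank-deficient
designs are rejected naming the aliased columns.

Permutation importance shuffles one covariate at a time, rebuilds the
design with the *fixed* reference encoding, recomputes predictions with
the fitted coefficients (no refit — the score isolates the prediction
pathway, and refitting would conflate importance with estimability),
and reports 1 − Pearson r(original, permuted predictions), averaged
over iterations; with several tree-replicate fits the mean and SD
across replicates are reported. Constant prediction vectors yield
importance 0 with a warning.

## Synthetic world

The generator emulates the *structure* of the real inputs, not their
physics or geography:

- **Grid** — a rectangular lattice; cell area A₀·cos(latitude proxy)
  with A₀ = 100 km² and latitudes spanning ±60°, exercising area
  weighting. Basins are connected components grown by seeded
  multi-source flood fill; ecoregions are contiguous row bands crossing
  several basins, so their intersection yields non-trivial sub-basin
  units.
- **Weekly series** — temperature: a row-dependent mean (default
  meridional span 25 °C, the order of real surface-water gradients
  between the tropics and 60°) plus a seasonal sinusoid (amplitude
  8 °C) plus per-cell AR(1) interannual anomalies (coefficient 0.3,
  innovation SD 0.5 °C). Flow: a sinusoid around 20 m³/s (amplitude
  15) sharing the anomaly, clipped at zero, with weeks zeroed at rate
  `zero_flow_prob` (default 1%). Weather noise is drawn once per world
  and shared by all scenarios, so members differ exactly by their
  forcing fields.
- **Scenarios** — warming levels 1.5/2.0/3.2/4.5 °C, 3 members per
  level (standing in for GCM–RCP combinations). Each member draws one
  multiplicative jitter field (1 + N(0, 0.15), floored at 0) shared
  across levels; its delta is level × field, making every member's
  family cell-wise nested in warming — the property the monotonicity
  results rest on. A fixed 20% of cells are drought-prone: their
  low-season flow is scaled by 1 − 0.12 × warming (floored at 0.05).
- **Ranges** — connected patches grown by random accretion within one
  basin; sizes lognormal with median ~15 cells. Requests exceeding the
  basin are truncated with a logged warning.
- **Traits and tree** — a pure-birth tree (depth normalised to 1;
  terminal edges extended by 1e-3 before rescaling so every branch is
  strictly positive even when the simulation stops at a speciation
  event), covariates drawn from fixed distributions, and a response
  X β + ε with ε ~ N(0, σ²V(λ)) for planted β and λ.
- **Planted threats** — `plant_exact_threat` selects a subset of range
  cells whose area fraction equals the target RT and raises their
  temperature above the species' `t_max` threshold. Exactness requires
  an exceedance-free baseline (noise-free, spatially uniform
  temperature within the range); the function verifies this and rejects
  otherwise, and rejects targets not expressible as a cell-subset area
  fraction, listing the achievable ones.

What the generator does **not** emulate: flow routing and river-network
topology, reservoirs and water use, thermal stratification and ice,
real geographic projections and geodesic areas, spatially realistic
climate-change patterns, and empirical trait covariances. Passing
tests therefore demonstrate that the *computational pipeline* is
correct and behaves as the method's algebra demands (oracle agreement,
planted-truth recovery, monotonicity, bounds), not that its outputs
match any real-world assessment.

## Problem sizes

Default study conditions: 26×26 grid, 6 basins × 4 ecoregions, 80
species, 30 years × 52 weeks, 3 members at each of four warming
levels (13 scenario runs), both dispersal modes, and one regression
per dispersal mode at 3.2 °C. The acceptance script runs these
defaults plus a 20-species planted-threat experiment and a 15-replicate
λ-recovery experiment at 150 tips; the regression-recovery test uses
200-tip trees with 50 replicates per λ ∈ {0, 0.5, 0.9}. All
experiments fix their seeds and reproduce bit-identically.

## Known limitations

- Rasterization overlap fractions are computed in planar grid
  coordinates; geodesic polygon support is out of scope.
- The sub-basin merge rule (longest shared boundary) is one of several
  defensible choices; partitions differing in tie handling would shift
  unit boundaries but not the algebraic guarantees.
- λ estimates at the true boundary (0 or 1) are reported as boundary
  values; no profile-likelihood confidence interval is computed.
- The synthetic response used by the pipeline's regression stage is the
  computed mean RT, whose distribution depends on the synthetic world's
  geometry; planted-coefficient recovery is only meaningful through
  `generate_traits_and_tree`, which plants the signal directly.
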