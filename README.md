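# aquathreat

Climate-extreme exposure assessment for riverine fish.

Freshwater fish live inside a hydro-thermal envelope set by the rivers
they occupy: how warm and how cold the water gets in the most extreme
week of the year, how low and how high the flow drops or swells, and
how often the channel falls dry. Climate change shifts those extremes.
`aquathreat` is a library for asking, species by species and cell by
cell on a gridded river network: *where do projected weekly extremes
leave the envelope a species experiences today, how much of each range
is exposed, and which kinds of species are exposed most?*

It is written for macroecologists and climate-impact modellers who have
(or want to emulate) gridded weekly streamflow and water-temperature
series, species range maps, a trait table and a phylogeny. A fully
synthetic world generator with planted ground truth ships with the
package, so every stage runs and is tested end to end without any
external data.

## The method

For each grid cell and scenario, five indicators are computed from the
weekly series over an N-year window (N = 30 by default):

    Q_min = (1/N) Σᵢ min(Q7ᵢ)       Q_max = (1/N) Σᵢ max(Q7ᵢ)
    Q_zf  = (1/N) Σᵢ #{j : q7ⱼ = 0}
    T_min = (1/N) Σᵢ min(T7ᵢ)       T_max = (1/N) Σᵢ max(T7ᵢ)

where Q7ᵢ, T7ᵢ are the weekly flow and temperature vectors of year *i*.
A species' tolerance window comes from the spatial distribution of the
baseline indicators across its range: outer 2.5%/97.5% quantiles for
Q_min, T_min, T_max and Q_zf (damping outlier cells), and the plain
within-range maximum for Q_max. A cell is threatened under a future
scenario when an indicator strictly exceeds the window, and the
percentage of range threatened for species *x*, scenario *c*, variable
group *v* is

    RT_{x,c,v} = AT_{x,c,v} / A_x · 100            (no dispersal)
    RT_{x,c,v} = AT / (A + (AE − AET)) · 100       (maximal dispersal)

with AT the threatened range area, A the range area, AE the habitable
area added by letting the species reach any suitable cell of the
sub-basin units (basin × ecoregion components) its range touches, and
AET the threatened part of that expansion. Per-cell threat is
summarised as the potentially affected fraction

    PAF_{i,w} = median_c ( 1 − S_{i,w} / S_{i,present} )

the median over the ensemble members *c* of warming level *w* of the
share of cell *i*'s species pool whose window is exceeded there, then
averaged over watersheds. Finally, log threat level is regressed on
species traits (range size, body length, climate zone, trophic group,
habitat, IUCN category, commercial importance) by phylogenetic GLS with
Pagel's λ estimated by maximum likelihood, and covariate relevance is
scored by permutation importance (1 − Pearson's r between original and
permuted-covariate predictions).

## Worked example

`examples/` holds one short script per capability. The full pipeline
(`examples/04_full_pipeline_and_paf_maps.py`) on a 20×20-cell world
with 50 species, 15 years of weekly data and 3 ensemble members per
warming level prints:

```
36 species retained (14 excluded: lentic or <10 cells)

share of species with more than half their range threatened:
  1.5 degC, none     dispersal:  22.2% +/- 2.8%
  2.0 degC, none     dispersal:  37.0% +/- 1.6%
  3.2 degC, none     dispersal:  83.3% +/- 2.8%
  4.5 degC, none     dispersal:  99.1% +/- 1.6%
  1.5 degC, maximal  dispersal:  11.1% +/- 0.0%
  2.0 degC, maximal  dispersal:  15.7% +/- 1.6%
  3.2 degC, maximal  dispersal:  38.9% +/- 2.8%
  4.5 degC, maximal  dispersal:  74.1% +/- 4.2%
```

Threat rises monotonically with warming, and allowing dispersal into
suitable neighbouring sub-basin cells lowers it at every level — the
two qualitative signatures the pipeline is built to expose. The ±
figures are standard deviations across ensemble members.

The regression example (`examples/05_phylogenetic_regression.py`)
plants β(range size) = −0.6, β(body length) = +0.4, λ = 0.6 in a
200-species world and recovers:

```
Pagel's lambda: planted 0.60, estimated 0.71
  log10_range_km2              -0.60 -> -0.62 +/- 0.02
  log10_body_length_cm         +0.40 -> +0.36 +/- 0.06
permutation importance: log10_range_km2 0.909, log10_body_length_cm 0.061
```

A command-line wrapper is available for end-to-end runs:
`aquathreat run --config run.yaml --seed 1 --out DIR` (every stage
writes plain CSV plus a manifest of seeds and file checksums).

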