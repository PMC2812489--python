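# mosaicpop

Spatially explicit simulation of how landscape simplification affects the
long-term dynamics of animal populations in agricultural patch mosaics.

Wildlife managers need to know how the *configuration* (arrangement of
habitat patches, presence of corridors) and *composition* (relative cover
of patch types) of a landscape affect population persistence, but
landscape-scale experiments on real populations are impossible.
`mosaicpop` runs the experiment *in silico*: it generates a realistic
raster patch mosaic, progressively strips it of structure, and measures
how populations with contrasting life histories respond, summarising each
response by two classical quantities — the equilibrium population size
*K* and the return time *φ* after a disturbance.

The pipeline has four stages:

1. **Synthetic landscape** — a grid of typed habitat patches (rotational
   fields, field boundaries, hedgerows, grassland, roadside verges,
   forest) grown around immovable barriers (roads, rivers, buildings,
   lakes), with a right-skewed patch-size distribution spanning two
   orders of magnitude and thin field-margin corridors hugging the arable
   fields.
2. **Complexity reduction** — three transforms yield variants B, C, D
   from the reference mosaic A: *shape homogenization* (patches re-grown
   compactly in place, removing corridors while conserving identity, type
   and area), *arrangement randomization* (type labels permuted among
   patches of the same quarter-decade size class, scrambling
   configuration while conserving composition), and *size randomization*
   (labels permuted regardless of size, changing composition).  Barrier
   cells are bit-identical across all variants.
3. **Individual-based population models** — four archetypes on an annual
   breed → disperse → overwinter cycle with emergent logistic density
   dependence and a 10-year cyclic weather sequence: a ground **beetle**
   (fast-reproducing, short-dispersing, blocked by barriers, overwinters
   only near field boundaries/hedgerows — landscape complementation), a
   field **vole** (grassland specialist, short-dispersing, elevated
   mortality in the arable matrix), a **skylark** (slow-reproducing
   far-disperser breeding in open fields, avoids nesting near trees), and
   a linyphiid **spider** (fast-reproducing ballooner: landscape-scale
   dispersal with high mortality).
4. **Perturbation–recovery analysis** — 181-year runs (11-year burn-in,
   removal of 80% or 95% of all individuals every 17th year, yearly
   censuses) give ten 17-year recovery windows per run.  Log abundance is
   fitted with the logistic

   ln *N*(*t*) = ln *K* / (1 + e^((*m* − *t*)/*φ*)),

   where *m* is the inflection time (abundance passes √*K*) and *φ* is
   the shape parameter — the e-folding time of the log-scale deviation
   from equilibrium, i.e. the reciprocal of the return rate.  Weather
   years enter as a random grouping factor on the asymptote; a
   four-parameter form with a lower asymptote serves species whose growth
   rate first accelerates (skylark).  Unperturbed runs get an
   intercept-only per-weather-year equilibrium fit.

The full factorial — 4 species × 3 perturbation intensities × 4 landscape
variants = 48 fitted models — is orchestrated by `run_pipeline`, and the
cross-cutting analyses (the K–φ correlation per species, variant deltas,
detection of incomplete recovery under repeated perturbation) live in
`mosaicpop.analysis`.

## Worked example

```bash
python examples/recovery_experiment.py
```

simulates a beetle population through the standard protocol on a
120×120-cell mosaic and fits the recovery model:

```
simulated 181 years; analyzed window: 170 years, 10 perturbations
10 recovery segments of 17 years each

fit converged: True
K   =     8179  (95% CI 7262–9013) — equilibrium population size
phi =     1.83  (95% CI 1.74–1.92) — return time in years
m   =    -0.88  — inflection: abundance passes sqrt(K) at this t
among-weather-year asymptote SD sigma_b = 0.152, residual SD sigma_e = 0.104
```

so this population equilibrates near 8 200 individuals and closes an
e-fold of its log-scale deficit in under two years; the weather cycle
moves the yearly asymptote by about ±15%.  The other scripts in
`examples/` walk through landscape generation, the variant transforms,
fit calibration on synthetic data, and a small end-to-end pipeline; a
thin CLI (`mosaicpop generate|modify|pipeline`) wraps the same calls for
shell use.

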