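# memscale

Multi-scale spatial eigenfunction analysis of community abundance data:
Moran's Eigenvector Maps (MEMs) on a Gabriel graph, Hellinger / chi-square
community transformations, PCA / RDA / partial-residual ordination,
smoothed scalograms with an R²max permutation test, two-stop forward
selection, and adjusted-R² variation partitioning.

## The problem

Regional surveys of an invasive insect (here modelled on the brown
marmorated stink bug *Halyomorpha halys* spreading through mid-Atlantic
soybean fields, alongside the native stink bugs *Chinavia hilaris* and
*Euschistus servus*) ask: **at which spatial scales is abundance
structured, and which environmental drivers — temperature, land use,
distance from the original source population — act at those scales?**

`memscale` answers this with the spatial-eigenfunction toolkit used in
community ecology:

- **Spatial template.** Sites become nodes of a *Gabriel graph* (edge
  *ij* kept iff no third site falls in the open disk with diameter *ij*).
  The binary adjacency **W** is doubly centered, Ω = **HWH** with
  **H** = **I** − **11**′/n, and its eigenvectors **v**₁…**v**ₙ₋₁ are the
  MEMs: an orthonormal basis of spatial patterns ordered from very broad
  (large positive eigenvalue, positive Moran's *I*; I(**v**ₖ) = nλₖ/ΣW)
  to very fine (negative *I*). A connected graph over n sites yields
  exactly n − 1 MEMs (328 for a 329-field survey).
- **Community structure.** The site × species count table **Y** is
  transformed (Hellinger to emphasize the abundant invasive, chi-square
  to emphasize the rarer natives), then ordinated: PCA for the overall
  pattern, RDA (PCA of the fitted values of **Y** ~ **X**) for the
  environmentally explained pattern, PRA (PCA of the residuals) for what
  remains.
- **Scalograms.** Each axis's site scores **s** are projected on the
  MEMs: R²ₖ = (**v**ₖ′**s**)²/(**s**′**s**), summing to 1. Consecutive
  blocks (8 components × 41 MEMs at n = 329) smooth the profile, and the
  largest smoothed component R²max is tested by permuting the scores
  across sites.
- **Inference.** Forward selection with the double stopping criterion
  (candidate admitted at permutation p ≤ α; selection halts once the
  subset's adjusted R² exceeds the global model's; nothing is selected
  unless the global test passes) picks environmental variables and MEMs;
  selected MEMs are split by Moran's-I sign into broad-medium and fine
  sets; adjusted-R² variation partitioning (Ezekiel:
  R²ₐ = 1 − (1 − R²)(n − 1)/(n − m − 1)) separates unique from shared
  fractions, each unique fraction tested by residual permutation.

Because survey datasets of this kind are rarely public, the package ships
a synthetic generator that reproduces the statistical structure the
method expects: an east-west temperature gradient interpolated from noisy
weather stations by inverse-distance weighting, compositional land-use
covariates at 7 buffer scales, distance from an invasion source, and
negative-binomial counts in which the invasive species drops to zero
above a hard June-temperature threshold (23.5 °C) while natives follow
July temperature and forest cover.

## Worked example

```python
import memscale as ms

table, truth = ms.make_dataset(ms.SyntheticConfig(seed=1))      # 329 sites
bundle = ms.run_pipeline(table, ms.PipelineConfig(seed=1, nperm=999))

ab = bundle.to_dict()["emphases"]["abundant"]                   # Hellinger emphasis
print([round(v, 2) for v in ab["pca"]["proportion"][:2]])       # [0.75, 0.21]
print(ab["scalograms"]["pca_axis1"]["argmax_component"],        # 0  (very broad)
      ab["scalograms"]["pca_axis1"]["p_value"])                 # 0.001
print(round(ab["rda"]["adj_r2"], 2), ab["rda"]["p_value"])      # 0.54 0.001
```

PCA axes 1–2 carry 75% and 21% of the variance in the transformed
invasive-emphasis table; axis 1's scalogram peaks in the very-broad
component (index 0) with p = 0.001 — the invasive species' thermal
gradient is a whole-region pattern, not a local one. The forward-selected
environmental variables explain the pattern with adjusted R² = 0.54
(permutation p = 0.001), and variation partitioning attributes most of it
to the fraction shared between environment and broad-scale space
(`environment&space_broad` ≈ 0.52 in this run) — spatially structured
environmental control, the signature the generator builds in.

The same pipeline runs from the shell:

```sh
memscale simulate --seed 1 --n-sites 329 --out survey.csv
memscale analyze --input survey.csv --seed 1 --nperm 999 --out results/
memscale test-scalogram --input survey.csv --axis 1 --nperm 999
```

## Layout

| module | contents |
| --- | --- |
| `memscale.graph` | Gabriel graph, spatial weights, connectivity |
| `memscale.mem` | MEM eigenbasis, Moran's I, broad/fine split |
| `memscale.transform` | Hellinger and chi-square transformations |
| `memscale.ordination` | PCA, RDA, PRA, adjusted R², permutation test |
| `memscale.inference` | two-stop forward selection, variation partitioning |
| `memscale.scalogram` | per-MEM R², block smoothing, R²max test |
| `memscale.synthetic` | survey generator + truth bundles |
| `memscale.io`, `memscale.pipeline`, `memscale.cli` | site tables, end-to-end runs, CLI |

See `docs/methods.md` for the statistical details and design choices.
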