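# geothermflora

Statistical machinery for relating geothermal soil gradients to vascular
plant community composition, exercised end-to-end on a synthetic study
system.

Geothermally heated ("endothermal") soils — e.g. acid-sulfate Andosols
around fumaroles and hot springs — carry distinctive floras: a handful of
obligate thermophytes found only on heated ground, a larger set of
facultative thermophytes, and a background flora that drops out as the soil
gets hotter. This package implements, as a tested reusable library, the
analysis chain such a study needs:

- **Taxon over/under-representation.** For a pool of `N` species with `K`
  in a taxon, and a group of `n` species with `k` in the taxon, the chance
  of the observed count is hypergeometric,
  `p(k) = C(K,k)·C(N−K,n−k)/C(N,n)`, and the one-sided inclusive tails
  `P_over = Σ_{i≥k} p(i)` and `P_under = Σ_{i≤k} p(i)` call a taxon over-
  or under-represented at `P ≤ 0.05`, with Benjamini–Hochberg q-values
  (15% FDR) reported alongside.
- **Phylogenetic clustering.** The Net Relatedness Index
  `NRI = −(MPD_obs − mean(MPD_null)) / SD(MPD_null)`, where `MPD_obs` is
  the mean patristic distance over (at most 100 subsampled) pairs of the
  group and the null draws the same number of pairs from the whole pool
  10,000 times; 10 replicates are median-aggregated and averaged over
  three taxonomy-guided graft variants of the backbone tree. Positive NRI
  with a small rank p means the group forms clusters of close relatives.
- **Zone-composition overlap.** Pairwise permutation tests (1000 draws) of
  the number of species shared by two thermal zones against random draws
  from the plot pool, with right- (more similar) and left-sided (less
  similar) p-values.
- **Limiting edaphic factors.** Spearman's rank test plus Hoeffding's D
  (with a permutation p) for every species × soil-property cell; a
  property is *important* for a species at `p ≤ 0.01` by either test, and
  properties disproportionately important for thermophytes are flagged by
  a one-sided Fisher's exact test.
- **Soil indices.** The temperature–depth gradient angle
  `α = arctan((T50 − T15)/35)`, the silica–titanium weathering index
  `STI = 100·SiO₂/(SiO₂/TiO₂ + Al₂O₃/TiO₂ + SiO₂/Al₂O₃)` and
  `Silica/R₂O₃ = SiO₂/(Al₂O₃+Fe₂O₃+TiO₂)`, one-sided Mann–Whitney zone
  comparisons with Bonferroni correction (exact by enumeration for small
  samples, tie-robust), and topsoil composition normalized to the
  non-heated zone.

Because no machine-readable species lists or soil tables accompany such
field studies, the package ships a first-class synthetic-data generator
(`geothermflora.synthetic`) that reproduces the statistical structure the
analysis assumes — 292 species in 60 families on an ultrametric tree,
thermophytes planted in few families, four thermal zones with nested hot
compositions and monotone soil gradients, and cover values coupled to
chosen soil properties through a Gaussian copula — so every stage is
testable and the whole chain runs from one seed.

## Worked example

```python
from geothermflora.pipeline import demo
report = demo("out", seed=0)
r = report.nri["thermal"]
print(f"thermal NRI = {r.nri:.2f}, p = {r.p_value:.4f}")
fam = report.enrichment[("thermal", "family")]
print(fam.loc[fam["call"] == "over", ["taxon", "K", "k", "p_over"]])
```

prints (seed 0):

```
thermal NRI = 6.07, p = 0.0001
   taxon  K  k        p_over
2  fam03  5  5  1.374394e-04
4  fam05  3  3  5.070636e-03
9  fam10  8  8  5.351080e-07
33 fam34  8  8  5.351080e-07
35 fam36  5  5  1.374394e-04
53 fam54  9  9  8.101987e-08
58 fam59  9  9  8.101987e-08
```

i.e. the 51 thermal species are far more closely related than random pairs
from the pool (NRI ≫ 0, p at the permutation floor), and exactly the
families into which the generator packed them are called over-represented.
The same run writes enrichment, NRI, zone-overlap, edaphic and soil tables
plus a `manifest.yaml` under `out/`, and reruns are byte-identical.

The numbered scripts under `analysis/` tell the same story stepwise
(simulate → enrichment → clustering → zone overlap → edaphic screen → soil
gradients), each writing its tables under `results/`.

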