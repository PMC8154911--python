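# Methods

This note documents the statistical procedures the package implements, the
choices made where the design was genuinely open, and what the synthetic
study system does and does not emulate.

## Study system and synthetic data

The analyses target a geothermal catena: four thermal zones (I–IV) defined
by soil temperature at 15 cm depth, from non-heated (< 25–30 °C) to hot
(> 80 °C), carrying a vascular flora in which obligate thermophytes occur
only on heated ground and facultative thermophytes on both. The synthetic
generator reproduces the features the statistics rely on:

- **Phylogeny.** An ultrametric depth-1.0 tree over 292 species in 60
  monophyletic families, built by a two-level random-coalescence process:
  family crown ages are drawn in (0.15, 0.45) and between-family divergences
  in (0.55, 1.0), so family clades are clean and deep. A pure-birth process
  would serve equally; the coalescence construction was chosen because it
  guarantees ultrametricity by construction rather than by rescaling.
- **Thermal status.** 18 obligate and 33 facultative thermophytes (the
  facultative count mirrors the study scale; the obligate count is a free
  parameter of the design, set once at 18). Thermal species are assigned
  sequentially: with probability `clustering_strength` (default 0.9) the
  next one comes from a family that already holds a thermal species,
  otherwise uniformly — at strength 1 thermophytes pack into as few
  families as possible, at 0 the assignment is exchangeable and per-family
  counts are exactly hypergeometric (a property the tests verify by Monte
  Carlo).
- **Zones.** Richness 24/18/12/8 from zone I to IV (species counts per
  square metre in such systems fall from the low twenties to below ten
  with heating). The hot zones are nested (IV ⊆ III ⊆ II), built hottest
  first with non-thermal species down-weighted by zone
  (weights 1 / 0.30 / 0.10 / 0.03), while zone I is drawn independently
  with obligate thermophytes nearly excluded — so non-thermal species drop
  out first toward the hot end and zone I differs from the heated zones.
  A `nested_zones=False` switch draws all zones uniformly for calibration
  experiments.
- **Soil.** Per-property zone means with truncated Gaussian noise, clipped
  to physical ranges (pH 0–14, percentages 0–100, temperatures −20…110 °C);
  particle-size closure assigns silt the remainder of 100 − sand − clay.
  Default gradients: temperature, EC, TiO₂, Al₂O₃, Fe₂O₃, kaolinite and
  clay increase toward zone IV; pH, Eh, SOC, SiO₂, smectite, quartz and
  sand decrease. The 15→50 cm temperature rise is ~3 °C in zone I
  (gradient angles of ~4.6–5.2°), ~9.5 °C in II, ~20 °C in III (angles in
  the twenties to thirties) and ~2 °C in the uniformly hot zone IV.
- **Cover.** A plot × species matrix (12 plots cycling through the zones,
  28 species of which 9 are thermophytes). Nominated species are coupled
  to a soil property through a Gaussian copula: cover = 100·Φ(z) with
  z = s·ρ·z_prop + √(1−ρ²)·ε, which plants a controllable Spearman
  correlation because Φ is monotone. Non-effect species get independent
  noise.

**What the generator does not emulate:** zero-inflated cover (real cover
matrices are mostly absences), spatial autocorrelation among plots,
mineralogy co-occurrence beyond monotone gradients, measurement error
structure in oxide totals, and polytomies or calibration uncertainty in
the backbone tree. Passing tests therefore demonstrate correctness and
calibration of the statistical machinery under clean monotone signals,
not robustness to those real-data features.

All generators draw from a single `numpy` Generator seeded by the config;
identical configs give byte-identical trees and tables.

## Taxon representation

Exact hypergeometric tails, both inclusive of the observed count, so
`P_over + P_under = 1 + p(k)` (an identity the tests assert to 1e-12).
Probabilities come from log-gamma-space routines stable at pool sizes in
the hundreds; the test oracle recomputes them with big-integer rational
arithmetic. Primary calls use the raw `P ≤ 0.05` rule; Benjamini–Hochberg
q-values are attached per rank (FDR applied within each rank, not across
ranks — the alternative is defensible but mixes taxa of very different
sizes) with calls at q ≤ 0.15 reported side by side. Single-species taxa
are reported but flagged low-power: with `K = 1` the smallest attainable
`P_over` is `n/N`, which cannot reach 0.05 for the group sizes used here.
Merging two thermal-status surveys follows an "observed thermal anywhere"
rule: thermal in either source wins; obligate contradicted by facultative
or non-thermal resolves to facultative, since the species was seen outside
heated ground at least once.

## Net Relatedness Index

`MPD_obs` is the mean patristic distance over the group's pairs, subsampled
to 100 pairs when the group forms more; the null distribution draws the
same number of distinct pairs uniformly from all pairs of the pool, 10,000
times. This **pair-subsampling null differs from the classic taxa-shuffle
null** (which draws intact groups of tips): it conditions on the number of
pairs, not the number of species, and is cheaper at megatree scale. Its
p-value is the add-one left-tail rank, `p = (#{null ≤ obs}+1)/(draws+1)`
(clustering means small MPD), which avoids p = 0 and is permutation-valid;
calibration under random groups is verified empirically (Kolmogorov–
Smirnov uniformity over 200 random 20-species groups).

The index standardizes against the null **mean**:
`NRI = −(MPD_obs − mean(MPD_null))/SD(MPD_null)` with the sample (n−1)
standard deviation. A min-standardized variant is retained as an explicit
option, but it is one-signed and cannot yield the documented behaviour of
positive NRI for clustered and negative for overdispersed groups, so the
mean convention is the default. A degenerate null (SD = 0, e.g. a star
tree) yields NRI = NaN rather than ±∞; the p-value is still computed.

Subsampling stochasticity is absorbed by 10 replicates per tree
(median NRI and median p), and the per-tree medians are averaged across
three graft variants of the backbone: a fraction of species (default 23%,
≈ 68 of 292) is pruned and re-attached (i) at the family crown node as a
basal polytomy, (ii) at a uniformly chosen internal node of the family
clade, or (iii) by a taxonomy-constrained rule that falls back to the
order's MRCA when the family has no tips (a stand-in for megatree
placement services, which resolve roughly to the same hierarchy). Grafted
pendant branches get length equal to tree depth minus attachment depth,
preserving ultrametricity exactly; a single-tip family is first split at
the midpoint of its pendant branch so it stays monophyletic. Grafting
never perturbs distances among pre-existing tips. Polytomies created by
grafting are kept, not resolved.

Scaling all branch lengths by a constant scales MPDs and leaves NRI and p
unchanged to floating-point precision (asserted at 1e-9).

## Zone overlap

The null for a zone pair draws independent uniform subsets of the two
observed sizes from the plot pool, without replacement within a subset,
1000 times, and counts common species. Both tails include ties and carry
the add-one correction, so `p_right + p_left ≥ 1` and neither tail can be
exactly zero. The null overlap mean equals the hypergeometric expectation
`|A||B|/|pool|`, which the tests check within Monte-Carlo error. The pool
is the union of observed zone compositions by default and is an explicit
argument everywhere.

## Edaphic screen

Spearman's rho uses mid-ranks; for n ≤ 9 the two-sided p enumerates all
n! permutations of one margin exactly (so a perfect monotone series of 8
plots gives p = 2/8!), and the t-approximation takes over for larger n
(adequate at the 12-plot scale: empirical P(p ≤ 0.01) ≈ 0.012 under
independence). Hoeffding's D uses the count-based formula with ½/¼ tie
weights, on the standard scale where D ∈ [−0.5, 1] and D = 1 for a strict
monotone bijection; its p-value is a one-sided permutation test (default
9999 permutations, vectorized over permutations) rather than the classical
asymptotic table — exact validity at small n was preferred over fidelity
to the table-based implementation. Brute-force O(n²) agreement and exact
calibration of the permutation p are both in the test suite.

A property is important for a species when either test reaches p ≤ 0.01.
No multiple-testing correction is applied across the species × property
grid — mirroring the screening character of the original design, where
flags feed expert interpretation rather than confirmatory claims — so
under global independence about 2α of cells flag by chance; BH q-values
are emitted as extra columns for users who want them. Missing values are
dropped pairwise; constant property columns are excluded with a warning.
The thermophyte aggregation is the one-sided Fisher exact probability of
the (thermophyte × important) 2×2 table, computed as the hypergeometric
upper tail — literally the same `p_over` routine as the taxon screen, and
cross-checked against an independent Fisher implementation in the tests.

## Soil statistics

The temperature–depth model is linear, `T(d) = k·d + T15` anchored at the
15 cm reference depth; with the standard two measurements (15 and 50 cm)
the slope is exactly `(T50 − T15)/35` and multi-depth profiles use least
squares. The gradient angle is `α = arctan k` in degrees: a non-heated
profile rising ~3 °C over the interval gives α ≈ 4.6–5.2°, a strongly
heated one rising 25 °C gives α ≈ 35.5°.

STI and Silica/R₂O₃ are computed directly from oxide mass percentages;
Silica/R₂O₃ is invariant under common rescaling of all oxides while STI is
not (it mixes ratios with an absolute SiO₂ term) — both behaviours are
asserted.

Group comparisons use the one-sided Mann–Whitney U test. When the number
of group assignments C(n₁+n₂, n₁) is at most 20,000 the p-value is an
exact full enumeration over assignments, which remains valid under ties
(the classical exact U distribution does not); larger samples use the
tie-corrected normal approximation. The caller must state the direction;
Bonferroni multiplies by the number of pairwise tests performed, capped at
1. Composition profiles are normalized to zone I by ratios of per-zone
medians (median rather than mean for robustness at 3 pits per zone; the
statistic is an argument), with zero reference medians yielding flagged
NaNs; the operation is idempotent. Temperature classes are left-closed:
< 30 (non-heated), 30–50 (slightly heated), 50–80 (moderately heated),
≥ 80 °C (hot), so a 30 °C sample is "slightly heated".

## Pipeline and problem sizes

`pipeline.run_all` derives one independent random stream per stage from
the run seed (`SeedSequence.spawn`), writes all tables with a fixed float
format, and records seeds, thresholds and the planted signals in a
manifest, making reruns byte-identical. A failing stage removes the
partially written bundle and reports the stage name. Stage toggles allow,
e.g., running without the tree-based stage.

Default problem sizes — 292 species, three graft variants, 10 replicates ×
10,000 null draws per NRI group, 1000 zone-overlap draws, 999 Hoeffding
permutations per cell at 12 plots — complete in a few seconds on a single
core; the heavier calibration experiments in the acceptance tests (200-seed
NRI uniformity, 5000-simulation Hoeffding calibration) were sized to give
stable Monte-Carlo verdicts (3 standard errors) in a couple of minutes.

## Known limitations

- The pair-subsampling null is not the taxa-shuffle null of classical
  community phylogenetics; NRI magnitudes are not comparable across the
  two conventions (the pair null has smaller variance for fixed pair
  count, inflating |NRI| for strongly clustered groups).
- The taxonomy-constrained graft method approximates megatree placement
  with the family→order hierarchy only; it does not consult any external
  reference topology.
- Hoeffding's D here is tested by permutation; published tables or
  asymptotic p-values from other implementations will differ slightly.
- The expert step of grouping species into ecological guilds from shared
  limiting factors is out of scope: the package exposes the importance
  matrix and stops there.
- Synthetic cover values are never exactly zero, so presence/absence
  effects of real cover data are untested.
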