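# Methods

## The inference problem

A lake fish ingests environmental microbes as it feeds, so its gut community
is, to first order, a mixture of the communities it feeds in, filtered
through the host. Pelagic feeders should therefore carry gut communities
that coalesce mostly with the water microbiota, benthic feeders with the
sediment microbiota. `microcoalesce` turns this into an estimation problem
(how much of each gut community is attributable to water vs sediment
sources?) and a validation problem (does the resulting binary habitat label
explain community structure better than host species, family, or trophic
level?).

## Source-tracking model

The sink (gut) count vector x over T taxa is modelled as
Multinomial(N, Σⱼ αⱼ γⱼ + α_u γ_u), where the γⱼ are the latent taxon
distributions behind the observed source count vectors sⱼ (each water and
sediment sample enters as its own source; class totals are obtained by
summing α afterwards, which preserves site information), and γ_u is an
unknown source absorbing sink reads unexplainable by any observed source.
EM maximizes the joint likelihood of sink and source counts:

- E-step: rᵢⱼ = αⱼ γⱼᵢ / Σ_l α_l γ_lᵢ for each sink taxon i.
- M-step: αⱼ ∝ Σᵢ xᵢ rᵢⱼ; γⱼ ∝ sⱼ + assigned sink counts; γ_u ∝ assigned
  sink counts only.

A pseudocount of 1e-6 reads is added to every source count so that no taxon
has an exactly-zero source probability (EM can never move mass onto a hard
zero). The log-likelihood reported in the trace is the pseudocount-augmented
joint objective, which makes the trace exactly non-decreasing.

**Unknown-source initialization.** The saturated solution α_u = 1,
γ_u = x/N is a global maximum of this likelihood, so the meaningful estimate
is a local optimum anchored near the observed sources; which optimum EM
reaches depends on where γ_u starts. Initializing γ_u uniformly over
sink-present taxa lets the unknown drift into source-explainable reads
(class-proportion errors around 0.1 on synthetic ground truth). We instead
initialize γ_u on the positive residual max(x/N − mean source profile, 0),
i.e. on the part of the sink the sources visibly do not explain, with the
uniform profile as a degenerate fallback. Ground-truth recovery error then
drops to ≈ 0.02.

**Convergence** is declared when no mixing proportion changes by more than
`tol` (default 1e-8) in an iteration, up to `max_iter` = 5000 iterations.
The α-update is monitored rather than the likelihood because the joint
log-likelihood is dominated by the fixed-magnitude source-count term
(≈ −10⁷ at survey depths), making any relative-likelihood criterion
insensitive to the sink fit — with a relative criterion EM halts while α is
still moving by ~0.1 on small sinks. Three restarts (uniform α, then
Dirichlet-jittered) guard against poor starts; the best final likelihood
wins.

**Habitat rule.** pelagic if Σ α_water > Σ α_sediment, benthic if the
reverse, unresolved on an exact tie. Sinks with α_unknown > 0.5 are flagged
low-confidence but still labelled; whether the unknown proportion should be
renormalized away is scientifically unsettled, so both the raw totals and
the flag are reported.

## Synthetic study generator

The generator emulates the survey the estimators are designed for, and its
defaults are the study conditions used by every recovery test:

- 200 taxa; 20 reserved for the unknown (host-resident) block, absent from
  both environmental sources, which makes the unknown component
  identifiable; water support 80 and sediment support 120 taxa with an
  overlap fraction of 0.3 of the smaller support.
- Water base profile ~ Dirichlet(0.3) (uneven, low effective diversity),
  sediment ~ Dirichlet(5.0) over a larger support (even, high diversity),
  reproducing the usual sediment > water α-diversity contrast; per-site
  profiles are Dirichlet-resampled around the habitat base (concentration
  2000), so the three sites are similar but not identical.
- 28 gut samples: 7 species × 4 fish, species nested within habitat groups
  (4 pelagic species = 16 fish, 3 benthic = 12; a 7-species design cannot
  nest whole species and split 14/14). Each fish mixes its site's water and
  sediment profiles with a major-source proportion drawn uniformly from
  [0.55, 0.8], an unknown weight of 0.1, and the minor source taking the
  remainder; sampling depth 50,000 reads throughout.
- δ15N per fish ~ Normal(species mean, 0.3‰), species means spanning
  10–15‰ against a primary-consumer reference of 8.0‰ (synthetic values;
  chosen so the high-trophic species straddle both habitat groups and the
  trophic factor is not a relabelling of habitat).

What the generator does *not* emulate: compositional overdispersion beyond
the Dirichlet site/host variation, taxon-taxon ecological interactions,
sequencing error, chimeras, or phylogenetic structure. Passing recovery
tests therefore show the estimator is correct *under its own observation
model* — the well-posed version of the question — not that real gut data
meet that model.

## Statistical components

- **Filtering**: a taxon survives when its total count across all samples is
  ≥ 0.005% of the grand total (≥ rule: a taxon sitting exactly on the
  boundary, e.g. 5 reads in 100,000, is kept). Filtering is global, not
  per-sample.
- **Shannon** uses natural logs. **Bray–Curtis** is computed on raw counts
  (the convention of the standard community-ecology toolchain), not on
  relative abundances.
- **ANOSIM**: R = (mean between-group rank − mean within-group rank) /
  (n(n−1)/4) over ranked pairwise dissimilarities; p = (1 + #{R_perm ≥
  R_obs}) / (1 + n_perm) with 999 permutations by default, so p can never be
  0 and the smallest attainable p is 1/1000. q-values are BH step-up across
  the four factors. An exhaustive-enumeration variant exists for small n and
  is used to validate the Monte-Carlo p.
- **NMDS**: nonmetric SMACOF (monotone regression) on the Bray–Curtis
  matrix, 20 random starts, 500 iterations, convergence 1e-9, Kruskal
  stress-1 reported; seeded.
- **PAM**: greedy BUILD then best-improvement SWAP on the dissimilarity
  matrix; ties break toward the lowest sample index, making runs
  deterministic. Verified against exhaustive medoid-set enumeration on
  small instances.
- **Calinski–Harabasz** is computed on a classical principal-coordinate
  embedding of the dissimilarity matrix (components with positive
  eigenvalues kept), which makes the centroid-based sums of squares
  well-defined for a non-Euclidean dissimilarity; k is scanned over 2..8.
- **Matching rate** maps each cluster to its majority factor level (ties to
  the lexicographically smallest level) and scores the fraction of samples
  matching their cluster's level.
- **Supervised AUC**: 500-tree random forest under leave-one-out
  cross-validation (n = 28 makes k-fold schemes noisy), macro one-vs-rest
  AUC on pooled out-of-fold probabilities.
- **Networks**: per-habitat-group Spearman correlations among taxa present
  in > 50% of the group's samples; edge when |ρ| ≥ 0.8 and BH-adjusted
  p < 0.05. The threshold 0.8 is a configuration default, not derived by
  random-matrix theory; edges ignore sign, since the downstream robustness
  analysis consumes an unsigned 0/1 adjacency.
- **Robustness**: for each removal fraction f in {0.05, …, 0.50},
  round(f·n) nodes are deleted uniformly at random, the natural connectivity
  ln((1/n')Σ e^λ) of the induced subgraph is computed via a symmetric
  eigendecomposition (log-sum-exp for overflow safety), means over 1,000
  iterations are regressed on f by OLS, and the slope is the stability
  statistic: steeper decline = less robust. Slopes are only comparable
  between networks of similar order, because natural connectivity scales
  with n.

## Numerical and design notes

- All randomness flows through `numpy.random.Generator` objects seeded
  explicitly; the pipeline spawns per-stage sub-seeds from one master seed
  via `SeedSequence`, so reports are byte-identical across runs.
- Trophic level TL = (δ15N_consumer − δ15N_reference)/3.4 + λ with λ = 2 for
  a primary-consumer reference; the binary trophic grouping assigns the
  boundary TL = 2.8 to the *high* group. The reference organism's δ15N is a
  per-study input supplied with the data (the generator emits its own).
- A weighted-UniFrac variant of the factor ANOSIM is not provided: no
  phylogeny accompanies the count tables, so Bray–Curtis is used throughout.
- Degenerate inputs are rejected loudly (all-equal distance matrices for
  NMDS, single groups for ANOSIM/silhouette, empty sources for coalescence,
  zero-total samples for relative abundance) rather than patched silently.

## Known limitations

- The EM estimator inherits the identifiability caveat of all
  unknown-source mixture models: the reported α is a local optimum selected
  by a deliberate initialization policy, and sinks dominated by the unknown
  (flag `low_confidence`) should not be habitat-classified without care.
- Rank-correlation networks on 12–16 samples are noisy; the prevalence rule
  (> 50%) keeps correlations defined but small-sample ρ estimates remain
  coarse, and the 0.8 threshold is a convention.
- The acceptance-level simulations run at desk scale (depth 50,000, 200
  taxa, 28 + 6 samples) — the package's own default study size, chosen to
  mirror the emulated survey design.
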