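# microcoalesce

Who seeded a fish's gut microbiota — the water column or the sediment?

`microcoalesce` infers the **vertical habitat preference** of lake fish
(pelagic vs benthic feeding) from 16S amplicon data alone, by measuring the
**coalescence** between each fish's gut community and the microbial
communities of its habitat, and then tests whether that preference — rather
than host taxonomy or trophic level — is the dominant factor structuring the
gut microbiota. It is aimed at microbial ecologists working with
ASV-by-sample count tables from surveys that pair host-associated samples
with environmental source samples.

## The model

Each gut community (the *sink*) is modelled as a multinomial draw from a
convex mixture of *source* communities plus an unknown residual:

    x ~ Multinomial( N, Σ_j α_j γ_j + α_u γ_u ),   Σ α = 1,  α ≥ 0

where γ_j are the (latent) taxon distributions of the water and sediment
samples and α_j the mixing proportions. The α are estimated by
expectation–maximization on the joint likelihood of sink and source counts
(the fast source-tracking model): the E-step assigns each sink read a
responsibility r_ij = α_j γ_ji / Σ_l α_l γ_li, the M-step re-estimates α
from the assigned reads and γ from source counts plus assigned reads. The
class sums Σ α over water sources and over sediment sources are the
**coalescence extents**; a fish is called *pelagic* when its gut coalesces
more with water than with sediment, *benthic* otherwise.

The validation machinery around the classifier reproduces a complete factor
comparison: Shannon diversity, Bray–Curtis dissimilarity, NMDS, ANOSIM with
999 permutations and Benjamini–Hochberg FDR, PAM (k-medoids) clustering with
Calinski–Harabasz selection of k and per-factor matching rates,
leave-one-out random-forest AUC, and Spearman co-occurrence networks whose
stability is measured by the decline slope of natural connectivity
( ln(1/n Σ e^λᵢ) over adjacency eigenvalues ) under random node removal.

Because the original survey data are not deposited, the package ships a
first-class synthetic study generator (`microcoalesce.synth`) that emulates
the study design — 28 gut samples (7 species × 4 fish), 3 water and 3
sediment samples across 3 sites, two latent habitat groups with known mixing
proportions, and per-fish δ15N values — so every estimator can be exercised
against ground truth.

## Worked example

```python
import microcoalesce as mc

# simulate the survey, filter rare ASVs (0.005% of all reads), source-track
table, meta, truth = mc.generate_study(seed=1)
table = mc.filter_rare_asvs(table)
estimates, coalescence = mc.track_study(table, meta, seed=1)
print(coalescence.head(3).round(3))
```

```
           water_total  sediment_total  unknown  habitat  low_confidence
sample_id
AN1              0.731           0.142    0.127  pelagic           False
AN2              0.705           0.163    0.132  pelagic           False
AN3              0.700           0.158    0.143  pelagic           False
```

Fish `AN1` draws an estimated 73% of its gut community from water and 14%
from sediment (the rest is host-resident "unknown"), so it is classified
pelagic. Against the generator's ground truth the class-summed proportions
are recovered with mean absolute error ≈ 0.02 and every habitat label is
correct. The full pipeline —

```python
report = mc.run_study(seed=1)
print(report["clustering"]["selected_k"])       # 2
print(mc.factor_ranking(report).round(3))
```

```
          factor  anosim_R  anosim_q  matching_rate    auc
0        habitat     0.997     0.002          1.000  1.000
1        species     0.515     0.002          0.286  0.639
2  trophic_group    -0.035     0.878          0.571  0.190
3         family    -0.095     0.878          0.857  0.578
```

— selects k = 2 clusters (the two habitat groups) and ranks habitat
preference above species, family and trophic group on ANOSIM R, PAM matching
rate, and random-forest AUC simultaneously: the qualitative conclusion the
package is built to test.

A thin CLI mirrors the library: `microcoalesce simulate`, `sourcetrack`,
`trophic`, `evaluate-factors`, `network`, `report` (see `--help`).

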