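# Methods

This note documents the statistical procedures, the synthetic-data model,
the parameter defaults and the numerical choices behind `invanet`, in the
order the pipeline runs them.

## Study design and data model

The pipeline targets paired field surveys: `n_sites` sites, each with one
rhizosphere sample under invasive vegetation (group **AP**) and one under
native vegetation (group **N**). Inputs are an OTU count table (samples ×
OTUs), a 7-rank taxonomy, sample metadata (site, group, lon/lat and seven
edaphic variables: pH, TC, TN, TP, AN, NN, AP), a qPCR CT matrix over a
chip panel, and per-sample absolute 16S copy numbers measured separately.
All tables are tab-separated text; networks are exported as GraphML.

The bundled chip panel has 71 functional assays — 35 carbon-cycle
(16 degradation, 13 fixation, 6 methane metabolism), 22 nitrogen, 9
phosphorus and 5 sulfur — plus one 16S reference. The element totals are
fixed by the chip; the split of the 35 carbon assays across the three
carbon subcategories is a package choice consistent with the relative sizes
observed in field deployments of the chip (degradation > fixation >
methane).

## qPCR quantification

Relative copy number is `N₀ = E^(31 − CT)` with E the assay's fold
amplification per cycle (default 2.0): CT = 31 is the detection threshold,
mapping to one relative copy; blank cells and CT > 31 are non-detects and
true zeros downstream (no imputation). Assays with E < 1.8 or E > 2.2 are
removed outright (bounds inclusive — only strictly outside values are
eliminated). Absolute copies per gram are
`N₀(gene) × abs16S / N₀(16S)` per sample; a sample whose 16S reference is
itself a non-detect is flagged and its abundances left undefined. The
synthetic generator produces CT values by inverting this chain exactly, so
quantification recovery is exact by construction (round-trip error is at
floating-point level, ~1e-15). Abundances below the detection floor
`abs16S / E^(31 − CT_ref)` are genuine non-detects and quantify to zero;
the round-trip guarantee applies to detected genes.

## Community statistics

Rarefaction subsamples each sample without replacement (multivariate
hypergeometric) to a common depth, defaulting to the minimum sample total;
shallower samples are dropped with a warning. Alpha diversity is computed
on rarefied counts: richness, bias-corrected Chao1, ACE with rare cutoff
10 (when every rare taxon is a singleton ACE is undefined and the
bias-corrected Chao1 is reported in its place, the EstimateS convention),
Shannon with natural log, and Gini–Simpson `1 − Σp²` (an inverse-Simpson
variant is available by flag; the literature uses both under the name
"Simpson diversity"). All-zero samples yield NaN with a warning, never a
silent zero.

Bray–Curtis, PCoA and ANOSIM are standard. PCoA retains negative
eigenvalues in the report (Bray–Curtis is a semi-metric) but excludes them
from coordinates and explained proportions; on Euclidean distance matrices
the embedding reproduces the input distances to 1e-9. ANOSIM uses mid-ranks
for ties and the +1 permutation convention, so p ≥ 1/(n_perm+1) and a seed
fully determines the result. The Kruskal–Wallis screen collapses the table
to a taxonomic rank, keeps the `top_n` most-abundant taxa (top-10 phyla and
top-20 families in the pipeline), and reports raw p-values against 0.05 —
no multiplicity correction by default, matching common practice for these
screens; a BH column is available.

## Networks and keystones

Features must be present (count > 0) in strictly more than 80% of samples.
OTU counts enter as relative abundances; genes as absolute copies (the
normalization is configurable — the field does not standardize this).
All pairwise Spearman correlations (mid-rank ties, two-sided p from the
t approximation) form one BH family per network build; an edge requires
|ρ| strictly above `r_min` (0.6 for the OTU+gene fMEN, 0.8 for the
gene–gene preset) and adjusted q strictly below 0.05. |ρ| rather than
signed ρ is thresholded so negative associations are kept and tagged.
Unadjusted-p mode exists because figure-level analyses sometimes use raw
p < 0.05.

Topology: average local clustering counts degree<2 nodes as 0;
transitivity is 3·triangles/triads; distances and diameter are computed on
the largest connected component (component count is reported); modularity
comes from greedy agglomerative maximization (deterministic) on the
unweighted graph. Keystone taxa are the top-5 degree OTU nodes, ties broken
by higher mean relative abundance then lexicographic id; fewer than 5 OTU
nodes returns them all with a warning.

## Driver importance

Two methods share one interface. `rf_permutation` is a bagged regression
forest (bootstrap-resampled scikit-learn decision trees). Importance is
%IncMSE: out-of-bag predictions are aggregated across trees, and each
predictor's OOB values are permuted (one shared shuffle per tree, which
also makes the result exactly invariant to predictor column order); the
importance is the percentage increase of the aggregate OOB MSE. `lmg` is
the averaged-over-orderings R² decomposition of the linear model, computed
from its subset-weight closed form (capped at 15 predictors since it
enumerates 2^p subsets); contributions sum to the full-model R² to 1e-9.

Significance for both comes from permuting the response: each observed
importance is compared to the null distribution of the **maximum**
importance across predictors (+1 convention). The max-null controls the
family-wise false-positive rate at the nominal level, so a null dataset
declares any predictor significant in ≈5% of runs regardless of how many
predictors are screened; a per-predictor null would inflate that to ~20%
at five predictors.

The keystone–gene regression defines "average standardized abundance" as:
z-score each keystone OTU's ln abundance across samples, then average the
z-scores within each sample; the response is ln gene abundance; the fit is
OLS. Zeros under a ln transform are an error by default (with the offending
samples listed); an optional pseudo-count of half the smallest positive
value is available and logged.

RDA standardizes the response columns, regresses them on centered
predictors, and takes the PCA of the fitted values; the overall test is a
permutation F (rows of the predictor matrix permuted). Collinear predictors
raise an error naming the dependent pair.

## Spatial interpolation

IDW with planar Euclidean distance in decimal degrees (the study region
spans ~1.3°, where planar error is negligible; haversine is available by
flag), default power 2, on a 100×100 grid over the data's bounding box
padded 5%. The interpolator is exact at sample points and, being a convex
combination, bounded by the input range. The north/south contrast splits at
the median sample latitude by default and applies the Kruskal–Wallis test
per gene category.

## Synthetic-data generator

The generator is the package's test-bed: it emulates the paired survey and
plants known structure recorded in `SyntheticTruth`.

OTU counts are Dirichlet-multinomial draws (concentration 500 around the
softmax of per-sample log means; depth log-normal around 15,000 reads,
floor 1,000). The log-mean of OTU i in sample s is

```
base_i + site_effect(site(s), i) + λ·f_s·[i keystone of group(s)] + δ·dir_i·[group=AP] + ε
```

with `f_s ~ N(0,1)` a per-sample latent factor, `dir_i = +1` for responder
phyla Bacteroidetes/Nitrospirae, `−1` for Actinobacteria, site-by-feature
effects N(0, 0.3) and residual ε ~ N(0, 0.25). Functional-gene log
abundances load the same factor with weight λ, add a latitude gradient
γ·z_lat for the configured categories (C-degradation, C-fixation,
C-methane, P), site effects N(0, 0.3) and residual N(0, 0.2). Ammonium
nitrogen is shifted by δ standard deviations between groups and negatively
coupled to the factor in AP samples, mirroring the invader's preferential
ammonium uptake. Defaults: λ = 0.9, δ = 0.8, γ = 0.8.

Two generator choices deserve explanation:

* **Keystone abundance floor.** Planted keystones are forced into the upper
  abundance tail (95th percentile of base abundance, ≈1–2% relative
  abundance). The latent-factor model is a Gaussian copula whose loading λ
  sets a target Spearman correlation; at low abundance,
  Dirichlet-multinomial counting noise attenuates the realized correlation
  far below that target, making the planted structure undetectable at
  realistic sample sizes. Residual noise defaults (0.25/0.2 log units) were
  likewise calibrated so that λ spans chance-level (λ=0) to reliably
  recoverable (λ=0.9) keystone structure at n = 22 samples per group.
  Consequence: the generator demonstrates recovery of *abundant* keystones;
  field surveys report keystones that can be rare, a harder regime the
  synthetic benchmark does not cover (see Limitations).
* **The calibration null.** `SynthConfig.null()` zeroes λ, δ, γ **and** the
  site random effects. Site effects correlate the paired samples, and under
  that dependence group-label permutation tests (ANOSIM) are conservative
  rather than exact — samples are not exchangeable. A type-I-error
  calibration requires an exchangeable null, so the null configuration
  removes all structure. The conservatism under pairing is a property of
  ANOSIM on paired designs, worth knowing when interpreting real-data
  p-values.

Coordinates are uniform over the study bounding box (38.74–40.04°N,
116.36–117.85°E). Determinism: one `numpy` Generator seeded from the
config; identical config+seed gives bit-identical datasets. The pipeline
derives per-stage seeds from a single global seed via `SeedSequence`
spawning in fixed stage order, so stages can be re-run in isolation.

## Problem sizes in tests and the acceptance script

Calibration simulations use the sizes that make their claims meaningful:
400 null datasets of 20 samples for ANOSIM type-I error, 50 default-size
(44-sample) datasets for keystone recovery, 100 null seeds (n=40, five
predictors, 60 trees, 19 permutations) for importance false-positive
rates, 1,000 random abundance vectors for the quantification round-trip.
The forest and permutation counts in the calibration harness are smaller
than the analysis defaults (500 trees, 99 permutations) — the false-positive
rate of a permutation test does not depend on those sizes, only its
resolution does.

## Limitations

* Planted keystones are abundant by design; rare-keystone recovery is not
  benchmarked.
* The generator has no phylogenetic signal, no compositional interactions
  beyond closure, and field edaphic variables are mostly independent —
  real covariance structures are richer.
* Spearman co-occurrence networks inherit all known caveats of
  correlation-based inference on compositional data; no SparCC/SPIEC-EASI
  style correction is attempted.
* ANOSIM p-values on paired designs are conservative (see above); the
  pipeline reports them as computed.
* The BH family is all pairs tested within one network build; a different
  family choice changes edge counts.
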