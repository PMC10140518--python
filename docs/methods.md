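# Methods

## The analysis chain

The package reimplements, as a tested library, the downstream statistics
of a root-compartment 16S survey: a taxa × samples count matrix with a
3 compartment × 3 stage × 3 replicate design is rarefied, summarized by
alpha/beta diversity, partitioned into community-assembly processes by
phylogenetic and taxonomic null models, condensed into per-compartment
co-occurrence networks with node roles, and annotated with
beta-regression abundance trends and rule-based functional groups.

## Data model and normalization

The community matrix is oriented taxa-rows × sample-columns throughout.
Normalization is rarefaction: each sample is subsampled without
replacement (a multivariate hypergeometric draw) to a common depth,
default the minimum sample total, under an explicit seed. Richness
estimators (Chao1, ACE) refuse non-integer input because their
singleton/doubleton logic is undefined after scaling. Prevalence
filtering is strict — a taxon must occur in *more* than the threshold
fraction of samples — so a taxon present in exactly half the samples is
removed at the 0.5 default.

Taxa present in the matrix but absent from the phylogeny abort the
assembly stage by default; an explicit `missing_taxa="prune"` drops them
with a warning. Silent pruning would change βMNTD without notice.
Missing taxonomy ranks are carried as explicit empty strings so that
phylum aggregation never folds unknowns into a named phylum.

## Diversity conventions

* Shannon uses the natural log; for rarefied OTU tables of a few
  thousand taxa this gives values in the 6–7 range typical of soil.
* Simpson is reported as the *unbiased dominance* form
  D = Σ nᵢ(nᵢ−1)/(N(N−1)) — values near 0 for diverse soils,
  anti-correlated with Shannon — rather than 1 − D.
* Chao1 uses the bias-corrected (+1) form uniformly so that samples
  without doubletons never divide by zero.
* ACE uses the conventional rare/abundant cutoff of 10; when every rare
  taxon is a singleton, the coverage estimate C_ace is 0 and ACE falls
  back to Chao1 with a warning.
* PCoA reports all eigenvalues (negative ones arise for Bray–Curtis) but
  keeps coordinate axes only for positive eigenvalues, with explained
  proportions relative to the positive-eigenvalue sum.
* PERMANOVA is the standard one-way sum-of-squared-distances
  decomposition with seeded label permutations;
  p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm), hence bounded below by
  1/(n_perm + 1). Its pseudo-F is cross-checked against scikit-bio's
  implementation in the test suite, and its type-I error is verified to
  sit at the nominal 5% on null simulations.
* Percent changes between group means are reported to two decimals as
  100·(a − b)/b. The bundled published summary means reproduce their
  narrative percentages exactly at that precision; where a published
  abstract rounds differently from its own table, the table arithmetic
  is the one reproduced here.

## Assembly null models

βMNTD between samples j and k is the abundance-weighted mean patristic
distance from each taxon to its nearest relative in the other sample,
averaged over both directions. βNTI is its z-score under a null that
shuffles which tips the taxa occupy. Two scopes are available:

* `pair_union` (default): taxa are re-placed only within the union of
  the focal pair's taxa — the common "taxa labels within comparison"
  practice;
* `all_taxa`: the union is re-placed across every taxon in the matrix.

Taxa shared by both samples contribute zero in the observed statistic
*and under every shuffle* (a shared taxon remains its own nearest
neighbour wherever it sits), so identical communities have a degenerate
null (sd 0); such pairs are recorded as missing with a warning rather
than forced to a value. Union taxa are processed in sorted order, making
results independent of the row order of the input matrix, and βNTI is
invariant to uniform branch-length scaling, as a z-score must be.

RC_Bray follows the occurrence/abundance null: each null community keeps
the observed richness (taxa drawn without replacement proportional to
occurrence frequency across samples) and the observed total abundance
(one individual per drawn taxon, the rest multinomial by regional
relative abundance); the observed Bray–Curtis is ranked against the null
distribution with ties at half weight and rescaled to [−1, 1].

Classification applies the selection thresholds first (βNTI < −2
homogeneous, > +2 heterogeneous; exactly ±2 counts as stochastic), then
RC (> 0.95 dispersal limitation, < −0.95 homogenizing dispersal,
otherwise undominated). Both null replicate counts default to 999 and
every randomized step takes an explicit seed. Group summaries pool
within-compartment pairs across stages — one number per compartment.

## Co-occurrence networks

Per compartment, the 9 samples are pooled, taxa are prevalence-filtered
(strictly over 50%), and all-pairs Spearman correlations (midrank ties,
p from the t approximation) are thresholded at |ρ| ≥ 0.7 *and* raw
p ≤ 0.01. The coefficient gate is applied to |ρ| so that negative
associations survive as negative edges — the positive/negative link
ratio is part of the topology record. No multiple-testing correction is
applied by default, matching the raw-p edge-deletion convention;
constant taxa (undefined correlations) are excluded with a warning.

Topology conventions, stated because the field's table labels are
ambiguous: nodes are edge-incident vertices only; "clusters" are
connected components; connectedness is the landscape form
1 − components/nodes; average path distance is computed on the largest
component; modularity is the weighted (|ρ|) Q of the detected partition
(greedy modularity by default — deterministic; Louvain behind a seed).

Zi (within-module degree z-score, 0 when the module's spread is zero)
and Pi (participation coefficient 1 − Σ(k_s/k)²) use the canonical
thresholds 2.5/0.62. A geometric consequence worth knowing: a node
touching only two modules has Pi ≤ 0.5, so connectors require links into
at least three modules.

## Beta-regression trends

Phylum relative abundances are modeled as Beta(μφ, (1−μ)φ) with
logit(μ) = β₀ + β₁x, constant precision, maximum likelihood (the
statsmodels BetaModel does the optimization; an independent direct
likelihood maximization cross-checks it in the tests). The gradient is
coded 0/1/2 — spatial uses all 27 samples, temporal fits within each
compartment. Proportions at exactly 0 or 1 are shrunk by
(y(n−1) + 0.5)/n before fitting; a perfectly constant response is the
degenerate φ→∞ limit and is returned as "flat" without fitting.
Direction calls use raw p < 0.05 on the Wald test of β₁. At the
27-sample design with φ = 50 and β₁ = 1 the fitted slope is unbiased to
within 0.01 and 95% Wald intervals cover at ~0.94.

## Functional annotation

The rule engine consumes a line-oriented format compatible with a subset
of the FAPROTAX database semantics: `group:` headers followed by
indented wildcard patterns, `-`-prefixed patterns as exclusions, matched
against the semicolon-joined ranked lineage. A taxon credits its full
abundance to every matching group, so overlapping guilds double-count by
design, and the provenance of every assigned abundance is retained and
verified to re-sum to the table. The full database is not redistributed;
users can point the engine at their own copy.

## The synthetic generator

The generator encodes the study conditions the analyses assume:

* 27 samples (3 × 3 × 3), 300 taxa and 10,000 reads/sample by default;
* lognormal(0, 1.5) regional abundances;
* a birth–death phylogeny (birth 1.0, death 0.5) rescaled to height 1,
  carrying a Brownian niche trait with rate 1 — so tip traits have unit
  variance and environment parameters are in trait-SD units;
* Gaussian environmental filtering exp(−(trait−env)²/2σ²) with widths
  σ = 3.0 / 1.5 / 0.75 and optima 0 / 0.8 / 1.6 for bulk / rhizosphere /
  rhizoplane: filtering strengthens toward the root surface, which
  reproduces the observed diversity ordering (bulk > rhizosphere >
  rhizoplane) and the dominance of the compartment factor over stage;
* an optional per-stage environment drift, default 0 — growth stage is
  deliberately a null factor;
* planted correlated blocks: six taxa sharing one per-sample lognormal
  latent factor (sd 1.0 on the log scale), with a common base abundance
  scaled to ~0.1 of the mean taxon so the block's total share stays
  small. Both choices matter: a weaker factor loses within-block rank
  correlation to multinomial noise, while a larger block share swings
  the compositional denominator and falsely correlates background taxa.

Two frozen regime configurations drive the assembly-recovery studies:
`selection_regime_config` (100 taxa, 3 + 3 samples at optima ±1.5,
σ = 0.25) and `neutral_regime_config` (σ = 10⁹). Selection recovery is
scored on between-environment pairs — the pairs heterogeneous selection
acts on; within-environment pairs under a shared optimum sit near
βNTI ≈ 0–1 because both samples select the same clade and the
union-scope null cannot make the observed βMNTD extreme. Neutral
datasets are scored on all pairs.

What the generator does *not* emulate: sequencing error and chimeras,
compositional bias from PCR, spatial autocorrelation among replicates,
taxon–taxon interactions beyond the planted blocks, and realistic
taxonomy (tests construct synthetic lineages). Passing recovery tests
therefore demonstrates correctness of the estimators under the stated
model, not robustness to those real-data artifacts.

## Validation studies and problem sizes

The acceptance script and test suite run: βMNTD vectorized-vs-naive
equivalence on 50 random 30-taxon instances (agreement to 1e−9);
assembly-regime recovery over 50 generated datasets per regime with 199
nulls; planted-block recovery over 50 generated 27-sample datasets;
PERMANOVA type-I error over 1,000 null simulations at 199 permutations;
beta-regression recovery over 200 replicates; and the exhaustive
classification grid. These sizes keep the full run around two minutes
on one CPU while leaving comfortable statistical margins.

## Numerical details

* Sampling weights are computed on the log scale and max-shifted before
  exponentiation, so extreme filtering never underflows to an all-zero
  weight vector; σ = 0 degenerates to "nearest-optimum taxa only".
* The rarefaction draw is `Generator.multivariate_hypergeometric`,
  giving exact column sums and reproducibility from one integer seed.
* All derived seeds are spawned from `numpy.random.SeedSequence` and
  kept below 2³¹.
* Pipeline runs are byte-reproducible under a fixed config except for
  the wall-clock runtimes echoed in `report.json`.

## Known limitations

* The βNTI pair-union null weakens homogeneous-selection detection for
  highly similar communities (shared taxa are null-invariant); the
  `all_taxa` scope mitigates but does not remove this.
* Spearman p-values use the t approximation, optimistic below ~10
  samples with heavy ties; the 9-sample per-compartment default is near
  that edge, which is one reason the |ρ| gate, not the p gate, is the
  binding filter.
* Greedy modularity on small dense graphs can split differently from
  Louvain; module *counts* are therefore reported alongside component
  counts rather than treated as comparable across methods.
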