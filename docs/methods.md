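# Methods

`mts` analyses paired soil surveys in which each site contributes one
nutrient-poor open-field (OF) sample and one or more nutrient-rich
greenhouse (GH) samples. This note documents the models, the estimators,
the synthetic-data generators used for validation, and the numerical
choices where the design was genuinely open.

## Community trait inference

**rrn copy number (amplicon route).** Each taxon is matched against a
rank-indexed trait reference (rrnDB-style rows of name, rank, value)
starting from the lowest rank and walking upward
(species → genus → … → domain). At each rank a direct entry for the
taxon's name wins; failing that, if the reference contains entries for
taxa that the community taxonomy places *below* that name, their
unweighted arithmetic mean is assigned (provenance `parent_mean`). Taxa
unmatched at every rank receive the global mean of all reference values,
with the fallback logged. The community value per sample is the
relative-abundance-weighted mean Σᵢ pᵢ·tᵢ; abundances are *not*
copy-number-corrected before weighting, to avoid circularity. The
starting rank is configurable because species-level amplicon names are
often unreliable.

**Genome count, AGS and ACN (metagenome route).** The number of genomes
in a metagenome is estimated as the arithmetic mean coverage of 35
universal single-copy marker genes (marker identities are
configuration-supplied labels; zero-coverage markers are retained in the
mean, with a warning). Average genome size (AGS) is total assembled base
pairs divided by the genome count. 16S coverage is annotated 16S base
pairs divided by the reference 16S gene length (default 1,550 bp,
configurable); average 16S copy number (ACN) is 16S coverage divided by
the genome count. Both estimators are scale-invariant: multiplying every
coverage and total_bp by a constant leaves them unchanged.

**Growth rate from codon usage.** Per-gene codon usage bias uses the
MILC statistic: for each amino acid *a* with synonymous codons *c*,
Mₐ = 2 Σ_c o_c ln(f_c / e_c) with o observed counts, f within-family
observed frequencies and e background frequencies (pooled over all genes
in the set); the gene statistic is (Σₐ Mₐ)/L − C with the length
correction C = Σₐ(rₐ − 1)/L over amino acids present. Stop codons and
ambiguous triplets are ignored; genes under 80 usable codons are flagged
and genes with none are excluded. The community statistic is the
coverage-weighted mean MILC over highly expressed (ribosomal-protein)
genes. Minimum generation time is mapped as d = exp(b0 + b1·CUB) with
b1 < 0 and maximum growth rate μmax = 1/d. The default calibration
(b0 = 1.5, b1 = −3) is illustrative — replace it with published
calibration constants when absolute rates matter; every in-package use
relies only on the map's strict monotonicity.

**Life-history classification.** Phylum-level copiotroph/oligotroph
(r/K) lists default to {Proteobacteria, Firmicutes, Bacteroidota} vs
{Chloroflexi, Acidobacteriota, Nitrospirota}; unlisted phyla are
`unclassified`. Overlapping lists are rejected.

## Assembly null models

**βMNTD / βNTI.** The abundance-weighted β-mean-nearest-taxon distance
between samples k and m is
½[Σᵢ p_ik·min_{j∈m} d(i,j) + Σⱼ p_jm·min_{i∈k} d(j,i)], minima over taxa
present (p > 0) in the other sample; shared taxa contribute zero. The
null shuffles taxon labels across all tree tips (999 replicates by
default) and βNTI is the z-score of the observed βMNTD. |βNTI| < 2 is
read as stochastic assembly. Pairs whose null has zero spread are
reported NA with a warning. The randomization scheme and replicate count
are configuration with these documented defaults. An optional five-way
partition (heterogeneous/homogeneous selection at βNTI ±2, dispersal
limitation / homogenizing dispersal at Raup-Crick ±0.95, drift
otherwise) is available.

**Raup-Crick (Bray-Curtis).** Null communities preserve each sample's
richness (taxa drawn with probability proportional to regional
occupancy) and total abundance (filled proportionally to regional mean
relative abundance, discretized to a configurable community size,
default 1,000 individuals). RC = 2·[(#null < obs) + ½(#null = obs)]/n_null − 1.
The pair order is canonicalized internally so the index is exactly
exchangeable.

**Sloan neutral community model.** Taxon occurrence frequency is
modelled as 1 − BetaCDF(d; N·m·p̄, N·m·(1 − p̄)) with detection limit
d = 1/N; the migration rate m is fitted by bounded nonlinear least
squares on the frequency scale, R² = 1 − SSE/SST, and the 95% envelope
uses Wilson score intervals. N defaults to configuration (1,000) since
read depths are not always available.

**Distance decay and PERMANOVA.** Similarity (1 − Bray-Curtis) is
regressed on great-circle distance (haversine, R = 6371 km) or on
Euclidean distance over z-scored soil variables. Slope differences
between groups are tested by pooling the pairwise points and permuting
group labels over points, p = [1 + #(|Δ|perm ≥ |Δ|obs)]/(n_perm + 1).
One-way PERMANOVA computes the pseudo-F from among/within sums of
squared distances with a seeded label-permutation p-value. All
permutation p-values use the add-one convention and can never be zero.

## Paired contrasts

Shannon diversity is computed in nats (configurable base); tables are
analysed as relative abundances with no rarefaction. The paired
log-ratio delta = log10(X_GH/X_OF) is computed per GH sample against its
site's OF sample (a site with several GH samples contributes several
pairs); delta-NPK averages the NH4, NO3, AP and AK deltas. Base 10 is
used throughout (a `base` switch exists); pairs with a zero member are
dropped with a logged count rather than pseudocounted. Group tests use
the two-sided Wilcoxon rank-sum test — exact enumeration when both
groups have ≤ 20 tie-free observations, otherwise the tie- and
continuity-corrected normal approximation — with Benjamini-Hochberg
correction across variables. Volcano enrichment requires
|log2 fold change| > 1 of group means and BH q < 0.05.

## PLS path model

Composite latents are estimated by the Lohmöller iteration: outer
proxies from weights, inner proxies by the centroid scheme (factor and
path schemes available), mode-A weight updates (mode B available),
iterated until the maximum weight change falls below 1e-6. Each latent
is oriented to correlate positively with its first indicator. Structural
paths are estimated from the latent correlation matrix by OLS.

Raw composite scores attenuate structural paths (a true standardized
path of 0.6 between latents measured by three 0.9-loading indicators is
estimated near 0.56). By default the inter-composite correlations are
therefore disattenuated by Dijkstra's ρ_A composite reliabilities before
path estimation, which removes this bias; `consistent=False` restores
the classic attenuated composites. Single-indicator blocks are treated
as error-free. Inference is by row-resampling bootstrap with percentile
intervals; p-values invert the interval with add-one smoothing, and the
first-indicator sign convention keeps replicates aligned. Missing rows
are deleted listwise with a logged count.

The end-to-end pipeline's delta-scale path model uses the classic
(attenuated) composites: its blocks are dominated by single indicators
and n is the site-pair count, too small for stable reliability
estimation.

## Synthetic-data generators

The generators define the study conditions under which the pipeline is
validated; every generator is a pure function of its parameters and
seed, and ground truth is emitted alongside the data.

**Paired survey.** Default 20 sites × 120 taxa, one OF and one GH sample
per site, 5,000 reads per sample (finite depth keeps tables sparse, as
real amplicon tables are). GH nutrient concentrations are drawn with the
fold increases observed in intensive greenhouse systems (NH4 ×1.88,
NO3 ×7.8, AP ×3.1, AK ×2.3, EC ×2.4; pH and organic matter unshifted).
A fraction (default 0.3) of taxa are copiotrophs whose expected
log-abundance is shifted by θ × delta-NPK (θ = 2 by default; θ = 0 gives
an exact null). Base log-abundances are normal with a wider spread for
copiotrophs (sd 1.8 vs 1.0): nutrient-driven copiotroph blooms are
dominated by a few taxa, so shifting community mass toward them lowers
evenness — without this dominance structure, boosting a random taxon
subset can raise rather than lower Shannon diversity. Compositions are
Dirichlet around the expected proportions (concentration = dispersion ×
expectation, default 300), then multinomially sampled at the read depth. Trait coupling assigns
copiotrophs high rrn (around 6, within the 2.5–9.7 range reported for
copiotrophic phyla), small genomes (≈4 Mb vs ≈6 Mb) and short doubling
times (≈1 h vs ≈8 h); a coupling parameter in [0, 1] relaxes this toward
uncoupled traits. The trait reference covers 70% of genera directly plus
all phyla, so hierarchical imputation exercises direct, parent-mean and
global fallback paths.

**Metagenome summaries.** Marker coverages scatter multiplicatively
(lognormal, default σ = 5%) around the summed genome coverage; 16S base
pairs and total base pairs receive per-genome multiplicative noise (the
per-gene coverage scatter of real assemblies), so the estimators'
errors shrink with the number of genomes. True AGS and ACN are the
coverage-weighted means.

**Coding sequences.** Background genes draw codons from a fixed,
mildly uneven within-family frequency table; highly expressed genes draw
from the mixture (1 − b)·background + b·preferred-codon. b = 0 makes the
two distributions identical; community CUB is strictly increasing in b.

**Assembly scenarios.** *Neutral*: per-taxon relative abundances from
the stationary Sloan approximation Beta(N·m·p̄, N·m·(1 − p̄)), then
binomial sampling at community size N — no phylogenetic structure, so
βNTI stays within ±2 and the NCM fit recovers m. *Selection*: a Brownian
trait on the tree defines two environmental optima (the 10% and 90%
trait quantiles); samples alternate between them and taxa are weighted
by a Gaussian filter (width 0.1) around the sample's optimum, with
meta-community dominance tempered (p̄^0.3) so the phylogenetic filter,
not a few hyper-abundant taxa, shapes the communities. Pairs across
optima occupy divergent clades and push |βNTI| well beyond 2.

**What the generators do not emulate.** Sequencing error, chimeras,
compositional bias of extraction/PCR, spatial autocorrelation of sites
beyond random coordinates, and real taxonomies' uneven rank coverage.
Passing tests therefore demonstrate correctness of the estimators and
calibration of the null models under idealized sampling, not robustness
to those artefacts.

## Problem sizes and numerical choices

Validation uses desk-scale sizes chosen once: oracle equivalence on
hundreds of instances of ≤ 10 taxa; trait recovery on 200 replicates of
20-genome mixtures; null calibration with 999 tip shuffles on 15-sample,
100-taxon communities; NCM recovery on 20 replicates of 50 samples × 300
taxa; rank-test calibration on 1,000 replicates of 100-feature null
tables; path-model recovery on 20 replicates of n = 500 with 299
bootstrap resamples. Path recovery is assessed on the mean estimate
across replicates (the sampling standard deviation of a single
standardized path at n = 500 is ≈ 0.04, so no consistent estimator can
bound every individual replicate by ±0.07). The full pipeline defaults
(999 nulls/permutations, 199 bootstrap resamples) complete in well under
a minute on one CPU at the default survey size.

Ties in permutation tests count as exceedances (conservative); Wilson
intervals avoid the degenerate normal intervals at frequencies near 0
or 1; Dirichlet concentrations are floored at 1e-6 to avoid numerical
zeros; the imputation walk is a total function (global-mean fallback)
so downstream weighting never meets a missing trait.

## Known limitations

- The growth calibration constants are placeholders; absolute μmax
  values are not comparable to culture-based measurements.
- The Raup-Crick null discretizes relative abundances to a configurable
  community size; results at very small sizes are grainy.
- PLS disattenuation assumes loadings proportional to weights within a
  block (mode-A consistency); grossly heterogeneous blocks violate it.
- The five-way assembly partition is reported but not validated against
  an external implementation.
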