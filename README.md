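# mts — microbial trait surveys

`mts` is a Python toolkit for analysing paired soil microbiome surveys in
which each site contributes a nutrient-poor open-field (OF) sample and a
nutrient-rich greenhouse (GH) sample. It asks the questions soil
microbial ecologists ask of such designs: does nutrient enrichment shift
communities from oligotrophic (K-selected) toward copiotrophic
(r-selected) life-history strategies, what happens to diversity and
functional potential, and is community assembly deterministic or
stochastic?

The toolkit covers, end to end:

- **Community trait inference** — per-taxon *rrn* operon copy numbers
  imputed hierarchically from a rank-indexed reference and averaged per
  sample weighted by relative abundance (Σᵢ pᵢ·tᵢ); average genome size
  (AGS = total bp / genome count, with the genome count from the mean
  coverage of 35 single-copy marker genes), average 16S copy number
  (ACN = 16S coverage / genome count), and maximum growth rate from the
  MILC codon-usage bias of highly expressed ribosomal-protein genes via
  d = exp(b0 + b1·CUB), μmax = 1/d.
- **Assembly null models** — abundance-weighted βMNTD with a
  tip-shuffling null (βNTI; |βNTI| < 2 read as stochastic assembly),
  abundance-based Raup-Crick on Bray-Curtis, and the Sloan neutral
  community model (occurrence frequency ≈ 1 − BetaCDF(d; Nmp̄, Nm(1−p̄))).
- **Biogeography and contrasts** — distance-decay regressions
  (geographic and edaphic) with a permutation slope-difference test,
  one-way PERMANOVA, Shannon diversity, paired log-ratio deltas
  (delta = log10(X_GH/X_OF), delta-NPK averaged over NH4/NO3/AP/AK),
  Wilcoxon rank-sum tests with Benjamini-Hochberg control, and volcano
  enrichment (|log2 FC| > 1, q < 0.05).
- **PLS path modeling** — composite latent variables (soil nutrients,
  functional potential, growth-rate potential, plant-beneficial
  features) fitted by the Lohmöller algorithm with consistent
  (disattenuated) path estimation and bootstrap inference.
- **Synthetic surveys with known ground truth** — generators for paired
  OF/GH surveys, metagenome coverage summaries, codon-biased gene sets
  and neutral/selection assembly scenarios, so every estimator is
  validated against truth without any downloads.

See `docs/methods.md` for the models, defaults, and their rationale.

## Worked example

Run the default synthetic paired survey (20 sites, 120 taxa, positive
nutrient-copiotroph coupling) through the full pipeline:

```bash
mts run --config run.yaml
```

with `run.yaml`:

```yaml
seed: 1
outdir: report
```

or equivalently from Python:

```python
from mts.pipeline import RunConfig, run_pipeline
outdir = run_pipeline(RunConfig(seed=1, outdir="report"))
```

The report directory contains per-stage TSV/JSON outputs plus
`summary.json`. With seed 1 the trait stage reports (percent difference
of the GH group mean versus OF, with BH-adjusted Wilcoxon q):

```
variable                 percent_difference   q          direction
shannon                  -10.03               1.7e-11    OF
community_rrn            +22.04               1.7e-11    GH
ags_bp                   -6.89                1.7e-11    OF
max_growth_rate_per_h    +26.49               1.7e-11    GH
copiotroph_abundance     +37.12               1.7e-11    GH
```

i.e. the nutrient-rich samples host more copiotrophs with more rRNA
operons, faster predicted growth and smaller genomes, at the cost of
taxonomic diversity — the classic life-history trade-off under nutrient
enrichment. The assembly stage reports the stochastic fraction of sample
pairs (|βNTI| < 2 for 94.9% of pairs here: the random phylogeny carries
no trait signal, so assembly looks neutral), Sloan-model fits per system
(R² ≈ 0.95, m ≈ 0.26-0.28), distance-decay slopes with a permutation
p-value for their difference, and a PERMANOVA of community composition
by system (p = 0.001). The PLS stage reports path coefficients of the
delta-scale model — nutrients→growth +0.68, nutrients→function −0.65,
growth→beneficial +0.94 — with bootstrap intervals.

Individual analyses are importable directly — e.g.
`mts.traits.impute_trait`, `mts.assembly.beta_nti`,
`mts.contrasts.delta_table`, `mts.plssem.fit_plspm` — and exposed as
`mts simulate|traits|assembly|contrast` subcommands.

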