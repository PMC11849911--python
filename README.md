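# dielwl

Analysis toolkit for **diel (time-of-day) responses of an allopolyploid crop
to prolonged water limitation**, built around the kind of experiment run on
*Brassica napus*: accessions grown under well-watered (WW) and water-limited
(WL) regimes, phenotyped daily for plant area, sampled for RNA every 6 h over
one day (ZT 1, 7, 13, 19; three replicates), and assayed for targeted
metabolites (glucosinolates and related sulfur compounds) at ZT 4, 12, 20.

It is aimed at plant scientists who want a tested, scriptable version of the
full statistical chain — from growth curves to homoeolog-resolved expression
divergence to metabolite time courses — with synthetic data generators that
carry known ground truth for every stage.

## What it computes

**Bayesian Gompertz growth model** (`dielwl.growth`). Plant area follows

    y_it ~ Student-t(nu, mu(t), sigma(t))
    mu(t)    = A * exp(-exp(-C * (t - B)))
    sigma(t) = subA / (1 + exp(-subC * (t - subB)))

with per-group (accession x treatment) parameters, median-parameterized
lognormal priors (A, B, C centered at 130 cm², 15 d, 0.25 d⁻¹; subA, subB,
subC at 20, 10, 3; scale 0.25 on the log axis) and a Gamma(2, 0.1) prior on
`nu` truncated at 1. Posterior hypotheses compare WW vs WL margins, e.g.
P[(A_WW − A_WL)/A_WL > 0.5].

**Differential diel patterning** (`dielwl.diel`). Per gene, a *kME* score
(change in correlation with a basis of eigengene profiles — pattern change)
and a *Med* score (change in median expression — level change), called
against an empirical-FDR null from permuting treatment labels of whole
replicate time courses. Includes the zero-variance / low-expression filters,
TMM library-size normalization and median-of-two missing-replicate
imputation.

**Phase and subgenome divergence** (`dielwl.phase`). Phase = ZT of peak
replicate-mean expression; WW→WL phase changes fall into five circular
groups {−12, −6, 0, +6, +12} h (positive = WL peaks earlier). Summaries by
BnA/BnC subgenome: phase-group proportions, expression bias, gene- vs
ortholog-level sharing across accessions, responsive-homoeolog profiles.

**Response-score modules** (`dielwl.modules`). Response score = WL − WW
replicate-mean log2 difference per gene, accession and ZT; a signed weighted
co-expression network over the concatenated accession x ZT vectors yields
global response modules with sign-oriented eigengenes, including splitting
of modules where accessions respond in opposite directions.

**Enrichment** (`dielwl.enrich`). One-sided hypergeometric (= Fisher exact)
term over-representation with BH adjustment, Arabidopsis-ortholog mapping
and broad-descriptor rollups.

**Targeted metabolomics** (`dielwl.metab`). LOD/LOQ censoring (2x / 5x
background peak height, with absolute overrides), representative-region-sum
normalization across injections, and two-way time-of-day x treatment models
with Holm-adjusted pairwise ZT contrasts.

**Synthetic data** (`dielwl.synthetic`). Generators for all three data
kinds plus archetypal response-score matrices, each returning a truth
record listing every planted effect, dropout and scale factor.

## Worked example

```python
from dielwl.synthetic import GrowthSimDesign, gen_growth_data
from dielwl.growth import fit_growth_model, hypothesis_table

design = GrowthSimDesign(seed=3)          # 16 plants/group, days 0-26
table, truth = gen_growth_data(design)    # WW: A=130, WL: A=65
post = fit_growth_model(table, seed=3)
print(hypothesis_table(post).round(3).to_string(index=False))
```

```
  hypothesis parameter  margin  posterior_probability  effect_size_pct  supported
asymptote_50         A    0.50                    1.0          105.681       True
inflection_5         B    0.05                    1.0            7.334       True
      rate_5         C    0.05                    0.0           -0.170      False
```

The asymptote hypothesis is supported (the WW asymptote is estimated ~106%
larger than WL, true value 100%), the inflection-point hypothesis is
supported (WW inflection ~7% later), and the growth-rate hypothesis is not
(both groups were generated with C = 0.25): water limitation restricts
final size rather than slowing the growth rate. `post.summary()` gives
per-parameter medians, 95% intervals, split-Rhat and effective sample
sizes.

The same chain is scriptable from the shell:

```bash
dielwl simulate --kind expression --seed 1 --out out/
dielwl dipattern --expr out/expression.tsv --meta out/expression_meta.tsv \
    --nperm 100 --fdr 0.05 --seed 1 --out out/
dielwl pipeline --seed 1 --out out/full_run   # end-to-end synthetic run
```

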