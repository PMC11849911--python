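# Methods

This note documents the models, estimators and defaults implemented in
`dielwl`, the choices made where the design was genuinely open, and what
the synthetic benchmarks do and do not demonstrate.

## Growth model

Plant area (cm²) over time t (days after treatment start) is modelled per
accession x treatment group as

    y_it ~ Student-t(nu, mu_g(t), sigma_g(t))
    mu_g(t)    = A_g exp(-exp(-C_g (t - B_g)))
    sigma_g(t) = subA_g / (1 + exp(-subC_g (t - subB_g)))

This is a *distributional* regression: the noise scale has its own logistic
time profile, capturing the fact that the spread of plant sizes grows as
the plants do, and the Student-t likelihood (shared `nu` across the groups
of one fit) absorbs occasional segmentation outliers. In this Gompertz
parameterization `B` is literally the inflection time in days (the curve
passes through `A/e` at `t = B`) and `C` is the growth rate in day⁻¹.

All plants of a group are pooled with shared group parameters; there are no
plant-level random effects. This matches the reporting unit (one parameter
set per accession x treatment) and keeps the posterior dimension at
6 x groups + 1.

**Priors.** Median-parameterized lognormals, LogNormal(log m, 0.25), with
medians m = 130 (A, cm²), 15 (B, d), 0.25 (C, d⁻¹), 20 (subA, cm²),
10 (subB, d), 3 (subC, d⁻¹); `nu ~ Gamma(shape 2, rate 0.1)` truncated at
1 (prior mean 20, gently favouring near-normal tails). The 0.25 log-scale
keeps the priors thick enough for the data to dominate. `prior_only=True`
returns iid draws from these priors — the exact no-data posterior — for
prior-predictive checking.

**Sampling.** The log-posterior on log-parameters is maximized (L-BFGS)
from the prior centers; the inverse negative Hessian at the mode (finite
differences) seeds the proposal geometry. The default sampler is an
affine-invariant ensemble (emcee) with differential-evolution moves,
at least 32 walkers initialized from that Laplace approximation, with
warmup steps discarded and kept steps retained per walker; walkers serve
as the diagnostic chains. This choice is driven by the posterior geometry:
with the logistic variance profile the noise scale is essentially zero at
early days, so early observations pin curve-parameter combinations to many
significant digits, producing extremely anisotropic, curved ridges
(condition numbers ~1e10) that defeat plain random-walk Metropolis. An
adaptive Metropolis-within-Gibbs sampler (`sampler="metropolis"`) is
retained for reference.

**Diagnostics.** Rank-normalized split-Rhat and effective sample size
(ArviZ) per parameter, computed across walker-chains. A fit with any Rhat
above 1.05 is automatically retried with doubled warmup (up to twice) and
otherwise flagged `converged=False` with a warning — never silently
accepted. With low-noise data the variance sub-model is only weakly
identified (any large-`subA`, late-`subB` combination that keeps
`sigma` small over the observed range fits equally well); the curve
parameters A, B, C remain well determined in this regime.

**Hypotheses.** For parameter θ ∈ {A, B, C}, the posterior probability of
`(θ_WW − θ_WL)/θ_WL > margin` is the fraction of paired draws exceeding the
margin (margins 0.50 for A, 0.05 for B and C); the effect size is the
posterior median of the percent difference; "supported" requires
probability ≥ 0.95 (a declared convention — the support threshold is
configurable). Posterior predictive ribbons are simulated observation
quantiles at parameters resampled from the posterior.

## Differential diel patterning

Expression enters as log2 normalized values on the fixed grid
ZT {1, 7, 13, 19} x replicates {1, 2, 3} per accession and treatment.
Preprocessing: (i) genes with zero variance across all samples are removed,
then genes are kept only if their replicate-mean log2 expression exceeds 0
at ≥ 1 ZT in either treatment; (ii) TMM scale factors (doubly trimmed
precision-weighted mean of M values against an upper-quartile reference,
rescaled to geometric mean 1) convert raw counts to CPM- or FPKM-like
log2 values when counts are supplied; (iii) a single missing replicate at a
gene x ZT is imputed as the median of the two observed values; genes with
two or more missing replicates at any ZT are excluded for that accession
(the median-of-two rule does not extend to them).

**Eigengene basis.** Each gene contributes its z-scored replicate-mean
4-point profile from each treatment; profiles are clustered by average
linkage on the signed-correlation dissimilarity (1 − r)/2 and cut at 0.3,
and each cluster of at least 20 profiles is summarized by the sign-oriented
first singular vector. The cut of 0.3 (within-cluster correlation ≳ 0.4)
matters: a coarser cut can fuse the shape families into a nearly collinear
pair of antiphase eigengenes, and a basis that does not span the
(3-dimensional) space of z-scored 4-point profiles is blind to pattern
changes in the orthogonal phases. Eigengene extraction deliberately skips
column centering — the members are already z-scored per profile and the
shared shape is the signal to retain.

**Scores.** For gene g with eigengene basis {E_m}:

    kME(g) = Σ_m | mean_r cor(z(g_WL,r), E_m) − mean_r cor(z(g_WW,r), E_m) |
    Med(g) = | median(g_WL samples) − median(g_WW samples) |

kME averages *per-replicate* correlations rather than correlating the
replicate-mean profile. The distinction is invisible on clean data (both
give 2 per eigengene for a noiseless antiphase flip and ~0 for a pure
median shift) but decisive for the permutation test: z-scoring makes a
replicate-mean profile amplitude-invariant, so a mixed pseudo-group of
antiphase courses (mean ∝ ±cos/3) z-scores back to the full pattern and a
balanced pattern change would survive label permutation almost undamaged,
leaving the empirical FDR with a floor near the planted fraction. Averaging
per-replicate correlations lets opposite-sign members cancel in mixed
pseudo-groups, restoring the null. The replicate-mean variant remains
available (`profile="replicate_mean"`).

**Permutation null.** The six replicate time courses are reassigned to two
pseudo-treatments of three, the same assignment for all genes of an
accession (preserving gene-gene and within-series correlation). The
identity assignment and its complement are excluded — they reproduce the
observed labelling and carry no null information. With C(6,3) = 20
assignments this leaves 18, sampled with replacement `n_perm` times
(default 100). The empirical FDR at score threshold s is
(mean null exceedances per permutation) / (observed exceedances), made
monotone from the smallest scores upward (a q-value); genes are called at
q ≤ 0.05 by default. Flat-profile genes have their correlations defined as
0 and are flagged, never called by kME.

**Validation and QC.** Welch two-sample tests per gene x ZT with BH
adjustment across genes within each ZT provide a single-timepoint
cross-check (Jaccard overlap reported against the permutation calls).
Accessions with fewer than 50 kME calls (configurable) are dropped from
cross-accession analyses, mirroring the practice of excluding
uninformative accessions.

## Phase analysis

Phase is the ZT of maximum replicate-mean expression; ties break toward the
earliest ZT (deterministic; ties have measure zero under continuous noise)
and all-flat profiles are excluded. With 6-hourly sampling the WW→WL phase
difference d = phase_WW − phase_WL is a multiple of 6; wrapping ±18 → ∓6
yields exactly five classes {−12, −6, 0, +6, +12}, where the two half-cycle
classes are circularly identical and distinguished only by the sign of the
raw difference. Sign convention: **positive = WL peaks earlier**; a
`flip_sign` flag serves the opposite reporting convention, since published
descriptions use both. Brute-force enumeration of the 16 ordered phase
pairs gives class counts {0: 4, +6: 4, −6: 4, +12: 2, −12: 2}, which the
test suite checks against an independent minimal-circular-displacement
oracle.

Subgenome summaries treat the homoeolog map (gene → BnA/BnC, ortholog
group, optional Arabidopsis ortholog) as authoritative: phase-group
proportions are normalized within accession (and within accession x
subgenome), expression bias is reported as the BnC − BnA mean log2
difference with a percentile bootstrap over genes, and sharing histograms
are computed at gene level and at ortholog level (an ortholog group's
accession set is the union over member genes, so ortholog-level sharing
always dominates).

## Response-score modules

The response score is the WL − WW replicate-mean log2 difference per gene,
accession and ZT. Each gene's feature vector concatenates its scores over
all accessions x ZTs and is z-scored, realizing a *global* network in which
a module is a temporal response pattern shared across the panel. Signed
adjacency a = ((1 + r)/2)^β with β = 6 (the standard signed soft-threshold
power); dissimilarity 1 − a; average-linkage clustering with a static cut
at 0.6. The cut height sits between the dissimilarity of strongly
co-responding genes (r ≈ 0.9 → 1 − 0.95⁶ ≈ 0.27) and of unrelated genes
(r ≈ 0 → ≈ 0.98); a cut at the conventional eigengene-merge level of 0.25
would fall *below* the within-module dissimilarity and shatter true
modules, so 0.25 is used where it belongs — as the merge level: modules
whose eigengenes correlate ≥ 0.75 are fused. Clusters under 30 genes fall
to the null module M0; labels are assigned by decreasing size.
Topological-overlap smoothing is omitted: at desk scale the correlation
dissimilarity is sufficient and exactly testable.

Module eigengenes are sign-oriented first singular vectors of the z-scored
member matrix, reshaped to accession x ZT. When any pair of per-accession
mean profiles correlates below −0.5 the module mixes opposing responders;
accessions are then partitioned by the sign of their projection onto the
leading principal direction of the accession-profile matrix (a shared
4-point reference shape — projecting onto each accession's own eigengene
segment would not work, being positively aligned by construction), and one
sub-module per sign is emitted with the same gene set.

## Enrichment

One-sided hypergeometric upper-tail p per term (identical to a one-sided
Fisher exact test, verified against it to 1e−12 in tests), BH adjustment
across the terms of one analysis, BH FDR 0.05 as the default significance
level. Annotations are plain (term, gene) tables; counting defaults to
gene ids with ortholog-level counting via `map_to_orthologs`
(de-duplicating homoeologs to one Arabidopsis id). Broad-descriptor
rollups group terms under parent-like labels and preserve accession/module
identifiers, giving the descriptor x (accession, module) presence shape
used for cross-accession comparison. No ontology-graph propagation is
performed.

## Metabolomics

Censoring uses peak height: below LOD → not detected (ND); [LOD, LOQ) →
detected but not quantifiable ("<LOQ"); ≥ LOQ → quantified, boundaries
inclusive at the upper category. The primary rule is multiplier-based
(LOD = 2x background, LOQ = 5x background) with per-analysis absolute
overrides, because published absolute limits (1.0E4 / 5.0E4 peak height)
are mutually inconsistent with a single background level under the 2x/5x
multipliers — they imply backgrounds of 5e3 and 1e4 respectively — so both
entry points are supported and tested.

Run normalization divides each sample's abundances by the summed abundance
of a representative retention-time x m/z region of that run and rescales by
the grand-mean region sum. The post-condition — every sample's region sum
equals the grand mean exactly afterwards — holds by construction and is
asserted in tests, as is idempotence. Technical injections are averaged
within biological samples after normalization, before modelling.

Per feature, effects are tested on log peak area of quantified values with
a two-way fixed-effects model `log(area) ~ treatment * ZT` (type-II F
tests for the ZT main effect, treatment effect and interaction), plus
Welch pairwise ZT contrasts within treatment, Holm-adjusted. Cells without
two quantified replicates mark the feature *partial* and their contrasts
are skipped; all-equal responses are flagged *degenerate* rather than
returning spurious p-values.

## Synthetic data

The generators emulate the study conditions downstream stages assume, with
one RNG stream per dataset kind spawned from the top-level seed, and emit a
truth record for every random choice.

* **Growth**: 16 plants per group observed daily over days 0–26; Gompertz
  means (WW: A=130, B=15, C=0.25; WL: A=65, B=14, C=0.25), logistic noise
  sd (20, 10, 3) in both groups, Student-t noise with 10 degrees of
  freedom. These equal the fitting priors' centers by design — the priors
  were chosen (upstream) to match this crop's phenotyping scale.
* **Expression**: ortholog groups with 1–3 copies per subgenome
  (probabilities 0.6/0.3/0.1), baseline 4.0 log2 units (gene-level sd 1),
  cosinor amplitude 1.0 with phases on the ZT grid, BnC/BnA expression
  ratio 1.1, Gaussian noise sd 0.2 on the log2 scale, WL responses planted
  in a random 10% of ortholog groups per accession as phase shifts from
  {±6, ±12} h (positive = WL earlier) or ±1.0 log2 median shifts, applied
  to a random non-empty homoeolog subset; optional replicate dropout
  removes at most one of three replicates per gene x ZT. Additive Gaussian
  noise on log2 is a modelling choice (the real noise family of normalized
  expression is not knowable from summaries); the z-scored downstream
  statistics are insensitive to it.
* **Metabolites**: features at ZT {4, 12, 20} x 2 treatments x 5
  biological replicates x 3 injections, log-normal abundances (bio sd 0.3),
  per-injection lognormal scale factors (sd 0.2), planted effects (none /
  ZT trend of 1.0 log unit / WL-at-ZT20 interaction of 1.0 log unit), a
  10% tranche parked below the detection limit, and a block of 20 stable
  "region" features (sd 0.01, emulating a sum over many background ions)
  anchoring the normalization.
* **Response archetypes**: orthonormalized random temporal archetypes over
  accession x ZT coordinates; member genes are archetype + noise scaled so
  the expected within-archetype correlation is 0.9 (the between-archetype
  correlation is ~0 by construction).

What passing these benchmarks does *not* show: the generators have no
read-level sampling noise, no gene-length or GC effects, no
correlation between genes beyond planted patterns, no batch structure in
expression, and clean on-grid phases — real-data performance (alignment
artifacts, partial phase shifts, correlated nulls) is outside their scope.
The permutation caller's calibration in particular is demonstrated under an
exchangeable null, which real replicate structure only approximates.

## Problem sizes and numerics

Benchmarks run at desk scale: growth fits use 16 plants/group (recovery
and hypothesis checks; calibration replicates use 8 plants at reduced draw
counts), expression benchmarks ~2,000 genes with 100 permutations, module
recovery 2,200 genes. Ensemble fits default to 1000 warmup + 1000 kept
steps over ≥ 32 walkers. Correlations are clipped to [−1, 1] before
dissimilarities; flat profiles z-score to zero vectors and are flagged;
proposal covariances receive a 1e−9–1e−14 diagonal guard; the Laplace seed
covariance clips eigenvalues at 1e−12 of the largest (positive
definiteness without flattening the geometry). Ties in phase estimation
break toward the earliest ZT; module labels order by size; all stochastic
stages take explicit seeds and are bit-reproducible.

## Known limitations

* The growth sampler's walker-level split-Rhat is conservative for
  ensemble moves; occasional fits stabilize near Rhat ≈ 1.06 with accurate
  medians and are reported flagged rather than hidden.
* The variance sub-model is unidentified beyond the observed time range
  when residual noise is very small; only A, B, C should be interpreted in
  that regime.
* kME depends on the eigengene basis; a basis from pathological data (all
  genes one shape) reduces sensitivity to orthogonal pattern changes.
* Enrichment treats annotation sets as flat (no true-path propagation).
* The five-group phase classifier is tied to the 6-h sampling grid; finer
  phase resolution requires a different (cosinor-type) estimator and is out
  of scope.
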