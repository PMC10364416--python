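# Methods

This note records the scientific and numerical choices behind `epilink`:
what the reconstruction pipeline assumes, what each tunable means, what the
synthetic-data generator does and does not emulate, and where the design
was genuinely open.

## 1. The reconstruction pipeline

The pipeline infers, per cell/tissue state, which enhancers regulate which
promoters using only CAGE activity (TPM = reads coverage per million mapped
reads over the element). It rests on two empirical premises: a true
enhancer's activity correlates positively with its target promoter's
activity across samples, and a promoter integrates input from several
enhancers in its genomic neighbourhood. The five steps and their tunables:

| step | operation | parameter (default) |
|------|-----------|---------------------|
| 1 | candidate enumeration | window 1 Mb around the TSS (midpoint-to-TSS distance) |
| 1 | joint LASSO, keep β > 0 | 5-fold CV penalty, z-scored activities, ≥ 8 samples |
| 2 | trans-null correlation filter | n_null = 10,000, empirical FDR = 0.05 |
| 3 | usage calls | TPM strictly > 1 |
| 4 | ABC score | γ = 1.0, d0 = 5,000 bp, B_p = 0 |
| 5 | replicate aggregation | union of active pairs, max ABC per edge |

Distances use the enhancer midpoint and the TSS; coordinates are 0-based
half-open throughout. Promoter windows are a strand-agnostic TSS ± 500 bp;
genes on chrY/chrM are excluded at parse time. Ties in orderings are broken
by (gene_id, enhancer_id) so every run is reproducible.

**LASSO details.** Activities are z-scored per element across samples
before the fit and coefficients are read on that standardized scale; the
penalty is chosen by seeded 5-fold cross-validation over scikit-learn's
default alpha grid. A zero-variance promoter yields an empty retained set
(logged, not an error). With ~20 samples and ~50 correlated candidates the
fit is in the p ≳ n regime: collinear co-active enhancers compete for the
same coefficient, which caps recall of true links at roughly 80–85% in the
synthetic world below. This is a property of L1 selection, not a bug.

**Step-2 threshold.** For each promoter the null is the Spearman
correlation against 10,000 enhancers drawn from the other chromosomes
(without replacement when the pool allows, else with replacement and a
warning); the threshold is the empirical 95% quantile with linear
interpolation between order statistics, and retention requires strictly
greater correlation. A ratio-style empirical FDR (smallest observed
threshold t with `frac(null > t)/frac(observed > t) ≤ FDR`) is available
via `fdr_mode="ratio"`.

*Calibration caveat.* The filter is calibrated **marginally**: for pairs
exchangeable with the trans null (independent activities), the probability
of passing is the configured FDR — we verify 0.050–0.051 empirically on a
no-signal dataset and on Gaussian pairs. Conditioned on having survived
step 1 the pass rate is necessarily higher (LASSO selects chance-correlated
candidates; measured ≈ 20% on no-signal data). Any calibration statement
about step 2 must therefore be read before the step-1 conditioning.

**ABC adaptation.** With only CAGE inputs, Activity is the geometric mean
`sqrt(A_e · A_p)` of the two TPM values and Contact is a power-law decay
`C(d) = (d + d0)^-γ`. The promoter background term B_p enters the
denominator only; with B_p > 0 the enhancer shares and the background share
sum exactly to 1, with B_p = 0 (default) the enhancer shares alone sum to
1. Scores are per promoter per sample; aggregation across a state's
replicates keeps the maximum.

## 2. The synthetic world

The generator produces the statistical structure the pipeline assumes, with
planted ground truth for every claim a test makes. Defaults (SynthConfig):

- **Geometry.** 4 chromosomes × 10 Mb, 1,000 enhancers (400 bp) and 200
  promoters placed uniformly — about 21 enhancers per Mb and ~47 candidate
  enhancers per promoter window, matching the density of genome-wide
  CAGE enhancer atlases (~63k enhancers over ~3 Gb).
- **States and usage.** 10 states × 2 replicates. Each element is active
  in exactly `round(usage_specificity · n_states)` states
  (`usage_specificity = 0.4`). Active elements draw log-normal TPM
  (median 5, σ = 0.8); inactive elements draw Uniform(0, 0.05), far below
  the 1-TPM usage rule. At `usage_specificity ≤ 0.2` the per-state mean
  activity has a Gini index above 0.8, matching the high specificity
  reported for real CAGE elements.
- **Neighbourhood structure.** With probability 0.2 an element adopts the
  activity pattern of its 500-kb chromatin domain, and with probability 0.4
  a promoter within 200 kb of its upstream neighbour shares that
  neighbour's pattern (co-regulated gene clusters). These two couplings
  create "hitchhiker" enhancers — elements correlated with a promoter they
  do not regulate — which is precisely the confounding that motivates joint
  regression over pairwise correlation.
- **Planted links.** Each promoter receives 2–4 enhancers with effect
  sizes β ~ Uniform(0.5, 1.5), preferring nearer enhancers with an
  exponential distance decay of scale 240 kb so that ~34% of links fall
  within 100 kb (the short-range bias seen in real EPI sets). With
  probability 0.6 a link slot reuses an enhancer already serving a
  co-patterned promoter, so a realistic fraction of enhancers regulate two
  genes — the case one-link-per-enhancer baselines cannot represent. A
  planted enhancer is co-active exactly in its target's states.
- **Activity coupling and noise.** In the promoter's active states its
  activity is `Σ β·A_latent(e) + N(0, noise_sd)` floored at 0; the
  *observed* enhancer TPM is the latent activity times a log-normal
  measurement factor (σ = 0.5), reflecting the shallowness of eRNA
  quantification. `noise_sd = 6.0` is calibrated once so planted pairs show
  a Spearman correlation of ≈ 0.70 across samples (measured 0.70–0.72
  across seeds); unlinked promoters get their own log-normal baseline.
- **Validation and GWAS.** `make_validation` keeps each true link with a
  given sensitivity and adds false within-1 Mb pairs at a given rate.
  `make_gwas` places SNPs uniformly, gives background SNPs Uniform(0,1)
  p-values and SNPs inside causal genes' bodies ± 2 kb or their planted
  enhancers `Beta(1/(1+effect_shift), 1)` p-values (shift 0 recovers the
  uniform law). Causal genes are drawn from genes whose signal regions are
  *private* (no body-overlap with another gene's assignment window, no
  shared or intron-resident enhancer), so that "false positive" is well
  defined in recovery tests.

What the generator does **not** emulate: read-level counts and their
sampling noise, LD structure among SNPs, distance-dependent contact
frequencies beyond the planting bias, assembly artefacts, and unequal
replicate numbers. A green recovery test therefore establishes that the
pipeline's statistics behave as designed under the stated coupling model —
not that real pcHi-C-scale confirmation rates would be reproduced.

**Measured behaviour at the defaults** (computed by the test suite and
`scripts/acceptance.py`, nothing asserted here that they do not compute):
the pipeline's AUPR against the planted truth, on the universe restricted
to validated enhancers, is ≈ 0.70–0.73 across seeds (one observed seed at
0.68), strictly above the max-correlation (≈ 0.52–0.72), closest-promoter
(≈ 0.18) and random (≈ 0.12) baselines; planted causal genes are recovered
at FDR < 0.05 with recall ≈ 1.0 and empirical FDR ≈ 0.05–0.13.

## 3. Evaluation machinery

- **AUPR** is step-wise average precision with tied scores grouped into one
  block (deterministic under input permutation; equals scikit-learn's
  `average_precision_score` when scores are distinct). Universe pairs
  without a prediction rank last at score 0. For truth-based evaluation the
  universe is restricted to within-1 Mb pairs whose enhancer appears in the
  validation set at least once. Baselines are scored by monotone transforms
  of their natural statistic (1/(1+d) for closest, (ρ+1)/2 for
  max-correlation, seeded uniform for random) — AUPR is invariant to the
  transform; it only keeps the scored pairs above the unscored remainder.
- **QTL enrichment** uses `OR = (a/b)/(c/d)` with controls drawn to match
  the real variants' MAF distribution over 50 equal-width bins on (0, 0.5],
  30 seeded repeats, reporting mean and SD (ddof = 1). A bin with real
  variants but no candidate controls is an error naming the bin. A
  posterior-probability cut (e.g. > 0.8) for fine-mapped variants is a row
  filter on the input.
- **Overlap enrichment** parameterizes the hypergeometric test with the
  query background as population, background members hitting the active
  set as successes, and the query as the draw; the OR is
  `(k/|query bg|)/(|active|/|active bg|)`.
- **Gene-level p-values** use Fisher's combination (χ² with 2k df), which
  assumes independent SNPs — true in the generator, a stated limitation
  for LD-structured real data; the combiner is a single function and can
  be swapped. BH adjustment is per state. The expression filter requires
  TPM > 1 and strictly above the median of all *other* genes in the
  sample, union-aggregated over the state's replicates.

## 4. Open design points and how they were fixed

- *Aggregation* of replicate calls is the union with maximal ABC — the most
  inclusive reading consistent with keeping a maximum.
- *Pipeline score for ranking* in PR evaluation is the edge's maximal ABC
  across states (the pipeline's quantification), not ρ or β.
- *Cross-state comparison* uses the union of all edges as a common
  coordinate system, ordered by (gene, enhancer); average linkage by
  default; a pair of empty networks gets distance 1 with a warning.
- *EPI-level specificity* applies the strict >50%/<50% rule to per-sample
  active flags, not to the aggregated networks.
- *Promoter TPM from coverage* counts a track record fully if it overlaps
  the window by ≥ 1 bp (`mode="any"`); a strict 5′-position mode is a flag.
- *SNP routing* through networks uses binary edge presence, not ABC
  weights.
- Degenerate inputs: zero-variance promoters select nothing; all-zero
  activity rows have undefined entropy specificity (NaN, reported as
  missing); an empty enhancer set yields empty networks without error.

## 5. Known limitations

- LASSO recall is bounded by collinearity at small sample counts; with
  hundreds of samples (as in full-scale atlases) the bound relaxes.
- The step-2 filter controls the marginal false-pass rate, not the rate
  conditional on step-1 selection (see §1).
- CAGE alone cannot distinguish active from poised enhancers; the pipeline
  makes no attempt to.
- Trans (inter-chromosomal) regulation, Hi-C-informed contact and LD-aware
  gene-based tests are out of scope.
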