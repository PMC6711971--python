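# Methods

## Study design and estimands

The package analyses a two-arm crossover/crossback exposure study. Subjects
enter on either the background-DBP drug (arm B₁HB₂) or the high-DBP drug
(arm H₁BH₂), are sampled at baseline, switch for one ~90-day spermatogenic
cycle (crossover sample), and switch back (crossback sample). Exposure
condition is therefore a deterministic function of arm × visit. Three
estimands are supported:

1. the **transition slope** — the change in a feature's expression (RPKM)
   between two consecutive visits within one arm;
2. the **condition slope** — the high-vs-background contrast (RPM) pooling
   all visits of an arm, for small RNAs whose per-visit sample sizes are too
   small to model transitions;
3. the **cohort slope** — the control-minus-IBD contrast for one visit
   against an external cohort (control coded 1, so positive means higher in
   controls).

## The mixed model and its fitter

Transitions and conditions are modelled per feature as

    y_ij = β₀ + β₁·x_ij + γ'c_ij + u_i + e_ij,
    u_i ~ N(0, σ²_u),  e_ij ~ N(0, σ²_e)

with `x` the later-visit (or high-DBP) indicator, `c` the nine adjustment
covariates (sequencing batch, months on high-DBP drug before the study, BMI,
seasonal warmth, smoking, age, amplification efficiency, duplication rate,
alignment rate) and `u_i` a per-subject random intercept. β₁ is the reported
slope, in matrix units.

Because the permutation machinery refits this model ~10⁵ times per run, the
fitter is a purpose-built profiled-REML solver for the single
variance-component case: the REML criterion is reduced to a one-dimensional
bounded search over λ = σ²_u/σ²_e, with closed-form GLS solves inside (each
subject block of V⁻¹ is `I − λ/(1+λn_i)·J`). The test suite verifies slope
agreement with statsmodels `MixedLM` to <10⁻³ and variance components to
~2%, on balanced and unbalanced designs. Degenerate fits fall back to
ordinary least squares on subject-mean-centred data and are flagged
(`method = ols_within`); an all-constant feature returns slope 0, p 1
(`method = constant`).

## Permutation empirical P-values

Testing >10⁵ features per comparison makes parametric per-feature inference
fragile, so significance comes from a resampling null. The null is built by
permuting, within each subject, which of the subject's observations carries
which visit (or condition) assignment, and refitting the full model. The
implementation permutes the subject's **responses across the subject's
design rows**, holding the design matrix fixed. The distinction from
permuting the label column alone matters: per-sample technical covariates
(batch, alignment rate, …) stay glued to their design rows, so the observed
and permuted statistics share the same design geometry and the test is
exact whenever observations are exchangeable within subject under the null.
Label-only permutation with covariates attached to samples was measured at
a type-I error of ~0.025 at α = 0.05 on this package's own null
simulations; the implemented scheme measures ~0.046 (see
`scripts/acceptance.py`).

The P-value uses the add-one estimator `p = (1 + #{|slope*| ≥ |slope|}) /
(B+1)`, so `p ∈ [1/(B+1), 1]` and is never zero. When the within-subject
permutation group has at most B elements the full group is enumerated
(identity excluded) and the test is exact by enumeration; a warning records
the truncation. Two resampling modes exist: `per_feature` (default; each
feature gets its own B permutations, seeded by hashing the feature id so
results do not depend on iteration order) and `pooled_null` (one pool of B
null slopes shared across features, round-robin over features — the
practical choice when B × features is prohibitive).

Calls are `up` when `p < α` and slope > +threshold, `down` for the mirror,
`ns` otherwise. Thresholds: 10 RPKM (long REs), 5 RPM (small RNAs), both
strict inequalities on the slope ("exceeds"), α = 0.05 strict.

## Pattern classification

The (T1, T2) call pair maps bijectively onto eight significant response
classes — acute up/down (T1 only), recovery up/down (T2 only), continuous
up/down (same direction twice), reversal up-down / down-up — with (ns, ns)
as `none`. `summarize_patterns` tabulates classes against RE classes and
reports the fraction of altered features significant in both transitions.

## RE classes

REs are classified against a gene model with deterministic priority
exonic > near-exon > intronic > orphan: any 1-bp exon overlap is exonic;
otherwise a gap of at most `near_window` bp to the closest exon is
near-exon; otherwise position inside a gene body is intronic; everything
else is orphan. `near_window` defaults to 1 kb and is deliberately exposed
as a parameter — the upstream discovery literature does not pin a single
value, and the classifier is a simplified interval rule, not a rediscovery
of the original RE-calling algorithm. Strand is ignored: sperm RNA is
heavily fragmented, and no strand-aware rule is defensible for these
elements. Coordinates are 0-based half-open throughout; adjacent intervals
do not overlap.

## Repeat enrichment

With `A` the REs overlapping *any* repeat (non-repeat REs never enter),
`R` those overlapping the repeat of interest, and the `_expressed` subsets
those with median expression ≥ 25 RPKM across the visit's samples
(boundary inclusive — "expressed at the threshold" counts),

    Δratio = R_expressed/A_expressed − R/A.

Significance is one-sided hypergeometric in the direction of the sign
(population `A`, `R` marked, `A_expressed` draws): enrichment tests
P(X ≥ R_expressed), depletion P(X ≤ R_expressed), Δratio = 0 returns p = 1.
Benjamini–Hochberg is applied within each arm × visit sweep (and within
each RE class when stratified); raw and adjusted P are both reported. An RE
overlapping several repeats counts once per repeat — a documented
double-count across repeats, not within one.

## Small RNAs

Libraries need ≥ 50,000 input reads (boundary inclusive: the threshold is a
required minimum). The condition model treats a subject's retained visits as
replicates of their condition; arms with a single condition present are
rejected. "Highly abundant" small RNAs have median RPM strictly exceeding
50 across all samples.

## IBD vs control

Controls contribute one sample per subject; IBD subjects may have replicate
samples at a visit. Per resample, one sample is drawn uniformly per IBD
subject and each feature is fit by OLS of expression on cohort (+
covariates shared by both sheets). The median slope and median P across the
B resamples are reported — a robust, order-independent aggregate — then
BH-adjusted across features. Without replicates every resample is
identical, so the computation collapses to a single fit. Resampling one
sample per subject (rather than bootstrapping subjects) was chosen because
the replicates are the stated reason for resampling; a subject-level
bootstrap is a reasonable alternative the module does not implement.
Consensus keeps features called in the same direction in ≥ 2 of the 3
visit comparisons; a conflicting third call is retained but flagged and
logged.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the design's structure: two arms (defaults 16 and
19 subjects — the arms' consecutive-visit-pair counts), per-visit
missingness (default 0.15) and replicate collections (default 0.4, which
brings ~35 subjects × 3 visits near the study's ~150 analysed samples),
subject random intercepts, covariates drawn from plausible distributions
(batch ~ 3 levels, age ~ N(35, 8) truncated at 18, BMI ~ N(27, 4), smoking
~ Bernoulli(0.2), seasonal warmth ~ Bernoulli(0.5), amplification
efficiency ~ Beta(20, 5), duplication rate ~ Beta(2, 8), alignment rate ~
Beta(30, 3), prior months on high-DBP ~ U(3, 60) for the chronically
exposed arm), and planted effects per response class (visit-cumulative
deltas for long RNAs, condition deltas for small RNAs, default ±30 RPKM /
±10 RPM on baselines of 50–150 RPKM / 20–80 RPM).

Noise is Gaussian on the RPKM/RPM scale with clipping at zero — matching
the scale the linear models consume, so the planted delta *is* the model's
estimand; the clipped fraction is recorded and stays below 5% at defaults.
The generator does not emulate counting noise (mean–variance coupling),
RNA fragmentation, alignment artifacts, or correlated features; passing
tests therefore demonstrate correctness of the inference machinery under
its own assumptions, not robustness to real-data violations of them. The
residual variance structure of the original analyses is unpublished;
Gaussian homoscedastic residuals are this package's assumption.

Replicate visits share the subject's intercept and planted effects and
differ only in per-sample draws (residual and technical covariates), which
is what the IBD resampling step must absorb.

## Numerical choices

* λ searched on log scale in [e⁻¹⁸, e¹⁸]; the lower boundary is reported
  as σ²_u = 0. Optimiser tolerance 1e-6 on log λ.
* One master seed; per-feature and per-stage streams derived by CRC-hashing
  `(stage, feature_id)` into numpy `SeedSequence`, so results are
  independent of feature order and of which stages run.
* Validation-study problem sizes (500 null features / B = 200; 120 pattern
  features / B = 500; 200 features per planted slope) were chosen as the
  smallest sizes whose binomial/Monte-Carlo error is comfortably inside the
  bands being checked, and run in a few minutes on one CPU.
* `pooled_null` trades per-feature exactness for an O(features)-fold
  reduction in refits; its pool mixes features, so it assumes a common null
  slope scale across features.

## Known limitations

* The near-exon window is a placeholder for the upstream definition; class
  counts are sensitive to it.
* The IBD model assumes cohort-comparable covariates; batch effects
  confounded with cohort are not identifiable and are not modelled.
* Δratio's hypergeometric test treats REs as exchangeable draws; spatially
  clustered repeat REs violate independence and the P-values are then
  optimistic.
* The permutation test's exactness argument needs within-subject
  exchangeability under the null; strong visit-linked heteroscedasticity
  would break it.
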