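# Methods

## The model

A cohort is a taxon-by-sample table of counts or relative abundances
(Q taxa × n samples) with a binary outcome per sample (1 = case). Write
*M*ᵢⱼ for the relative abundance of taxon *j* in sample *i* (Σⱼ *M*ᵢⱼ = 1).
Given a sub-community S of p selected taxa, abundances are renormalized
within S, *M̃*ᵢⱼ = *M*ᵢⱼ / Σⱼ∈S *M*ᵢⱼ, and the community-based risk score is
the sub-community alpha diversity with the orientation *lower diversity ⇒
higher risk*:

- **shannon** (default): Σⱼ *M̃*ᵢⱼ ln *M̃*ᵢⱼ ∈ [−ln p, 0], i.e. Shannon
  entropy without the negative sign; 0·ln 0 ≡ 0.
- **simpson**: Σⱼ *M̃*ᵢⱼ² (concentration form, range (0, 1]). Concentration
  was chosen over Gini–Simpson or inverse Simpson so that every index shares
  the Shannon orientation without an extra sign flip.
- **observed**: −(number of selected taxa present).
- **pd**: −(total branch length of the minimal subtree spanning the present
  selected taxa). The spanning subtree is rooted at the LCA of the present
  leaves — branches from the LCA up to the global root are excluded by
  default (`include_root_path=True` restores them). Taxa missing from the
  tree are an error, not silently dropped.

Samples in which every selected taxon is absent receive the
minimal-diversity limit (shannon 0, simpson 1, observed 0, pd 0) and a
degenerate flag rather than NaN, so cross-validation never drops samples
silently.

The summation-based alternative is MRS_S(i) = Σⱼ wⱼ *M*ᵢⱼ over the **raw**
(non-renormalized) relative abundances, with wⱼ = 1 (unweighted) or the DA
effect sizes estimated on the discovery/training samples (weighted). For
transcriptome-type layers the score is Σⱼ signⱼ · ln(countᵢⱼ + 1), the sign
being the direction of the training fold change; natural log of count+1 is
the package's reading of "log-transformed counts".

## Differential abundance

Two built-in tests produce per-taxon (p-value, signed effect), positive =
enriched in cases:

- **wilcoxon**: two-sided rank-sum on relative abundances. Exact by
  enumeration of all label assignments for total n ≤ 10 (p = probability of
  a rank-sum at least as far from its permutation mean as observed; valid
  under ties), otherwise a normal approximation with tie and continuity
  corrections. Effect = difference in mean relative abundance.
- **clr_ttest**: Welch t-test per taxon on centered log-ratio values,
  x ↦ ln((x+c)/g(x+c)) with pseudocount c = 0.5 (configurable). Effect =
  difference in mean CLR.

Dedicated DA tools are deliberately not re-implemented; their output enters
through `import_da_results` (TSV: feature_id, p_value, effect). P-values are
consumed raw by the threshold search — published cutoffs for this style of
selection (e.g. 0.42) only make sense on the raw scale — and a
Benjamini–Hochberg column is attached for reporting only. Constant taxa get
p = 1, effect = 0, and a degenerate flag.

## P+T threshold selection

Candidate cutoffs are the sorted unique p-values (nearest-rank
quantile-thinned to `max_grid`, default 100, so a thinned grid is a subset
of the full one) plus a terminal 1 + ε so the full table is always a
candidate; each value t defines the nested set {taxa : p < t} (strict
inequality). Under LOO (default) or seeded stratified k-fold CV, DA is re-run
on the training samples of each fold and every threshold's training-derived
sub-community (with training-derived weights, for weighted scores) scores
the held-out samples; pooled held-out scores give AUC(t), and the chosen
cutoff is the argmax, ties broken toward the smallest cutoff (fewest taxa).
Thresholds whose full-data set is empty are excluded from the argmax (their
pooled scores are a degenerate constant). The final sub-community is the
full-data DA result thresholded at the chosen cutoff.

Two deliberate design points:

- **Grid placement vs fold membership.** The grid is laid out once from the
  full-data p-values — like a regularization path fixed before
  cross-validation — while set membership at each grid value inside a fold
  uses training-only p-values. Held-out samples therefore cannot influence
  which taxa a fold selects (the leakage-guard test perturbs held-out
  samples arbitrarily and asserts fold selections are unchanged).
- **Scoring along the path** exploits nestedness: sorting taxa by p-value
  turns every threshold into a prefix, so prefix sums evaluate all
  thresholds in O(Qn) per fold for shannon/simpson/observed/sum scores (PD
  has no prefix structure and is scored directly, outside the search).

An imported DAResult is reused across folds (its p-values already saw all
samples); this external-selection leakage is warned about.
`da_scope="full"` reuses the built-in full-data DA the same way for
comparison with the non-nested variant.

Pooled CV-AUC maximized over a grid carries winner's-curse optimism; under a
pure-null simulation (n = 60, 50 taxa) the maximum pooled LOO AUC typically
lands between 0.55 and 0.85. The chosen sub-community, not the maximized
curve value, is the quantity that transports.

## Evaluation

AUC is the Mann–Whitney estimator (ties one half), computed from midranks;
the ROC curve is a threshold sweep. The default 95% CI is DeLong's
structural-components variance mapped through the delta method on
logit(AUC) and back-transformed. The logit scale matters: at the high AUCs
a well-separated sub-community produces, the plain normal interval is
anti-conservative (its upper tail crosses 1 and its lower bound sits too
high); the logit interval stays inside (0, 1) and achieves ~95% coverage in
the binormal study below. `scale="linear"` gives the plain truncated
interval; a stratified bootstrap (2000 seeded resamples, percentile) is the
alternative and the automatic fallback when the DeLong variance degenerates
(AUC exactly 0 or 1).

Risk dichotomization: high risk iff score > mean (or > third quartile,
linear-interpolation definition); a score exactly at the cut is low risk.
Extreme-category classification dichotomizes each of several scores at its
own mean, predicts *case* for subjects high in **all** scores and *control*
for subjects low in all, excludes discordant subjects (their count is
reported), and computes sensitivity/specificity/accuracy/F1 with the case
class positive.

## Multi-omics integration

Per-layer scores are z-standardized with training-fold moments and combined
by an additive logistic regression fitted with IRLS (tolerance 1e-8 on the
coefficient step, ≤ 100 iterations). Separation or a singular design
triggers a refit with ridge 1e-4 on the slopes (intercept unpenalized),
flagged in the model object — LOO folds on small cohorts separate
routinely. Within each CV fold of `combined_cv_prediction`, every layer's
score is rebuilt on training samples only, *including its own P+T
selection*; the inner threshold is chosen by training-sample AUC along the
nested path rather than an inner CV (nested CV at LOO scale would multiply
runtime by n while the outer CV already measures honest held-out
performance). Interaction terms are out of the default model.

Cross-omics structure is described by Spearman correlations (average ranks,
tie-corrected) between each layer's top-k features, ranked by selection
proportion across CV folds with |effect| breaking ties.

## Synthetic data

Microbiome counts are Dirichlet-multinomial: base concentrations are
log-normal(0, σ = 1) scaled to a total of 50 over Q = 200 taxa (small
per-taxon concentrations produce the sparsity and zero inflation of real
tables — ~40% zeros at the default library sizes, uniform on
[5 000, 50 000]); per-sample proportions are Dirichlet draws and counts
multinomial. The reference cohort is 100 cases + 100 controls with 10
signal taxa at a 4-fold concentration effect.

The default effect pattern is classic dysbiosis: the baseline-dominant
signal taxon *blooms* in cases and the other nine deplete. This pattern
determines the orientation of the community score. Within the sub-community
the renormalized composition is again Dirichlet, and at small concentrations
the *total* concentration of the set controls dispersion: depleting most of
the set shrinks that total in cases, so case compositions are more
dispersed — typically one dominant taxon, more sampling zeros — and case
sub-community diversity drops, as the score assumes. (Enriching all signal
taxa uniformly would cancel in the renormalized mean by Dirichlet
aggregation and *raise* the case total, making cases look more even — the
opposite orientation.) A side effect is that whole-community Shannon
diversity retains a modest association with the outcome (AUC ≈ 0.66 under
the reference conditions); the sub-community score still clears it by ≈ 0.29
AUC, which is the contrast the selection step is supposed to create.

`population_seed` separates the population (base concentrations, signal
assignment, gene truth) from the sampling seed, so independent discovery
and validation cohorts can be drawn from one generative model. The
companion gene layer is negative-binomial (gamma–Poisson, dispersion 0.4)
with DE genes log2-shifted in cases; `shared_latent_weight` couples the two
layers through a per-sample latent liability (0 = layers independent given
the outcome).

What the generator does *not* emulate: phylogenetic correlation of effects,
taxon–taxon interactions, longitudinal dynamics, batch effects, and
compositional biases of extraction/sequencing. Passing tests therefore show
the pipeline recovers the signal structure it targets under a plausible
sparse compositional model, not that it is robust to every artifact of real
data.

## Simulation studies (problem sizes)

The acceptance script and test suite run these studies; sizes were chosen to
keep each study in the seconds-to-minutes range on one CPU.

- **Signal recovery** (20 seeds, reference conditions): fraction of the 10
  planted taxa inside the chosen sub-community (typically ≈ 0.9) and the
  margin of the CV-AUC over whole-community Shannon (typically ≈ 0.25–0.3).
- **External validation** (50 replicate cohort pairs): discovery at the
  reference size, validation at 200+200 — twice the discovery arms, so the
  validation AUC estimate contributes little noise to the comparison; the
  discovery AUC is the final sub-community score evaluated on the discovery
  cohort (the number external-validation practice reports), with its DeLong
  95% CI. Validation AUC falls inside that CI in ≈ 85–90% of replicates.
- **Integration** (50 replicates of the two-layer preset: 300+300 samples,
  100 taxa with 10 weak 1.45-fold signal taxa drawn from the abundant half
  under quantile concentration spacing, 200 genes with 10 DE at log2FC
  0.55): marginal CV-AUCs near 0.72/0.77; the additive combination exceeds
  both in effectively every replicate, and a pure-noise third score moves
  the combined AUC by < 0.05.
- **DeLong coverage** (500 binormal datasets, 50 cases + 50 controls, true
  AUC 0.75): interval covers the truth ≈ 95% of the time.
- **DA type-I error** (500 null cohorts, 25+25 samples, 40 taxa, 10%
  prevalence filter): rejection at nominal 5% ≈ 0.048 (wilcoxon) and
  ≈ 0.051 (clr_ttest).

## Numerical choices and degenerate inputs

- 0·ln 0 ≡ 0 everywhere; all-zero sample columns are kept (with a warning)
  so metadata alignment never breaks.
- Relative-abundance validation tolerance 1e-9 on column sums; tables
  restricted to a taxon subset are marked `subset` and exempt from the
  column-sum invariant (they are deliberately not renormalized by
  `align_to_taxa`).
- Wilcoxon exactness switches at total n = 10 (configurable); the normal
  branch uses tie-corrected variance and a 0.5 continuity correction.
- Threshold comparison is strict (p < t); AUC ties count one half; argmax
  ties resolve to the smallest threshold; AUC orientation is fixed (cases
  assumed higher-scoring) unless `orient="auto"`, which records the sign.
- IRLS weights are clipped below at 1e-10; divergence is declared at
  max|β| > 1e4.
- Seeds: every stochastic operation takes an explicit seed (CLI default 17,
  recorded in provenance); identical configurations reproduce all JSON/TSV
  artifacts byte-identically.

## Known limitations

- P+T over the PD index is not supported inside the CV search (no prefix
  structure); select with another index and score the chosen sub-community
  with PD afterwards.
- The maximized CV-AUC is an optimistic estimate of transported performance
  (winner's curse over the grid); report the validation AUC or the
  discovery-cohort AUC of the final score instead.
- Covariate-adjusted DA, survival models, and PRS construction are out of
  scope; scores and risk strata are exported for external tools.
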