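# Methods

This note documents the models, estimators and numerical choices behind
`aoacorpus`, and what the synthetic-data experiments do and do not establish
about real corpora.

## The corpus-based AoA estimator

For child *c* and word *w*, the first-occurrence age `F(c, w)` is the age (in
months) of the earliest recording session in which *c* produces *w* at least
once. Two structural facts shape the estimator:

1. **Anti-precedence.** A word can only be produced after it is acquired, so
   `F(c, w) ≥ A(c, w)`, the true acquisition age, always.
2. **Frequency bias.** Conditional on acquisition, the waiting time until a
   word is first *sampled* falls with its usage rate; rare words are attested
   late (or never), so first-occurrence AoA is confounded with frequency.

The k-child estimate retains words attested by at least k children.
Aggregation follows the convention that the 1-child variant is the earliest
occurrence in *any* child (an open-vocabulary, maximally inclusive measure),
while the 6- and 12-child variants take the mean first age over **all**
attesting children. Both aggregators are exposed (`kchild_aoa(..., aggregator=)`);
for a fixed word set, min ≤ mean always. Words already present in a child's
first session are flagged `censored` (their true first production may predate
the recording window) but are retained, since no principled imputation exists
for them; the flag supports sensitivity analyses.

Ages use a 30.44-day month throughout and are stored at two decimals —
day-level precision, matching what a `Y;M.D` CHAT age string can encode.

## CHAT parsing and tokenization

The reader implements a minimal CHAT dialect: `@`-headers (with the
participant age taken from the target speaker's `@ID` record), `*COD:` main
tiers with tab-indented continuations, `%`-dependent tiers ignored. Token
normalization is deliberately conservative, biased toward real lexical types:
lowercasing; dropping `xxx`/`yyy`/`www`, `&`-prefixed fillers and fragments,
`0`-prefixed omissions, bracketed annotation codes and bare punctuation;
stripping `@`-form markers to the stem (`doggy@c` → `doggy`); keeping `+`/`_`
compounds as single types. Inflected forms count as distinct types (no
lemmatization). All rules live in one configurable `TokenizerConfig`;
they are analysis decisions, not facts about any particular corpus, and the
extraction layer makes them auditable rather than hiding them in regexes.

## Reliability

ICC(2,k) comes from the two-way random-effects ANOVA decomposition of the
words × children matrix of first ages:

    ICC(2,k) = (BMS − EMS) / (BMS + (JMS − EMS)/n)

with BMS/JMS/EMS the between-word, between-child and residual mean squares
and *n* the number of words. The canonical path requires a complete matrix
and therefore drops words not attested by every rater (for the 12-child set
this is exact; for sparser variants it restricts to the universally attested
core). An alternative path (`icc2k_unbalanced`) estimates crossed word/child
variance components by REML over all available cells and forms the ICC with
the mean raters-per-word; it is model-based and labeled non-canonical.
Degenerate inputs (fewer than two complete rows, zero between-word variance)
return NaN with a warning rather than a misleading number.

Split-half reliability partitions children into random halves (sizes differ
by at most one when odd), computes per-word mean first ages within each half,
and correlates them over words present in both halves. Because a word needs
two attestations to appear in both halves, words attested by fewer than two
children are excluded up front. The reported value is the mean over 100
seeded partitions (`n_splits`, configurable); no Spearman–Brown correction is
applied by default, since the raw half-correlation is the quantity of
interest, but the correction is available as an option. A seed is mandatory.

## Parent-report AoA50

Per word, the CDI observations (age, children saying it, children asked) are
fitted with a binomial GLM, logit(p) = β₀ + β₁·age, and AoA50 = −β₀/β₁, the
age at which the fitted curve crosses 50%. Exclusion rules: non-convergent
fits (`no_convergence`), fits with β₁ ≤ 0 (`non_positive_slope`, a curve that
never rises), and crossings outside 6–60 months (`out_of_range`; such
crossings come from near-flat curves and extrapolate far beyond the observed
age window). The admissible range is configurable. Aggregated binomial counts
and child-level binary rows give identical ML fits; counts are used.

## Norm harmonization

Test-based AoA uses grade levels {2, 4, 6, 8, 10, 12, 13, 14}; polysemous
entries are merged by taking the minimum grade over meanings. Child
log-frequency is the natural log of the arithmetic mean of the preschool
(0–6 y) and primary-school (6–12 y) per-million rates; zero-frequency words
become missing rather than smoothed (an ε-smoothing flag is not enabled by
default because the downstream analyses are complete-case anyway). Words join
by exact string match after case folding, with duplicates within a source an
error. Units are *not* harmonized across measures (years, grades, months):
every downstream statistic is a correlation or a standardized coefficient,
hence scale-free.

**Frequency adjustment.** The adjusted corpus AoA is the OLS residual of AoA
on child log-frequency fitted over the **full** set of words with both
values. Residuals for any word subset are taken from this single fit; within
a subset they may correlate with frequency again, which is expected behavior,
not a defect — refitting within subsets would silently remove subset-specific
frequency structure.

## Validation battery

Correlation matrices are complete-case (listwise) within each k-child word
set, Pearson by default with Spearman available. Standardized regressions
z-score all variables on the analysis rows (ddof = 1) and fit OLS; p-values
are the usual two-sided t tests, unadjusted for multiplicity; VIF_j =
1/(1 − R²_j) from regressing predictor j on the others, with VIF ≡ 1 for a
single predictor. Perfect collinearity raises an error naming the predictor.
Corpus AoA enters the RT regressions unadjusted by default, with the
frequency-corrected variant run as a parallel model in the pipeline.

Cross-validation is repeated k-fold (5 folds × 4 repeats by default) with
standardization statistics recomputed **inside each training fold** — no
leakage into held-out folds — and RMSE reported on the standardized outcome
scale, so an uninformative model scores ≈ 1 by construction. This makes the
RMSE interpretable without reference to the outcome's raw units.

## The synthetic world

The generator emulates the study design the package targets: `n_children`
= 12 recorded in `n_sessions` = 36 sessions with uniform 10–14-day gaps
starting at 24 months, spanning roughly the third year of life. The latent
model:

- word mean acquisition ages `A_w ~ lognormal(median 22 mo, 0.25 log-units)`
  — centered where dense CDI norms place early vocabulary, right-skewed;
- per-(child, word) ages `A_cw = max(A_w + N(0, σ_child), 10 mo)` with
  `σ_child = 2.5` months (meaningful but not dominant individual variation;
  the 10-month floor prevents pathological ages);
- usage: the rank-r word's expected tokens per session are Zipfian
  (exponent 1) scaled to a 400-token expected session budget over
  `n_words = 500` types; counts are Poisson, zero before `A_cw`. Rates are
  assigned to words independently of `A_w`, so any AoA–frequency correlation
  in the output is attributable to the sampling mechanism alone;
- CDI: P(child of age t says w) = logistic(0.5·(t − A_w)) per month — the
  50% crossing equals `A_w` by construction;
- ratings (years) = 0.5 + A_w/12 + 0.3·(−log usage share, centered) +
  N(0, 0.75) — the contamination term encodes raters judging frequent words
  as learned earlier than they were;
- frequency table: per-million rates in two bands (1.2× and 0.8× the usage
  share × 10⁶), mean exactly proportional to usage;
- RT (ms) = 600 + 4·A_w − 25·log(per-million) + N(0, 30) — the positive-AoA
  / negative-frequency sign pattern adult lexical decision data show.

Every generator is a pure function of (parameters, seed), using independent
seed substreams per component; identical seeds give bitwise-identical worlds.

**What passing tests show — and don't.** The synthetic corpus validates the
machinery: extraction correctness, anti-precedence, the direction and
rate-dependence of the frequency bias, estimator reliability under the
stated design, AoA50 recovery, and the regression/CV pipeline. It does not
model discourse structure, session-length variation, child dropout,
comprehension-production gaps, morphology, or the coupling of frequency with
acquisition age found in real lexicons — so quantitative results on synthetic
worlds (e.g. ICC ≈ 0.9 under the default parameters) characterize the
simulated conditions, not any real corpus.

## Problem sizes

Default experiment sizes were chosen to make every property measurable with
comfortable statistical margins at desk scale: 500-word worlds for
single-world analyses; 100 seeded replicates for recovery-rate and
sign-recovery experiments; a 6-children × 18-sessions × 100-words design for
the 5-point usage-rate grid (100 seeds per point); n = 2000 for coefficient
recovery and n = 5000 for the null-CV calibration.

## Known limitations

- The canonical ICC path reduces sparser k-child variants to their
  universally attested core; the REML path relaxes this but changes the
  estimand slightly (mean-k average rather than fixed k).
- Censored first occurrences (words already present in a child's first
  session) are kept at the first-session age, which biases AoA downward for
  very early words; the flag allows excluding them, but no correction is
  applied.
- The CHAT reader targets a minimal dialect; exotic CLAN annotations outside
  it are handled by the conservative drop rules, not by a full grammar.
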