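# Methods

This note records the models, conventions, and numerical choices behind
`antkit`, and what the simulation-based tests do and do not establish.

## Condition model and scoring

Each of the six ANT cells is treated as an additive composition of a
baseline RT, cue benefits (alerting, orienting — subtracted), a conflict
cost (executive control — added), and two interaction terms: γ_AE
(alerting × conflict) and γ_OE (orienting × conflict).  All per-condition
summaries are medians of correct, window-filtered RTs; scores are always
computed from condition medians, never from trial-level differences.

Two score families follow from the cell algebra:

* dissection scores `AL = ncc − ccc`, `OR = ccc − scc`, `EX = nci − ncc`
  are unbiased for (A, O, E) regardless of γ, because each subtraction
  involves cells whose interaction content is identical;
* traditional condition-mean scores absorb the interactions, with the
  closed-form expectations `AL_old = A − γ_AE/2`, `OR_old = O − γ_OE/2`,
  `EX_old = E + (2γ_AE + γ_OE)/3`.

The influence scores are the four interaction contrasts.  In raw form the
two pairs are exact negatives of each other; the reported asymmetry
between, say, AL→EX and EX→AL can only arise after normalization, which
divides each contrast by a different pure score.  Normalization is
therefore an explicit, reported parameter everywhere (`raw` | `baseline`
for network scores, `raw` | `score` for influence scores), with the
normalized mode as the default in the scoring API.  Sign conventions:
positive alerting/orienting = RT benefit, positive executive = RT cost,
positive influence = the source network enlarges the target's effect.

Division by a zero score in normalized influence mode yields NaN for that
subject (a relationship cannot be measured from a zero score); downstream
statistics drop NaNs explicitly.  Accuracy-based scores can be formed from
the same contrasts but are excluded from correlation and reliability
analyses by default, because accuracy differences are frequently exactly
zero.

## Preprocessing

Fixed order: RT window filter → accuracy → subject exclusion → medians.

* Window bounds 200/1200 ms are *retained*; only strictly outside values
  are removed.  The removed fraction is counted over responses: a miss
  (no key press before the 1700 ms deadline) carries no RT and passes
  through the filter, but it counts as an error in accuracy.  Misses are
  treated as errors because a trial without a correct response is not a
  correct response; users with a different convention can pre-filter.
* The accuracy criterion is strict: below 0.75 in at least one condition
  excludes; exactly 0.75 is retained.
* Median of an even count is the midpoint of the two middle order
  statistics (numpy's default).

## Inference

t-tests and Pearson correlations delegate to scipy; all p-values are
two-tailed.  The repeated-measures ANOVA is computed from the closed-form
sum-of-squares decomposition of a complete balanced within-subject design,
with a separate subject-by-effect error term per effect and partial
η² = SS_effect/(SS_effect + SS_error).  Greenhouse–Geisser ε is obtained
from the sample covariance of the subjects' cell scores through an
orthonormal Helmert contrast basis (Kronecker product for the
interaction): ε = tr(M)²/(d·tr(M²)) with M = C S Cᵀ, clipped to
[1/d, 1]; ε = 1 exactly for two-level effects.  Corrected and uncorrected
p-values are always reported side by side rather than gated on a
sphericity test, since the gating criterion is itself a modelling choice;
callers who want Mauchly-style gating can compare the two.  An effect with
exactly zero sum of squares is reported as F = 0 even when its error term
also vanishes.  Post hoc comparisons are plain paired t-tests; Bonferroni
correction is left to the caller (the number of comparisons is
context-dependent).

## Reliability

ICC is the one-way random-effects form across the k = 3 runs (blocks),
with per-run scores computed from run-level condition medians — the only
granularity at which "one value per item per run" is well defined.  ICC
can be negative (MSw > MSb); negative values are reported as computed.

Split-half reliability splits the correct, window-filtered trials within
each subject × condition into random halves, scores each half, correlates
the two score vectors across subjects, and averages over permutations
(default 1000).  Odd cells assign the extra trial to a random half; the
expectation of the mean r is invariant to that tie-break.  No
Spearman–Brown correction is applied by default (the mean r itself is the
reported reliability); `SplitHalfResult.spearman_brown` provides the
full-length prophecy for users who want it.  Subjects with fewer than two
correct trials in any condition are dropped from the split-half with a
warning.  Reliability defaults to raw scores: normalized influence scores
divide by half-sample score estimates whose near-zero realizations
produce unbounded correlation outliers; normalization remains a parameter
for users who accept that.

## Simulator

`simulate_dataset` draws, per subject, a Normal baseline offset (SD 40 ms
by default) and — optionally — Normal offsets on each effect parameter;
per trial it adds an ex-Gaussian residual (Normal σ = 50 ms plus
Exponential τ = 100 ms), right-skewed like empirical RT distributions,
which is precisely why the pipeline summarises by medians.  RTs reaching
the 1700 ms deadline become misses.  Correctness is Bernoulli with
target-dependent error rates (defaults 0.02 congruent / 0.10 incongruent)
and is independent of RT — a documented simplification; error trials
still have latencies.  Default effect sizes are baseline 600 ms, alerting
40 ms, orienting 35 ms, conflict 90 ms, γ_AE 20 ms, γ_OE 10 ms — a
realistic regime for a condensed single-modality ANT.

The schedule is exactly counterbalanced: each block is one pass through
3 cues × 2 targets × 9 SOAs (200–600 ms; the nine values are taken
equally spaced at 50 ms steps, an explicit assumption recorded in the
config) in seeded random order.  SOA, cue duration, and the post-target
fixation are schedule metadata only; the default model gives SOA no
effect on RT since all analyses collapse over it.  No sequential effects,
fatigue/practice drift, or inhibition-of-return dynamics are modelled.

Because every between-subject difference-score signal cancels through the
shared baseline, the effect-SD parameters (default 0) are what create
between-subject score variance; reliability studies on simulated data
must set them.  What passing recovery tests show is that the estimators
are unbiased and correctly ordered **under this generative model**; real
ANT data add sequential dependencies, RT–accuracy coupling, and
non-stationary noise that the simulator deliberately omits, so empirical
reliability magnitudes are not predicted by these simulations — only the
structural orderings (e.g. dissection scores more reliable than influence
scores when effect variance dominates) are.

## Problem sizes and tolerances

Algebraic identities are checked exactly (antisymmetry) or at 1e−9
(floating-point accumulations over 1000 random median sextets); oracle
equivalences at 1e−10 (ICC) and 1e−8 (interaction F vs t²).  Parameter
recovery uses a 200-subject cohort at 27 trials/condition with a 3-SE
Monte-Carlo band; type-I calibration uses 2000 null replicates with a
3-sigma binomial band around 0.05; reliability-ordering runs use 36
subjects and 150 permutations, sizes at which the orderings are stable
across seeds while the whole suite stays fast.
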