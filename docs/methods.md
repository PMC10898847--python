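# Methods

## Task environment

The Two-Step Task couples a probabilistic stage-1 transition to a pair of
drifting stage-2 bandits. Stage-1 action *a* ∈ {0, 1} leads to its common
planet (state *a*) with probability 0.7 and to the other planet
otherwise. Each planet offers two aliens whose reward probabilities
follow four mutually independent Gaussian random walks. The original
task description leaves the walk parameters open; this package uses the
convention standard for this task family — reflecting bounds
[0.25, 0.75], per-trial step SD 0.025, initial values uniform within
bounds — all configurable, with pre-determined walks loadable from a
4-column CSV. Counterbalancing permutes the four walk columns through
four schemes (identity, planets swapped, aliens swapped, both), assigned
round-robin across subjects, and each subject keeps the same walks at
follow-up. Sessions comprise 200 main trials; the 50 tutorial trials
(10 response-training, 20 stage-2-only, 20 full practice) are counted in
the configuration but never enter any analysis. Stimulus left/right
placement is randomized per trial and the response side logged, because
the same-key engagement filter operates on response sides. No response
deadline is simulated.

Missing-data semantics: a missing stage-1 response voids the whole
trial; a missing stage-2 response keeps the stage-1 data and carries no
reward.

## The hybrid agent

Five parameters: learning/forgetting rate α ∈ [0, 1]; model-based weight
β_MB ≥ 0; model-free weight β_MF ≥ 0; repetition bias β_rep ∈ ℝ; stage-2
inverse temperature β_consistency ≥ 0. All Q values start at 0. Per
completed trial, in order:

1. stage-1 softmax over β_MB·Q_MB + β_MF·Q_MF + β_rep·I[repeat]
   (I = 0 for both actions when there is no previous stage-1 choice);
2. transition, then stage-2 softmax over β_consistency·Q(s, ·);
3. chosen-alien update Q(s, c2) ← (1 − α)Q(s, c2) + r;
4. the chosen spaceship's model-free value is **replaced** by that
   freshly updated alien value;
5. all unchosen spaceships and aliens decay by (1 − α).

Step 4 is the one genuinely open design point in this model family's
bookkeeping: a "pure decay" rule for the chosen stage-1 value would be
overwritten by the copy rule anyway, so the copy-plus-decay scheme is
the only reading under which all update rules are jointly operative.
Q_MB is recomputed from the stage-2 table each trial as the maximum
alien value in each action's common planet. Incomplete trials contribute
their observed stage-1 choice to the likelihood but trigger no value
update; the repetition indicator tracks the last observed stage-1
choice. We note the model family's prose convention that *lower* α means
faster learning coexists uneasily with the update algebra; the
implementation follows the equations as written, and the recovery suite
characterizes α's empirical behaviour directly.

Numerical safety: softmax with max-subtraction, log-probabilities
floored at log(1e-12). The session likelihood is a compiled (numba)
trial recursion; a readable reference implementation composed from the
individual update operations is kept in `agent.py` and the two are held
to 1e-10 agreement in tests.

## Hierarchical MAP fitting

Parameters are estimated on an unconstrained scale (logit for α, log for
the non-negative betas, identity for β_rep). A Gaussian population prior
with full covariance is placed on the stacked two-session vector
(10-dim; 5-dim when only one session exists), so the prior carries both
between-subject and between-session structure. Estimation alternates:

* **E-step** — per-subject MAP by L-BFGS-B over the penalized objective
  (session log-likelihoods plus log prior density). The first E-step
  runs `n_fits` optimizations from `n_starts` distinct prior draws
  (desk-scale defaults 50 runs / 10 starts; raise toward 500 runs for a
  heavy-duty fit); later E-steps warm-start from the previous optimum
  plus a few fresh restarts. The Laplace posterior covariance comes from
  a central-difference Hessian at the optimum, ridge-regularized if not
  positive definite.
* **M-step** — prior mean as the average of MAP estimates; covariance as
  the average of squared deviations plus Laplace covariances (the
  standard empirical-Bayes moment update). With attrition, marginal
  blocks are updated from every subject carrying that session and the
  cross-session block from complete subjects only; baseline-only
  subjects are fitted under the 5-dim marginal prior.

EM stops when the prior mean changes by less than `em_tol` (1e-3) in any
coordinate or after `max_em_iter` (40) iterations; an approximate
marginal likelihood is logged per iteration as a monotonicity
diagnostic. A diagonal-covariance mode is available by configuration.

**Chance screen.** The random-choice model (probability ½ for every
observed choice) is the betas-to-zero limit of the hybrid model. The
statistic 2·(data log-likelihood − chance log-likelihood) is referred to
χ² with 5 degrees of freedom per fitted session — all free parameters,
ignoring the boundary constraints on the betas (a documented
simplification that makes the screen conservative). Subjects with
p ≥ 0.05 are excluded from parameter-level analyses but retained for the
behavioural regressions. Because the data log-likelihood is evaluated at
the MAP (not ML) estimate, the statistic can be marginally negative for
random responders under an informative prior; χ² survival then returns
p = 1 and the subject is excluded, which is the intended behaviour.

## Parameter recovery

The recovery experiment draws generating parameters from broad
distributions — α ~ Uniform(0.05, 0.95); log β_MB, log β_MF,
log β_consistency ~ Normal(0, 0.8); β_rep ~ Normal(0.5, 0.7) — simulates
one 200-trial session per subject on a single counterbalanced walk set
(the task's own protocol), refits the whole cohort with the hierarchical
pipeline, and reports Pearson (primary, natural-space) and Spearman
correlations between generating and recovered values, averaging over
datasets per subject when more than one is simulated. The desk-scale
default is 60 subjects × 1 dataset; the correlation for α sits around
0.95 there. Two attenuating forces are worth naming: empirical-Bayes
shrinkage pulls weakly identified subjects (those with small betas,
whose choices carry little information about α) toward the prior mean,
and a single dataset per subject leaves simulation noise in each
recovered value — recovery from a cohort's own fitted (already shrunken)
estimates with many datasets per subject, as in a full-scale
application, yields visibly higher correlations.

## Synthetic cohort

Defaults mirror a two-group study: 30 MUD-like and 31 control-like
subjects, two sessions with follow-up attrition probabilities 7/30 and
5/31, 2% missing responses. Group parameter distributions live on the
unconstrained scale and encode only the reported *directions* of group
differences at moderate effect size — the MUD-like group lower in β_MF
and β_rep and higher in β_consistency; α and β_MB do not differ.
Magnitudes are declared assumptions rather than estimates, and
everything is configurable. Session-2 parameters
correlate 0.7 with session 1 on each coordinate. Reaction times are
log-normal with subject-level locations; pathological subjects can be
injected (high missingness ≈19% of trials, single-key responding ≈97%
same side, fast responders at ≈0.18 s, random choosers). "Same key" is
interpreted as the same response *side* pooled over both stages.
Attrition is missing-at-random within group. Substance-use metadata for
the MUD-like group link frequency-of-use monotonically to
β_consistency, which is all the correlation/regression analyses need for
an end-to-end oracle; clinical realism is out of scope.

What passing tests on this generator do **not** show: real participants
differ from the generator in ways it does not emulate — parameter
distributions are not Gaussian on the transformed scale, missingness is
not at random, reaction times carry sequential structure, and group
differences may load on several parameters at once. Tests against the
generator certify the machinery (coding, fitting, inference), not any
clinical claim.

## Behavioural statistics

Stay/switch records are built from consecutive trial pairs whose
earlier member is complete and whose later member has a stage-1 choice;
pairs spanning a missing trial are dropped. Previous Win and Previous
Transition are effect-coded −1/+1; Group is control = 0, MUD = 1 and
Time is baseline = 0, follow-up = 1, chosen so the sign conventions
customary in this literature (negative Group, negative Group × Previous
Win for a reward-insensitive clinical group) are directionally
reproducible. The baseline model is the full
Win × Transition × Group factorial with a random intercept per
participant; the longitudinal model crosses every term with Time and
adds an independent random Time slope per participant.

No installed Python package offers frequentist logistic mixed models, so
`glmm.py` implements maximum likelihood with per-group *adaptive*
Gauss–Hermite quadrature (Newton mode search, curvature-scaled nodes; 12
nodes by default, a 2-D product rule for the slope model with
uncorrelated intercept and slope). Wald standard errors come from the
numerical Hessian of the marginal likelihood. The implementation is
cross-checked against lme4::glmer (nAGQ=12) in the test suite and agrees
to two decimals on coefficients and standard errors. Constant outcomes —
overall or within a design cell — raise a separation error naming the
cell.

Post-hoc marginal means are computed on the linear-predictor scale for
the four Group × Previous-Win cells with Previous Transition averaged
out (its ±1 coding cancels at 0); the default contrast family is all six
pairwise comparisons, adjusted by the studentized-range (Tukey)
distribution with k = 4; a family of one is returned unadjusted. Group
comparisons of fitted parameters use two-sided Mann-Whitney U (exact for
group sizes ≤ 20, normal approximation otherwise; rank-biserial effect
size). Group-by-Time ANOVAs use pingouin's mixed ANOVA, dropping
subjects without both sessions. The substance-use analyses compute a
Spearman matrix over parameters, use variables and the
days-since-last-use covariate, then per use variable an OLS regression
of the mean-centred outcome on the five parameters plus the covariate,
with variance-inflation factors; configurable outlier limits drop rows
exceeding a cap on any involved column before fitting. Beyond the Tukey
post-hocs no multiple-testing adjustment is applied, matching the
analysis battery this mirrors. Bayes-factor analogues are out of scope;
frequentist tests with effect sizes stand in.

## Problem sizes and calibration

Desk-scale sizes used by the test suite and the acceptance script, as
the package's own choices: recovery at 60 subjects × 1 dataset;
chance-screen rates over 100 simulated model-free agents; behavioural
fingerprints from 10 + 10 subject cohorts at 200 trials; type-I-error
calibration over 500 replicates of 15 + 15 subject null cohorts at 120
trials. Calibration cohorts vary subjects only in β_rep — the axis the
stay model's random intercept absorbs — because unmodelled
between-subject *slope* heterogeneity (e.g. in β_MF) genuinely inflates
Wald tests of interaction terms in a random-intercept model; that
inflation is a property of the model specification shared with the
analyses this package mirrors, not an implementation artifact, and the
calibration isolates the implementation.

## Known limitations

* Alternative hybrid formulations (mixture-weight ω, eligibility
  traces, expectation-based model-based values) are not implemented; the
  model-based value rule is isolated in one function to permit
  extension.
* The chance-screen degrees of freedom ignore boundary effects.
* The longitudinal random effects are uncorrelated (intercept ⟂ slope).
* Wald inference for the mixed models is asymptotic in the number of
  subjects; with very small cohorts it runs slightly anticonservative.
* EM maximizes an approximate (Laplace) marginal likelihood; no full
  posterior sampling is provided.
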