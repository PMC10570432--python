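# Methods

## The task economy

The Iowa Gambling Task presents four decks. On every card a deck pays a fixed
gain and, on some cards, a penalty. The package implements the Japanese-yen
variant: decks A and B pay +10,000 yen per card and lose 125,000 yen per
10-card cycle (A spreads its penalty over 5 cards, B concentrates it in one);
decks C and D pay +5,000 per card and lose 25,000 per cycle (C over 5 cards, D
in one). A and B are therefore net-losing (−2,500/card on average) and C and D
net-winning (+2,500/card). The participant starts with a 200,000-yen loan and
draws 100 cards, scored in five blocks of 20 as the net score
(#C + #D) − (#A + #B) per block.

Only per-cycle totals and loss counts are fixed by the published task
description; the position and size of individual penalties inside a cycle are
taken from the original deck layout (A: −150/−300/−200/−250/−350 at cards
3/5/7/9/10; B: −1,250 at card 9; C: −50/−50/−50/−25/−75 at 3/5/7/9/10; D: −250
at card 10) scaled ×100 into yen, which reproduces the printed totals exactly.
`PayoffSchedule.shuffled_losses(seed)` permutes penalty positions within each
cycle for sensitivity checks. Decks are treated as inexhaustible (the cycle
wraps), since 100 draws from one deck would exhaust a physical 40-card deck
and no depletion rule is part of the task description.

Losses are stored as non-positive numbers; a trial's net gain is
`x(t) = win + loss = win − |loss|`.

## The cognitive model

PVL-DecayRI has four subject-level parameters:

* feedback sensitivity `alpha ∈ [0, 1]` — exponent of the power utility
  `u(t) = x(t)^alpha` for gains and `−lam·|x(t)|^alpha` for losses;
* loss aversion `lam ∈ [0, 5]` — multiplicative weight on loss utilities;
* recency `A ∈ (0, 1)` — decay factor applied to **all** deck expectancies each
  trial, `E_j(t) = A·E_j(t−1) + I_j(t)·u(t)`, where `I_j` indicates the chosen
  deck. Low `A` = rapid forgetting. (Some model variants decay only unchosen
  decks; this package implements the all-deck decay rule.)
* response consistency `c ∈ [0, 5]` — softmax sharpness through
  `theta = 3^c − 1`; choice probabilities are
  `P(j) ∝ exp(theta·E_j)`. `c = 0` gives `theta = 0` and uniform choice.

Numerical choices: expectancies initialise to zero, so the first choice is
uniform (probability 1/4) for any parameter values — a testable anchor.
`theta` is constant per subject (the formula has no trial dependence). The
softmax subtracts the maximum of `theta·E` before exponentiating so no
parameter combination can overflow. Outcomes are divided by the schedule's
scale divisor (default 10,000, i.e. +10,000 yen → +1.0) before the utility;
the power law is unit-sensitive and raw yen magnitudes would push `alpha`
toward degenerate values. `u(0) = 0` is enforced explicitly, including at
`alpha = 0` where `0^0` would otherwise give 1. Wins and losses on the same
card are netted into a single `x(t)` before the utility is applied.

The likelihood of a trial sequence is the product over trials of the softmax
probability of the observed choice given the expectancies built from the
*realised* outcomes of earlier trials. Because outcomes are deterministic
given choices, sequence probabilities over all `4^n` choice paths sum to 1 —
the brute-force normalisation oracle used in the tests.

## Estimation

Parameters are estimated on probit-transformed coordinates
(`alpha = Φ(z₁)`, `lam = 5Φ(z₂)`, `A = Φ(z₃)`, `c = 5Φ(z₄)`), with
independent standard-normal priors on each `z` by default — weakly
informative, centred on the middle of each box. `PriorSpec` overrides the
hyperparameters, drops the prior entirely (`flat=True`, turning MAP into
MLE), or builds empirical-Bayes priors from first-pass estimates
(`PriorSpec.from_estimates`), which is the package's two-stage stand-in for a
full joint hierarchical model.

* **MAP** (`fit_map`): multi-start L-BFGS-B, 8 restarts by default (first
  start at the prior mean, the rest standard-normal, seeded). Deterministic
  under a fixed seed; ties between optima go to the first found. Used as the
  fast oracle in recovery and power studies.
* **MCMC** (`fit_mcmc`): an affine-invariant ensemble sampler (emcee) per
  subject, walkers initialised around a quick MAP estimate. Walkers serve as
  chains for split R-hat and bulk ESS (computed with arviz); because ensemble
  walkers are not independent chains, these diagnostics are conservative
  screens, not exact Gelman-Rubin statistics. R-hat > 1.05 or ESS < 100 flags
  the subject (`converged=False` and a warning) without aborting. Point
  estimates are posterior means.

Whether published group values of this kind come from posterior means or
modes is generally ambiguous; this package reports posterior means for MCMC
and the MAP point for the optimisation path, and says which column is which.

Recovery behaviour worth knowing: `A` and `c` (the discriminating parameters)
recover well at 100 trials when agents span the boxes; `lam` is weakly
identified (loss frequency varies little within a deck cycle) and `alpha`
intermediate. With near-random agents (`c` close to 0) no parameter is
identifiable from choices — a property of the model, not the fitter.

## The synthetic cohort

The generator emulates a case-control study with known ground truth: two
groups (patient-like "OCD", control-like "HC"), 47 subjects each, 100 trials
per subject. True parameters are drawn from normal distributions with the
published group means/SDs (e.g. recency 0.290 (0.177) vs 0.530 (0.213);
consistency 0.393 (0.280) vs 0.645 (0.305)), truncated to the parameter
boxes. Truncation shifts the realised mean slightly from the nominal one
(about +0.02 for patient-group recency, whose lower bound sits 1.6 SD below
the mean; under 0.01 for the control group); the nominal moments are treated
as the targets and the bias is accepted rather than re-calibrated away.

Severity scores emulate an obsession subscale (integers 0–20). Patient
severities couple to the recency parameter through a Gaussian copula: normal
scores of the recency ranks are mixed with independent noise at Pearson
correlation `2·sin(π·ρ_s/6)` — the bivariate-normal value whose implied rank
correlation equals the Spearman target (0.334 by default) — then pushed
through a normal marginal (mean 11.85, SD 3.49), rounded and clipped.
Rounding introduces ties that attenuate the realised Spearman by well under
0.01 at these moments. Control severities are independent draws from a
near-zero marginal (0.04, SD 0.20), floored at 0.

Seeding: the master seed spawns child seeds keyed by (seed, stream, subject
index), so enlarging a cohort leaves existing subjects' draws unchanged, and
identical configs produce byte-identical output files.

What the generator does **not** emulate: real response processes beyond
PVL-DecayRI (perseveration, exploration bonuses, deck-position memory),
item-level severity structure, comorbidity covariates, or any demographic
variable. Passing tests therefore show that the pipeline is self-consistent —
the estimator recovers what the generative model put in — not that the model
is the right description of human choices.

## Statistics

* Mann-Whitney U: midranks; the reported U is `min(U₁, U₂)`; Z uses the
  normal approximation with the tie correction and a continuity correction;
  effect size `r = |Z|/√N` (the definition consistent with the published
  Z/r triplets, e.g. Z = 5.033 at N = 94 → r = 0.52). When the pooled sample
  is ≤ 20 with no ties, the p-value comes from the exact permutation
  distribution instead. Approximation quality note: two-sided
  continuity-corrected normal p can deviate from the exact p by up to ~0.09
  at n₁ = n₂ = 2, ~0.04 at 3, ~0.02 at 4; the automatic exact path makes this
  moot for small samples. All-identical samples return a flagged degenerate
  result (Z, p = NaN).
* Spearman: Pearson correlation of midranks, two-sided p via the
  t-approximation (scipy); zero rank variance returns a degenerate result.
* Net-score ANOVA: two-way mixed design (group between, block within) via
  pingouin, uncorrected df by default (no sphericity correction, matching the
  uncorrected-df reporting convention; Greenhouse-Geisser epsilon is in the
  returned table for readers who want it). Bonferroni-adjusted pairwise block
  comparisons; simple main effects as one-way ANOVA of group within each
  block and one-way repeated-measures ANOVA of block within each group, with
  univariate df conventions (a MANOVA-style simple-effect df would differ;
  the convention used here is the one stated).
* t tests: Student pooled or Welch unpooled with Welch-Satterthwaite df.
* No multiple-testing correction is applied across the four parameter
  contrasts, matching the analysis design being emulated.

## Problem sizes used in validation

Recovery studies use 40 agents × 100 trials with Latin-hypercube truth
spanning the boxes; the power property uses 10 replicate cohorts of 47 + 47
subjects fitted in MAP mode; copula calibration uses n = 10,000 draws;
likelihood normalisation enumerates all 4³ three-trial sequences; the
Mann-Whitney oracle enumerates all labelings for n₁ = n₂ ≤ 6. These sizes
give stable checks while keeping the full validation suite runnable on a
laptop in a few minutes.

## Known limitations

* Only PVL-DecayRI is implemented — no Delta-rule, EVL, VPP or ORL variants,
  and no model-comparison machinery (WAIC/LOO).
* The MCMC path samples subjects independently; hierarchy enters only through
  empirical-Bayes priors, not a joint model.
* `lam` recovery is weak at 100 trials; group contrasts on `lam` from fitted
  values should be interpreted accordingly.
* The exact Mann-Whitney path requires tie-free data; tied small samples fall
  back to the tie-corrected normal approximation.
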