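# Methods

This note documents the models implemented in `metaconf`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the design decisions taken where more than one reasonable
reading existed.

## The confidence forced-choice (CFC) paradigm

An observer makes two perceptual decisions (a *pair*) and then reports which
of the two is more likely to be correct.  This yields confidence data without
ratings and without criterion confounds: the analysis only needs the binary
forced choice per pair.

## Generative model

All confidence modelling happens in *normalized* units — stimulus strengths
recentered on the perceptual criterion and rescaled by the psychometric
slope, so that sensory evidence has unit variance:

- Sensory stage: `s = mu_s + eps_s`, `eps_s ~ N(0, sigma_s^2)`; response
  `r = sign(s - c)` with criterion `c`.
- Ideal confidence observer: confidence evidence `w = (s - c) / sigma_s`,
  i.e. exactly the decision evidence, normalized.
- Human confidence evidence:
  `w = alpha * mu~ + (1 - alpha) * (s - c) / sigma_s + eps_c`, with
  confidence noise `eps_c ~ N(0, sigma_c^2)` and confidence boost
  `alpha` in [0, 1], where `mu~ = (mu_s - c) / sigma_s`.
- Forced choice: interval 1 is chosen when `w1 r1 + b > w2 r2` (`b` is an
  additive interval bias); exact ties are broken by a fair coin, a
  probability-zero event except in the degenerate noiseless boost-1 family.

The boost term uses the *normalized* stimulus strength so that both terms of
`w` share units.  This choice only affects the scale on which `alpha` mixes;
it is flagged because the source text does not state the scale.

Confidence reuses the same sensory sample that produced the response
(single-channel assumption).  When a trial table lacks the latent sample,
`simulate_confidence` re-draws it from the truncated Gaussian consistent
with the recorded response, which preserves the joint law.

## Pair designs

`build_pair_design` enumerates ordered combinations of signed stimulus
levels: a base count per combination, extra pairs for matched unsigned
strength, and extra pairs for strengths one magnitude-step apart (pairs of
very unequal difficulty produce ceiling confidence choices and are
deliberately rare).  The literal counting rules for the laboratory design
yield 572 pairs, while the design is documented as totalling 576 pairs /
1,152 trials; the shipped `exp1_design` therefore applies a count-override
of one extra pair on each of the four ordered combinations of zero with the
smallest nonzero magnitude.  The override table is exposed so other
resolutions of this ambiguity can be expressed.  The online design
(167 pairs / 334 trials per task) is produced by largest-remainder scaling
of the exp1 counts, which is deterministic and preserves the design shape.

## Pair-choice probabilities

`pair_choice_probability` returns the exact joint law over the 8 outcomes
(r1, r2, choice).  Conditional on the first interval's evidence, the
remaining two Gaussian dimensions (second-interval evidence and the
difference of confidence noises) collapse analytically into a bivariate
normal CDF, evaluated by a vectorized Owen's-T formula; the outer dimension
is integrated with a Gauss–Legendre rule on the inverse-CDF-transformed
truncated normal (64 nodes by default).  Accuracy is ~1e-5 per outcome
(~1e-4 in the worst case `sigma_c = 0`, where the inner CDF has a kink);
each row of 8 outcomes sums to 1 by construction because choice-2
probabilities are computed as complements within the (r1, r2) cell.  The
degenerate `alpha = 1, sigma_c = 0` family is handled as a deterministic
comparison with 50/50 tie splitting.

The all-noise family used for equivalent noise (`alpha = 1`,
`sigma_c = tau`) has the closed form
`P(r1=a, r2=b, choice=1) = Phi(a mu1) Phi(b mu2) Phi((a mu1 - b mu2) / (tau sqrt(2)))`,
which makes the root-finding and the bootstrap cheap.  The generic
quadrature path reproduces this closed form to 1e-6, which is tested.

## Fitting and efficiency

The model is fit to data aggregated across participants after per-subject
normalization, by maximizing the multinomial likelihood of outcome counts on
a binned strength grid (bin width 0.2 normalized units; the default designs
land exactly on this grid for a typical observer).  `alpha` is optimized
through a logit transform, `sigma_c` on a log scale with floor 1e-4, the
bias unconstrained; L-BFGS-B with multistart.

`sigma_c` and `alpha` trade off along a shallow likelihood ridge (noise
hurts, boost helps; nearly cancelling combinations are close to
observationally equivalent at realistic sample sizes).  Point estimates of
the two parameters are therefore reported with bootstrap intervals, and the
well-identified quantity is confidence *efficiency*:

- `tau2_ideal`: the equivalent-noise variance whose all-noise model matches
  the ideal observer's probability of choosing the interval with the correct
  response (among pairs with exactly one correct response) on the observed
  design.  Zero-strength intervals have no correct answer and count as
  incorrect for this conditioning.
- `tau2_human`: same matching criterion, but applied to the *observed*
  choice accuracy of the data.  Matching the data rather than the fitted
  (sigma_c, alpha) point avoids inheriting the ridge: with ideal synthetic
  data the fitted-point route is biased (~0.95) while the data route is
  calibrated at 1.
- `eta = tau2_ideal / tau2_human`; 1 for the ideal observer, below 1 when
  confidence noise dominates, above 1 when post-decisional information
  (boost) dominates.

The likelihood-matching alternative for `tau` can be expressed with
`fit_cfc(..., fix_alpha=1.0)`.

Uncertainty comes from a participant bootstrap (default 1,000 resamples,
configurable): participants are resampled with replacement, data
re-aggregated and re-fit (warm-started at the full-sample estimate), and
`tau2_human` re-matched to the resample's accuracy.  The equivalent-noise
matching curve uses the full-sample design throughout, so resamples differ
only through their data, not through design jitter.

## Hierarchical Bayesian effect sizes

Group-level CFC parameters have no per-participant estimates, so the
bootstrap distribution stands in for the sample distribution: `N` central
quantiles ((k-0.5)/N, order-statistic method, no interpolation) form `N`
pseudo-subjects.

For a within-subject contrast the two conditions are bootstrapped with the
*same* resample stream, and the pseudo-subject effects are quantiles of the
paired difference distribution.  Pairing the marginal quantiles of two
independent bootstraps would collapse the effect spread (two sorted margins
differ almost deterministically rank by rank) and inflate the standardized
effect size; this failure mode was observed and is the reason for the paired
construction.  Because the bootstrap spread approximates the standard error
of the aggregated estimate, the resulting `delta` behaves like a
standardized z-quantity for the contrast; its null distribution is not
pinned at zero, which the tests treat accordingly (discriminative checks at
pipeline level; proper coverage calibration at model level with data
generated from the model itself).

Models (uniform priors over wide supports: means/shapes in (0, 100],
`mu_x` in [-50, 50], `sigma_x` in (0, 50]):

- Within: `A_i ~ family(mean, shape)`, `x_i = B_i - A_i ~ N(mu_x, sigma_x^2)`,
  `delta = mu_x / sigma_x` sample-wise.
- Between: group means `m` and `m + delta * sigma_AB`, with `sigma_AB^2` the
  combined variance of the two groups (computed from data, held fixed).
- Families: gamma in a mean–shape parameterization and beta in
  mean–precision (effects act on means); beta-family values are mapped to
  the logit scale first, since additive effects could otherwise leave (0, 1),
  and `delta` is then an effect size in logit units.

Posteriors are drawn by coordinate-wise slice sampling with stepping-out and
shrinkage (12,000 iterations over 3 chains, 1,000 burn-in, thinning 3 by
default).  Summaries: posterior mean of `delta`, the narrowest interval
containing 95% of draws (HDI), split-R-hat and effective sample size via
ArviZ, and a Savage–Dickey Bayes factor `BF10 = p_prior(0) / p_post(0)` with
a unit-information Normal(0, 1) prior and a Silverman-bandwidth Gaussian KDE
for the posterior density at zero (BF10 above 1 favours an effect).

## Two-stage accumulation simulator

Pre-decision evidence follows `s(t+dt) = s(t) + mu dt + eps`,
`eps ~ N(0, sigma^2 dt)`, absorbed at a collapsing bound
`b(t) = (b0 - floor) exp(-t / tau_b) + floor`.  The Euler scheme alone has an
O(sqrt(dt)) first-passage bias; each step therefore also samples in-step
barrier touches from the Brownian-bridge crossing probability
`exp(-2 (b - s_t)(b - s_{t+dt}) / (sigma^2 dt))`, after which the
constant-bound hitting probability matches the closed form
`1 / (1 + exp(-2 mu a / sigma^2))` within Monte-Carlo error even at
`dt = 1 ms`.

After commitment, accumulation continues with drift `lambda * mu`
(permeability `lambda = 1`: same signal-to-noise as pre-decision;
`lambda = 0`: noise only) and unchanged diffusion noise until the next
decision is cued: the window is nondecision time + any remaining wait for
the response cue + a 200 ms inter-trial interval.  A backward mask
multiplies the diffusion SD from mask onset (500 ms after stimulus offset)
onward.  Because no bound acts post-decision, the increment is exactly
Gaussian and is sampled in closed form (mean `lambda mu T`, variance
`sigma^2` integrated over the window, with the mask factor where active).

Defaults (`sigma = 0.009 / sqrt(ms)`, drift gain `1.5e-4` per unit stimulus
strength and ms, `b0 = 1`, `tau_b = 450 ms`, floor 0.15, NDT 300 +/- 30 ms)
were calibrated once so that median RTs span roughly 700–1,250 ms across the
design's strengths, accuracies are psychophysically plausible, and the
post-decision noise does not completely swamp the at-bound evidence; they
are this package's values, not estimates from any data set.

Predicted confidence efficiency reuses the equivalent-noise machinery:
simulated choices define an effective psychometric function (fit, then
normalize), confidence picks the interval with the larger final evidence
signed by its own choice, and the simulated confidence accuracy is matched
within the all-noise family against the decision-time ideal.

For the RT-group prediction, observers differ by a *time-rescaling* factor
`g` (deterministic log-normal quantile ladder, spread 0.9 by default): drift
is scaled by `g` and the diffusion variance by `g`, so accuracy is invariant
while speed scales like `1/g` — slower responders accumulate a lower
signal-to-noise ratio for a longer duration with flat perceptual
sensitivity across speed groups, matching the empirical observation the
prediction targets.  Drift-only heterogeneity was tried first and rejected:
it makes sensitivity vary strongly across RT groups and does not produce the
decreasing high-minus-low efficiency pattern.  The two task regimes
(`lambda = 1` vs `lambda = 0`) share each observer's noise stream (common
random numbers), which is both conceptually right — they are counterfactual
readouts of the same trials — and a large variance reduction for the
between-task difference.  With shared timing and noise, the `lambda = 1`
readout equals the `lambda = 0` readout plus a truth-aligned deterministic
term, so its accuracy dominates pointwise: the simulator predicts the
high-minus-low difference shrinking toward zero for slow responders, not a
sign flip; a sign flip would need between-task parameter differences that
are not modelled here.

## What the synthetic generator does and does not emulate

It reproduces: the pairing designs and their printed totals, Gaussian
sensory evidence with criterion, confidence noise/boost/bias, condition
effects as parameter shifts, exclusion-triggering behavior (flat responders,
biased confidence), and optional log-normal nuisance RTs
(accumulation-derived RTs come from the simulator).

It does not emulate: stimulus rendering, task-irrelevant cues (held neutral,
as their measured influence was nil), learning or drift across blocks,
non-Gaussian sensory noise, or per-trial lapses.  Passing tests therefore
validate the analysis chain under the model's own assumptions; they cannot
certify robustness to violations real data might show.

## Numerical conventions and degenerate inputs

- Psychometric fits: ML on (mu, log sigma), L-BFGS-B, multistart from
  probit-linearized moments; all-identical responses return an explicit
  flat fit with sigma pinned at 20x the stimulus range, flagged, so the
  slope exclusion rule catches it.  Exclusion thresholds are strict
  inequalities ("exceeds", "more than"); sigma exactly at half the range is
  retained, exactly 78% bias is retained.
- RT terciles: stable sort with ties broken by participant id.
- Equivalent-noise root-finding: Brent on log tau in [1e-4, 1e3]; an
  accuracy outside the family's achievable range raises with the range.
- Slice sampler: stepping-out capped at 100 widths; shrinkage to an
  interval below 1e-300 returns the current point.
- Problem sizes in tests and in the acceptance script (cohorts of 100–200
  observers at 167 pairs, 150 bootstrap resamples, 1e5–2e6 Monte-Carlo
  draws, 15 simulated observers x 2,500 pairs for the RT terciles) are the
  package's chosen report sizes; all are configurable upward.

## Known limitations

- `sigma_c` and `alpha` are weakly separated by design; only their bootstrap
  distributions and the derived efficiency should be interpreted.
- The bootstrap-pseudo-subject effect size inherits the scale of the
  aggregated estimate's standard error rather than true between-subject
  heterogeneity; treat `delta` from this route as a standardized contrast,
  not a population effect size.
- The accumulation simulator is a prediction engine, not a fitted model; its
  parameter defaults are calibrated, not estimated, and it does not fit RT
  distributions.
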