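# metaconf

Modelling and simulation tools for **perceptual metacognition measured with
confidence forced choice (CFC)**: after every two perceptual decisions, an
observer reports which of the two is more likely to be correct.  The package
is aimed at psychophysicists who want to quantify how *efficiently*
confidence tracks accuracy — separately from perceptual sensitivity — and at
modellers exploring post-decisional evidence accumulation as the mechanism
behind confidence.

## What it computes

**Confidence noise-and-boost model.**  In criterion-centered, noise-scaled
units, interval *i* of a pair carries sensory evidence
`s_i ~ N(mu_i, 1)` and response `r_i = sign(s_i)`; the confidence evidence is

```
w_i = alpha * mu_i + (1 - alpha) * s_i + eps_c,  eps_c ~ N(0, sigma_c^2)
```

and interval 1 is chosen when `w_1 r_1 + b > w_2 r_2`.  `sigma_c` is
confidence noise, `alpha` in [0, 1] is confidence boost (information not
used by the perceptual decision), `b` an interval bias.  The package
computes the exact 8-outcome law of a pair by deterministic integration,
fits (sigma_c, alpha, b) to aggregated data by maximum likelihood, and
derives **confidence efficiency**

```
eta = tau_ideal^2 / tau_human^2
```

via equivalent noise: the all-noise model (`alpha = 1`, `sigma_c = tau`)
matched to the observed probability of choosing the interval with the
correct response.  `eta = 1` for the ideal confidence observer (who reuses
exactly the decision evidence), below 1 when confidence noise dominates,
above 1 when post-decisional information dominates.  Uncertainty comes from
a participant bootstrap.

**Psychometrics and screening.**  Cumulative-Gaussian fits
`P(+1 | x) = Phi((x - mu)/sigma)`, normalization of stimulus strengths per
observer, exclusion rules (psychometric slope above half the stimulus range;
one confidence response on more than 78% of pairs), and median-RT summaries
with tercile splits.

**Hierarchical Bayesian effect sizes.**  Bootstrap quantiles form
pseudo-subjects; within-subject effects `x_i ~ N(mu_x, sigma_x^2)` give
`delta = mu_x / sigma_x` (gamma/beta/normal likelihood families), sampled by
a slice sampler (stepping-out + shrinkage), summarised by the 95% highest
density interval and a Savage–Dickey Bayes factor under a unit-information
Normal(0, 1) prior.

**Two-stage accumulation simulator.**  Evidence drifts to a collapsing
bound (decision + RT, with a Brownian-bridge correction for first-passage
accuracy); accumulation then continues with drift scaled by a permeability
`lambda` (1 = same signal-to-noise as pre-decision, 0 = noise only) until
the next decision is cued, and the final evidence drives the confidence
choice.  This turns timing manipulations (response-cue delay, backward
mask) into predicted efficiencies.

**Synthetic data.**  Generative observers and the pairing designs
(laboratory design: 576 pairs / 1,152 trials; online design: 167 pairs /
334 trials per task) make every stage testable without any data download.

## Worked example

```python
import numpy as np, pandas as pd
import metaconf as mc

# one synthetic cohort: 40 observers, online design, known parameters
design = mc.online_design()
rng = np.random.default_rng(7)
records = []
for i in range(40):
    obs = mc.GenerativeObserver(sigma_s=3.5, criterion=0.0, sigma_c=0.5,
                                alpha=0.2, id=f"obs{i:02d}")
    trials = mc.simulate_trials(design, obs, rng)
    pairs = mc.simulate_confidence(trials, obs, rng)
    fit = mc.fit_psychometric(trials)                    # mu, sigma
    trials = mc.normalize_strengths(trials, fit)         # criterion units
    records.append(mc.cfc_model.pair_records(trials, pairs))

rec = pd.concat(records, ignore_index=True)
cfc = mc.fit_cfc(mc.aggregate_pairs(rec))
boot = mc.bootstrap_fit(rec, n_boot=200, seed=1, start=cfc.params)
print(f"sigma_c = {cfc.params.sigma_c:.2f}  "
      f"[{boot.ci95['sigma_c'][0]:.2f}, {boot.ci95['sigma_c'][1]:.2f}]")
print(f"alpha   = {cfc.params.alpha:.2f}  "
      f"[{boot.ci95['alpha'][0]:.2f}, {boot.ci95['alpha'][1]:.2f}]")
print(f"eta     = {cfc.efficiency:.2f}  "
      f"[{boot.ci95['efficiency'][0]:.2f}, {boot.ci95['efficiency'][1]:.2f}]")
```

prints

```
sigma_c = 1.10  [0.77, 1.32]
alpha   = 0.71  [0.36, 1.00]
eta     = 1.33  [1.04, 1.68]
```

The cohort was generated with `sigma_c = 0.5`, `alpha = 0.2`, which imply
`eta = 1.34` on this design.  The point estimates sit elsewhere on the known
noise/boost trade-off ridge — the two parameters are only weakly separated,
which is why they are reported with bootstrap intervals — while the
well-identified quantity, confidence efficiency, is recovered almost exactly
(1.33 vs 1.34): the simulated observers' boost outweighs their confidence
noise, so their confidence is better than the ideal observer's evidence
alone would allow.

The same chain runs from the command line (`metaconf simulate`,
`metaconf fit-cfc`, `metaconf effects`, `metaconf simulate-accumulation`,
`metaconf run`), reading YAML configs and writing CSV/JSON/YAML artifacts.

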