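"""Hierarchical Bayesian effect sizes on bootstrap pseudo-subjects.

Group-level CFC parameters are estimated on aggregated data, so their
participant-resampling bootstrap distribution stands in for the sample
distribution.  ``N`` central quantiles of the bootstrap distribution (one per
participant) form pseudo-subjects for hierarchical modelling.

Within-subject comparisons assume each subject's value in condition B differs
from condition A by an effect ``x_i ~ Normal(mu_x, sigma_x^2)``; the effect
size is ``delta = mu_x / sigma_x``.  Between-subject comparisons model
``delta`` directly through the difference in group means,
``y = delta * sigma_AB``, with ``sigma_AB^2`` the combined variance of the
two groups.  Parameter values are described by a gamma likelihood for
positive quantities (efficiency, confidence noise), a beta likelihood for
confidence boost (with effects on the logit scale), or a normal likelihood
(slopes, RTs).  Priors are uniform over wide supports.

Posteriors are sampled by coordinate-wise slice sampling with stepping-out
and shrinkage.  Evidence against the no-effect null is summarised by the 95%
highest density interval of delta and by a Savage-Dickey Bayes factor under a
unit-information Normal(0, 1) prior on delta.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np
from scipy.special import betaln, gammaln, logit
from scipy.stats import gaussian_kde, norm

__all__ = [
    "PseudoSubjectData", "EffectPosterior", "MCMCConfig",
    "quantile_pseudosubjects", "paired_pseudosubjects", "slice_sample",
    "fit_within_effect", "fit_between_effect", "hdi", "savage_dickey_bf",
]

Family = Literal["gamma", "beta", "normal"]

# uniform prior supports: wide relative to the O(1) magnitudes of the
# parameters being compared (efficiencies, noise SDs, logit boosts)
_SUPPORT = {
    "mean": (1e-6, 100.0),
    "shape": (1e-3, 1e4),
    "scale": (1e-6, 100.0),
    "mu_x": (-50.0, 50.0),
    "sigma_x": (1e-6, 50.0),
    "delta": (-50.0, 50.0),
}


@dataclass(frozen=True)
class MCMCConfig:
    """Total samples are split over independent chains; burn-in and thinning
    apply per chain."""

    n_samples: int = 12000
    n_chains: int = 3
    burn_in: int = 1000
    thin: int = 3

    @property
    def per_chain(self) -> int:
        return self.n_samples // self.n_chains


@dataclass(frozen=True)
class PseudoSubjectData:
    values_a: np.ndarray
    values_b: np.ndarray
    family: Family = "gamma"

    def __post_init__(self) -> None:
        a = np.asarray(self.values_a, float)
        b = np.asarray(self.values_b, float)
        object.__setattr__(self, "values_a", a)
        object.__setattr__(self, "values_b", b)
        if a.size != b.size or a.size < 2:
            raise ValueError("need paired values with N >= 2")
        # only condition A carries the family likelihood in the within model;
        # condition B enters through the additive effect
        if self.family == "gamma" and a.min() <= 0:
            raise ValueError("gamma family requires positive values")
        if self.family == "beta" and not (
                0 < a.min() and a.max() < 1 and 0 < b.min() and b.max() < 1):
            raise ValueError("beta family requires values in (0, 1)")


@dataclass(frozen=True)
class EffectPosterior:
    """Posterior of an effect-size comparison.

    ``delta_samples`` has shape (chains, draws); summaries are over the
    pooled draws.
    """

    delta_samples: np.ndarray
    posterior_mean: float
    hdi_95: tuple[float, float]
    bf10: float
    config: MCMCConfig
    param_samples: dict[str, np.ndarray] = field(default_factory=dict)
    ess: float = float("nan")
    rhat: float = float("nan")


def quantile_pseudosubjects(bootstrap: np.ndarray, n: int) -> np.ndarray:
    """``n`` equally spaced central quantiles (k - 0.5)/n of a bootstrap
    distribution, one pseudo-subject per participant."""
    boot = np.asarray(bootstrap, float)
    if n < 1:
        raise ValueError("n must be >= 1")
    if boot.size < n:
        raise ValueError("bootstrap sample smaller than requested N")
    q = (np.arange(1, n + 1) - 0.5) / n
    # order-statistic quantiles (no interpolation) so a monotone transform
    # of the bootstrap sample transforms the pseudo-subjects identically
    return np.quantile(boot, q, method="inverted_cdf")


def paired_pseudosubjects(boot_a: np.ndarray, boot_b: np.ndarray, n: int,
                          family: Family = "gamma") -> PseudoSubjectData:
    """Pseudo-subjects for a within-subject contrast from paired bootstraps.

    ``boot_a`` and ``boot_b`` must come from the same participant resamples
    (one joint bootstrap), so their element-wise difference is the bootstrap
    distribution of the condition effect.  Condition-A pseudo-subjects are
    quantiles of ``boot_a``; the paired effect of pseudo-subject ``i`` is the
    matching quantile of ``boot_b - boot_a``.  Pairing the marginal quantiles
    of two independent bootstraps instead would collapse the effect spread
    and inflate the standardized effect size.
    """
    a = np.asarray(boot_a, float)
    b = np.asarray(boot_b, float)
    if a.size != b.size:
        raise ValueError("paired bootstraps must have equal length")
    q_a = quantile_pseudosubjects(a, n)
    q_x = quantile_pseudosubjects(b - a, n)
    return PseudoSubjectData(q_a, q_a + q_x, family=family)


# ---------------------------------------------------------------------------
# slice sampler
# ---------------------------------------------------------------------------

def _slice_update(logpdf, x: np.ndarray, logp: float, dim: int, width: float,
                  rng: np.random.Generator, max_steps: int = 100):
    """One univariate slice-sampling update (stepping-out + shrinkage)."""
    y = logp + np.log(rng.uniform())
    x0 = x[dim]
    lo = x0 - width * rng.uniform()
    hi = lo + width

    def at(v):
        x[dim] = v
        return logpdf(x)

    steps = 0
    while at(lo) > y and steps < max_steps:
        lo -= width
        steps += 1
    steps = 0
    while at(hi) > y and steps < max_steps:
        hi += width
        steps += 1
    while True:
        v = rng.uniform(lo, hi)
        lp = at(v)
        if lp > y:
            return v, lp
        if v < x0:
            lo = v
        else:
            hi = v
        if hi - lo < 1e-300:  # pathological shrink; stay put
            x[dim] = x0
            return x0, logp


def slice_sample(log_density: Callable[[np.ndarray], float],
                 init: np.ndarray, n_samples: int = 12000, n_chains: int = 3,
                 burn_in: int = 1000, thin: int = 3,
                 widths: np.ndarray | float = 1.0,
                 seed: int | np.random.Generator | None = None) -> np.ndarray:
    """Coordinate-wise slice sampling of an unnormalized log density.

    ``n_samples`` iterations are divided over ``n_chains`` independent
    chains; each chain discards ``burn_in`` iterations and keeps every
    ``thin``-th of the rest.  Returns an array (n_chains, kept, dim).
    """
    rng = np.random.default_rng(seed)
    init = np.atleast_1d(np.asarray(init, float))
    dim = init.size
    widths = np.broadcast_to(np.asarray(widths, float), (dim,))
    lp0 = float(log_density(init))
    if not np.isfinite(lp0):
        raise ValueError("log density not finite at init")
    per_chain = n_samples // n_chains
    if per_chain <= burn_in:
        raise ValueError("burn_in consumes every sample of a chain")

    chains = []
    for _ in range(n_chains):
        x = init.copy()
        # jitter starts so chains are independent explorations
        for d in range(dim):
            for _ in range(5):
                cand = x.copy()
                cand[d] += 0.1 * widths[d] * rng.standard_normal()
                if np.isfinite(log_density(cand)):
                    x = cand
                    break
        lp = float(log_density(x))
        kept = []
        for it in range(per_chain):
            for d in range(dim):
                v, lp = _slice_update(log_density, x, lp, d, widths[d], rng)
                x[d] = v
            if it >= burn_in and (it - burn_in) % thin == 0:
                kept.append(x.copy())
        chains.append(np.array(kept))
    return np.stack(chains)


# ---------------------------------------------------------------------------
# likelihood families
# ---------------------------------------------------------------------------

def _gamma_logpdf_mean_shape(x: np.ndarray, mean: float, shape: float) -> float:
    """Gamma density parameterized by mean and shape (rate = shape/mean)."""
    if mean <= 0 or shape <= 0:
        return -np.inf
    rate = shape / mean
    return float((shape * np.log(rate) - gammaln(shape)
                  + (shape - 1) * np.log(x) - rate * x).sum())


def _beta_logpdf_mean_precision(x: np.ndarray, mean: float,
                                precision: float) -> float:
    if not (0 < mean < 1) or precision <= 0:
        return -np.inf
    a, b = mean * precision, (1 - mean) * precision
    return float(((a - 1) * np.log(x) + (b - 1) * np.log1p(-x)
                  - betaln(a, b)).sum())


def _normal_logpdf(x: np.ndarray, mean: float, sd: float) -> float:
    if sd <= 0:
        return -np.inf
    return float((-0.5 * ((x - mean) / sd) ** 2
                  - np.log(sd) - 0.5 * np.log(2 * np.pi)).sum())


def _in(v: float, key: str) -> bool:
    lo, hi = _SUPPORT[key]
    return lo <= v <= hi


# ---------------------------------------------------------------------------
# within- and between-subject models
# ---------------------------------------------------------------------------

def fit_within_effect(data: PseudoSubjectData,
                      config: MCMCConfig | None = None,
                      seed: int | np.random.Generator | None = None,
                      ) -> EffectPosterior:
    """Paired comparison: A_i ~ family, B_i = A_i + x_i,
    x_i ~ Normal(mu_x, sigma_x^2), delta = mu_x / sigma_x.

    For the beta family both conditions are mapped to the logit scale first
    (additive effects could otherwise leave (0, 1)) and the likelihood of A
    is normal on that scale; delta is an effect size on logit units.
    """
    cfg = config or MCMCConfig()
    fam = data.family
    if fam == "beta":
        a = logit(np.clip(data.values_a, 1e-9, 1 - 1e-9))
        b = logit(np.clip(data.values_b, 1e-9, 1 - 1e-9))
        fam = "normal"
    else:
        a, b = data.values_a, data.values_b
    x = b - a

    if fam == "gamma":
        def loglik_a(theta):
            return _gamma_logpdf_mean_shape(a, theta[0], theta[1])
        p2_key = "shape"
        init2 = max(1e-2, float(a.mean() ** 2 / max(a.var(), 1e-12)))
    else:
        def loglik_a(theta):
            return _normal_logpdf(a, theta[0], theta[1])
        p2_key = "scale"
        init2 = max(1e-3, float(a.std()))
    mean_key = "mu_x" if fam == "normal" else "mean"

    def logpost(theta):
        m, p2, mu_x, sigma_x = theta
        if not (_in(m, mean_key) and _in(p2, p2_key)
                and _in(mu_x, "mu_x") and _in(sigma_x, "sigma_x")):
            return -np.inf
        return loglik_a(theta) + _normal_logpdf(x, mu_x, sigma_x)

    init = np.array([float(a.mean()), init2,
                     float(x.mean()), max(1e-3, float(x.std()))])
    widths = np.array([max(0.1, a.std()), max(0.5, init2 / 2),
                       max(0.05, x.std()), max(0.05, x.std())])
    chains = slice_sample(logpost, init, cfg.n_samples, cfg.n_chains,
                          cfg.burn_in, cfg.thin, widths, seed)
    delta = chains[:, :, 2] / chains[:, :, 3]
    return _summarize(delta, cfg, {
        "mean_a": chains[:, :, 0], p2_key: chains[:, :, 1],
        "mu_x": chains[:, :, 2], "sigma_x": chains[:, :, 3]})


def fit_between_effect(values_a: np.ndarray, values_b: np.ndarray,
                       family: Family = "gamma",
                       config: MCMCConfig | None = None,
                       seed: int | np.random.Generator | None = None,
                       ) -> EffectPosterior:
    """Independent groups: group B's mean exceeds group A's by
    ``delta * sigma_AB`` where ``sigma_AB^2`` is the combined variance of the
    two groups (computed from the data and held fixed)."""
    cfg = config or MCMCConfig()
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if family == "beta":
        a = logit(np.clip(a, 1e-9, 1 - 1e-9))
        b = logit(np.clip(b, 1e-9, 1 - 1e-9))
        family = "normal"
    sigma_ab = float(np.sqrt((a.var(ddof=1) + b.var(ddof=1)) / 2.0))
    if sigma_ab == 0:
        raise ValueError("zero combined variance across groups")

    if family == "gamma":
        def loglik(theta):
            m, p2, delta = theta
            mb = m + delta * sigma_ab
            if mb <= 0:
                return -np.inf
            return (_gamma_logpdf_mean_shape(a, m, p2)
                    + _gamma_logpdf_mean_shape(b, mb, p2))
        p2_key = "shape"
        init2 = max(1e-2, float(a.mean() ** 2 / max(a.var(), 1e-12)))
        mean_key = "mean"
    else:
        def loglik(theta):
            m, p2, delta = theta
            return (_normal_logpdf(a, m, p2)
                    + _normal_logpdf(b, m + delta * sigma_ab, p2))
        p2_key = "scale"
        init2 = max(1e-3, float(np.concatenate([a, b]).std()))
        mean_key = "mu_x"

    def logpost(theta):
        if not (_in(theta[0], mean_key) and _in(theta[1], p2_key)
                and _in(theta[2], "delta")):
            return -np.inf
        return loglik(theta)

    init = np.array([float(a.mean()), init2,
                     float((b.mean() - a.mean()) / sigma_ab)])
    widths = np.array([max(0.1, a.std()), max(0.5, init2 / 2), 0.5])
    chains = slice_sample(logpost, init, cfg.n_samples, cfg.n_chains,
                          cfg.burn_in, cfg.thin, widths, seed)
    delta = chains[:, :, 2]
    return _summarize(delta, cfg, {
        "mean_a": chains[:, :, 0], p2_key: chains[:, :, 1]})


def _summarize(delta: np.ndarray, cfg: MCMCConfig,
               params: dict[str, np.ndarray]) -> EffectPosterior:
    pooled = delta.reshape(-1)
    interval = hdi(pooled, 0.95)
    try:
        bf = savage_dickey_bf(pooled)
    except ValueError:
        bf = float("nan")  # too few draws for density estimation
    ess = rhat = float("nan")
    try:
        import arviz as az
        ess = float(az.ess(delta))
        rhat = float(az.rhat(delta))
    except Exception:
        pass
    return EffectPosterior(delta_samples=delta,
                           posterior_mean=float(pooled.mean()),
                           hdi_95=interval, bf10=bf, config=cfg,
                           param_samples=params, ess=ess, rhat=rhat)


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``mass`` of the samples."""
    s = np.sort(np.asarray(samples, float).reshape(-1))
    if s.size < 4:
        raise ValueError("too few samples for an HDI")
    k = max(1, int(np.ceil(mass * s.size)))
    widths = s[k - 1:] - s[:s.size - k + 1]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def savage_dickey_bf(delta_samples: np.ndarray,
                     prior_sd: float = 1.0) -> float:
    """Savage-Dickey Bayes factor BF10 for the point null delta = 0.

    The unit-information prior is Normal(0, prior_sd^2); the posterior
    density at 0 is a Gaussian kernel estimate (Silverman bandwidth) of the
    MCMC draws.  BF10 > 1 favours an effect.
    """
    pooled = np.asarray(delta_samples, float).reshape(-1)
    if pooled.size < 1000:
        raise ValueError("need >= 1000 samples for density estimation")
    if pooled.std() == 0:
        raise ValueError("degenerate posterior: zero variance")
    post_at_0 = float(gaussian_kde(pooled, bw_method="silverman")(0.0)[0])
    prior_at_0 = float(norm.pdf(0.0, scale=prior_sd))
    if post_at_0 <= 0:
        return float("inf")
    return prior_at_0 / post_at_0
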