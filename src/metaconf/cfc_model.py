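"""The confidence noise-and-boost model for confidence forced choice.

In normalized units (criterion-centered, sensory-noise-scaled) each interval
``i`` of a pair carries evidence ``s_i ~ N(mu_i, 1)``; the perceptual response
is ``r_i = sign(s_i)`` and the confidence evidence is

    w_i = alpha * mu_i + (1 - alpha) * s_i + eps_c,i,   eps_c,i ~ N(0, sigma_c^2).

Interval 1 is judged more likely correct when ``w_1 r_1 + bias > w_2 r_2``.
A pair therefore has 8 possible outcomes: (r_1, r_2, choice).

Confidence efficiency compares the observer with the ideal confidence
observer (``sigma_c = 0``, ``alpha = 0``) through equivalent noise: the
variance ``tau^2`` of an all-noise confidence model (boost forced to 1) that
matches the observer's confidence choice accuracy.  Efficiency is

    eta = tau_ideal^2 / tau_human^2,

1 for the ideal observer, < 1 when confidence noise dominates, and can exceed
1 when boost (post-decisional information) dominates.

Pair-choice probabilities are computed by deterministic numerical
integration: a Gauss-Legendre rule over the first interval's truncated
evidence, with the remaining two Gaussian dimensions collapsed analytically
into a bivariate normal CDF (Owen's T).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize
from scipy.special import expit, logit, ndtr, ndtri, owens_t

__all__ = [
    "CFCParams", "CFCFit", "BootstrapSummary", "IDEAL",
    "pair_choice_probability", "pair_records", "aggregate_pairs",
    "fit_cfc", "choice_accuracy", "empirical_accuracy", "equivalent_noise",
    "efficiency", "bootstrap_fit", "OUTCOMES",
]

#: Outcome order of the 8-vector returned by :func:`pair_choice_probability`:
#: (r1, r2, confidence_choice).
OUTCOMES: tuple[tuple[int, int, int], ...] = tuple(
    (r1, r2, ch) for r1 in (1, -1) for r2 in (1, -1) for ch in (1, 2)
)

_SIGMA_C_FLOOR = 1e-4


@dataclass(frozen=True)
class CFCParams:
    """Confidence noise (sigma_c), boost (alpha) and interval bias."""

    sigma_c: float = 0.0
    alpha: float = 0.0
    interval_bias: float = 0.0

    def __post_init__(self) -> None:
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


#: The ideal confidence observer: exactly the perceptual decision evidence.
IDEAL = CFCParams(sigma_c=0.0, alpha=0.0, interval_bias=0.0)


@dataclass(frozen=True)
class BootstrapSummary:
    """Participant-resampling distributions of the fitted quantities."""

    samples: dict[str, np.ndarray]
    mean: dict[str, float]
    sd: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    n_boot: int
    n_failed: int = 0


@dataclass(frozen=True)
class CFCFit:
    params: CFCParams
    nll: float
    n_pairs: int
    tau2_ideal: float
    tau2_human: float
    efficiency: float
    converged: bool = True
    bootstrap: BootstrapSummary | None = None

    def with_bootstrap(self, boot: BootstrapSummary) -> "CFCFit":
        return replace(self, bootstrap=boot)


# ---------------------------------------------------------------------------
# exact pair-choice probabilities
# ---------------------------------------------------------------------------

def _phi2(h: np.ndarray, k: np.ndarray, rho: np.ndarray) -> np.ndarray:
    """Standard bivariate normal CDF P(X <= h, Y <= k), vectorized.

    Owen's T decomposition; Phi2 is continuous in (h, k) so exact zeros are
    nudged off the axes where the decomposition is singular.  |rho| -> 1
    degenerates to the comonotone / antithetic closed forms.
    """
    h, k = np.broadcast_arrays(np.asarray(h, float), np.asarray(k, float))
    rho = np.broadcast_to(np.asarray(rho, float), h.shape)
    h = np.where(h == 0.0, 1e-12, h)
    k = np.where(k == 0.0, 1e-12, k)
    out = np.empty(h.shape, float)
    hi = rho > 1 - 1e-12
    lo = rho < -1 + 1e-12
    mid = ~(hi | lo)
    out[hi] = ndtr(np.minimum(h, k))[hi]
    out[lo] = np.maximum(0.0, ndtr(h) + ndtr(k) - 1.0)[lo]
    if mid.any():
        hh, kk, rr = h[mid], k[mid], rho[mid]
        s = np.sqrt(1.0 - rr * rr)
        t1 = owens_t(hh, (kk - rr * hh) / (s * hh))
        t2 = owens_t(kk, (hh - rr * kk) / (s * kk))
        beta = np.where(hh * kk > 0, 0.0, 0.5)
        out[mid] = 0.5 * (ndtr(hh) + ndtr(kk)) - t1 - t2 - beta
    return np.clip(out, 0.0, 1.0)


def pair_choice_probability(mu1, mu2, params: CFCParams,
                            n_nodes: int = 64) -> np.ndarray:
    """Joint law over the 8 outcomes (r1, r2, choice) of a pair.

    Parameters
    ----------
    mu1, mu2 : array-like
        Normalized stimulus strengths of intervals 1 and 2.
    n_nodes : int
        Gauss-Legendre nodes for the outer (truncated-normal) dimension.
        64 nodes give ~1e-5 absolute accuracy per outcome; the worst case is
        ``sigma_c = 0`` where the inner CDF has a kink.

    Returns
    -------
    (n, 8) array of probabilities in the order of :data:`OUTCOMES`; each row
    sums to 1 (up to 1e-9, by construction of the complements).
    """
    mu1 = np.atleast_1d(np.asarray(mu1, float))
    mu2 = np.atleast_1d(np.asarray(mu2, float))
    if mu1.shape != mu2.shape:
        raise ValueError("mu1 and mu2 must have the same shape")
    if not (np.isfinite(mu1).all() and np.isfinite(mu2).all()):
        raise ValueError("stimulus strengths must be finite")
    alpha, sigma_c, bias = params.alpha, params.sigma_c, params.interval_bias

    xg, wg = np.polynomial.legendre.leggauss(n_nodes)
    u = 0.5 * (xg + 1.0)
    wu = 0.5 * wg

    omx = 1.0 - alpha
    sz = float(np.hypot(omx, np.sqrt(2.0) * sigma_c))
    cols = []
    for a, b in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
        m1, m2 = a * mu1, b * mu2
        z_ab = ndtr(m1) * ndtr(m2)        # P(r1 = a, r2 = b)
        # X1 = a*s1 ~ N(m1, 1) truncated to (0, inf), inverse-CDF nodes
        lo = ndtr(-m1)[:, None]
        q = np.clip(lo + u[None, :] * ndtr(m1)[:, None], 1e-300, 1 - 1e-16)
        x1 = m1[:, None] + ndtri(q)
        # choice-1 condition given s1:  (1-a)Y + eps' < c,  Y = b*s2
        c = (alpha * a * mu1[:, None] + omx * x1 + bias
             - alpha * b * mu2[:, None])
        if sz == 0.0:  # alpha = 1, sigma_c = 0: deterministic comparison
            inner = ndtr(m2)[:, None] * np.where(
                c > 0, 1.0, np.where(c == 0, 0.5, 0.0))
        else:
            z0 = (c - omx * m2[:, None]) / sz
            y0 = np.broadcast_to((-m2)[:, None], z0.shape)
            inner = ndtr(z0) - _phi2(y0, z0, omx / sz)
        p1 = ndtr(m1) * (wu[None, :] * inner).sum(axis=1)
        p1 = np.clip(p1, 0.0, z_ab)
        cols.extend([p1, z_ab - p1])
    return np.stack(cols, axis=1)


def _alpha1_probability(mu1: np.ndarray, mu2: np.ndarray,
                        tau: float) -> np.ndarray:
    """Closed-form 8-outcome law of the equivalent-noise family.

    With boost forced to 1 the confidence evidence is ``mu_i + eps`` with
    ``eps ~ N(0, tau^2)``, independent of the sensory sample, so
    ``P(r1=a, r2=b, choice=1) = Phi(a mu1) Phi(b mu2) Phi((a mu1 - b mu2) /
    (tau sqrt(2)))``.
    """
    out = np.empty((mu1.size, 8))
    j = 0
    for a in (1, -1):
        for b in (1, -1):
            z_ab = ndtr(a * mu1) * ndtr(b * mu2)
            d = a * mu1 - b * mu2
            if tau > 0:
                p_ch1 = ndtr(d / (tau * np.sqrt(2.0)))
            else:
                p_ch1 = np.where(d > 0, 1.0, np.where(d == 0, 0.5, 0.0))
            out[:, j] = z_ab * p_ch1
            out[:, j + 1] = z_ab * (1.0 - p_ch1)
            j += 2
    return out


# ---------------------------------------------------------------------------
# data aggregation
# ---------------------------------------------------------------------------

def pair_records(trials: pd.DataFrame, pairs: pd.DataFrame) -> pd.DataFrame:
    """Assemble per-pair records (mu1, mu2, r1, r2, choice) from the tables.

    ``trials`` should already carry normalized strengths when the records are
    meant for across-observer aggregation.
    """
    t = trials.sort_values(["participant", "pair", "interval"], kind="stable")
    i1 = t[t["interval"] == 1].set_index(["participant", "pair"])
    i2 = t[t["interval"] == 2].set_index(["participant", "pair"])
    if not i1.index.equals(i2.index):
        raise ValueError("trial table pair structure is inconsistent")
    p = pairs.set_index(["participant", "pair"])
    if not p.index.sort_values().equals(i1.index.sort_values()):
        raise ValueError("pair table does not match trial table pairs")
    p = p.reindex(i1.index)
    rec = pd.DataFrame({
        "mu1": i1["mu_s"].to_numpy(float),
        "mu2": i2["mu_s"].to_numpy(float),
        "r1": i1["response"].to_numpy(int),
        "r2": i2["response"].to_numpy(int),
        "choice": p["confidence_choice"].to_numpy(int),
    }, index=i1.index).reset_index()
    return rec


def aggregate_pairs(records: pd.DataFrame,
                    bin_width: float = 0.2) -> pd.DataFrame:
    """Aggregate pair records into outcome counts on a strength grid.

    Normalized strengths are rounded to multiples of ``bin_width`` so that
    pooled data from many observers collapse onto a manageable set of
    (mu1, mu2) cells; ``bin_width = 0`` keeps raw values.
    """
    rec = records.copy()
    if bin_width > 0:
        rec["mu1"] = np.round(rec["mu1"] / bin_width) * bin_width
        rec["mu2"] = np.round(rec["mu2"] / bin_width) * bin_width
    counts = (rec.groupby(["mu1", "mu2", "r1", "r2", "choice"])
              .size().rename("count").reset_index())
    return counts


def _count_matrix(counts: pd.DataFrame):
    """Unique (mu1, mu2) cells and an (m, 8) count matrix aligned to OUTCOMES."""
    cells = counts[["mu1", "mu2"]].drop_duplicates().sort_values(
        ["mu1", "mu2"]).reset_index(drop=True)
    key = {(row.mu1, row.mu2): i for i, row in cells.iterrows()}
    idx_of = {o: j for j, o in enumerate(OUTCOMES)}
    mat = np.zeros((len(cells), 8))
    for row in counts.itertuples(index=False):
        mat[key[(row.mu1, row.mu2)],
            idx_of[(row.r1, row.r2, row.choice)]] += row.count
    return cells["mu1"].to_numpy(), cells["mu2"].to_numpy(), mat


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def fit_cfc(counts: pd.DataFrame, fix_alpha: float | None = None,
            n_nodes: int = 32, start: CFCParams | None = None,
            compute_efficiency: bool = True) -> CFCFit:
    """Maximize the multinomial likelihood over (sigma_c, alpha, bias).

    ``counts`` is the output of :func:`aggregate_pairs` on data pooled after
    per-participant normalization (the aggregated model then has unit sensory
    noise by construction).  ``alpha`` is optimized through a logit transform
    and ``sigma_c`` on a log scale with floor 1e-4; ``fix_alpha`` profiles
    the likelihood at a fixed boost.  Deterministic given data and starts.
    """
    mu1, mu2, mat = _count_matrix(counts)
    if len(mu1) < 2:
        warnings.warn("only one (mu1, mu2) cell: sigma_c and alpha are not "
                      "separately identifiable", RuntimeWarning)
    n_pairs = int(mat.sum())

    def unpack(theta):
        sigma_c = float(np.exp(theta[0]))
        if fix_alpha is None:
            alpha = float(expit(theta[1]))
            bias = float(theta[2])
        else:
            alpha = float(fix_alpha)
            bias = float(theta[1])
        return CFCParams(sigma_c=sigma_c, alpha=alpha, interval_bias=bias)

    def nll(theta):
        p = pair_choice_probability(mu1, mu2, unpack(theta), n_nodes=n_nodes)
        return float(-(mat * np.log(np.clip(p, 1e-300, None))).sum())

    lb_s, ub_s = np.log(_SIGMA_C_FLOOR), np.log(50.0)
    if fix_alpha is None:
        bounds = [(lb_s, ub_s), (-10.0, 10.0), (-5.0, 5.0)]
        if start is not None:
            starts = [(np.log(max(start.sigma_c, _SIGMA_C_FLOOR)),
                       logit(np.clip(start.alpha, 1e-4, 1 - 1e-4)),
                       start.interval_bias)]
        else:
            starts = [(np.log(0.3), logit(0.1), 0.0),
                      (np.log(0.8), logit(0.4), 0.0),
                      (np.log(0.05), logit(0.02), 0.0)]
    else:
        bounds = [(lb_s, ub_s), (-5.0, 5.0)]
        if start is not None:
            starts = [(np.log(max(start.sigma_c, _SIGMA_C_FLOOR)),
                       start.interval_bias)]
        else:
            starts = [(np.log(0.3), 0.0), (np.log(0.8), 0.0)]

    best = None
    for s in starts:
        res = minimize(nll, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    params = unpack(best.x)

    tau2_i = tau2_h = eta = float("nan")
    if compute_efficiency:
        design = (mu1, mu2, mat.sum(axis=1))
        tau2_i = equivalent_noise(IDEAL, design, n_nodes=n_nodes)
        # tau_human is fitted to the data: it matches the observers'
        # realized confidence accuracy, not the (sigma_c, alpha) point
        # estimate, which sits on a likelihood ridge
        tau2_h = _tau2_matching_accuracy(empirical_accuracy(counts), design)
        eta = tau2_i / tau2_h
    return CFCFit(params=params, nll=float(best.fun), n_pairs=n_pairs,
                  tau2_ideal=tau2_i, tau2_human=tau2_h, efficiency=eta,
                  converged=bool(best.success))


# ---------------------------------------------------------------------------
# equivalent noise and efficiency
# ---------------------------------------------------------------------------

def choice_accuracy(mu1: np.ndarray, mu2: np.ndarray, probs: np.ndarray,
                    weights: np.ndarray | None = None) -> float:
    """P(confidence chooses the interval with the correct response | exactly
    one response correct), weighted over the design.

    A response is correct when it matches the stimulus sign; zero-strength
    intervals have no correct answer and count as incorrect, so pairs where
    both intervals are at zero strength never enter the conditioning event.
    """
    mu1 = np.atleast_1d(mu1)
    mu2 = np.atleast_1d(mu2)
    w = np.ones(mu1.size) if weights is None else np.asarray(weights, float)
    num = den = 0.0
    for j, (r1, r2, ch) in enumerate(OUTCOMES):
        c1 = r1 * mu1 > 0
        c2 = r2 * mu2 > 0
        one = c1 ^ c2
        hit = np.where(ch == 1, c1, c2) & one
        num += float((w * probs[:, j] * hit).sum())
        den += float((w * probs[:, j] * one).sum())
    if den == 0:
        raise ValueError("degenerate design: no pair can have exactly one "
                         "correct response")
    return num / den


def _alpha1_accuracy(tau: float, mu1, mu2, weights) -> float:
    return choice_accuracy(mu1, mu2, _alpha1_probability(mu1, mu2, tau),
                           weights)


def empirical_accuracy(counts: pd.DataFrame) -> float:
    """Observed P(confidence chooses the correct interval | exactly one
    correct) from aggregated outcome counts."""
    mu1 = counts["mu1"].to_numpy(float)
    mu2 = counts["mu2"].to_numpy(float)
    c1 = counts["r1"].to_numpy() * mu1 > 0
    c2 = counts["r2"].to_numpy() * mu2 > 0
    one = c1 ^ c2
    hit = np.where(counts["choice"].to_numpy() == 1, c1, c2) & one
    n = counts["count"].to_numpy(float)
    den = float((n * one).sum())
    if den == 0:
        raise ValueError("no pairs with exactly one correct response")
    return float((n * hit).sum()) / den


def _tau2_matching_accuracy(acc: float, design,
                            tau_bracket=(1e-4, 1e3)) -> float:
    """tau^2 of the all-noise family matching a given accuracy scalar."""
    mu1, mu2, w = design
    lo, hi = tau_bracket
    f = lambda log_tau: _alpha1_accuracy(np.exp(log_tau), mu1, mu2, w) - acc
    f_lo, f_hi = f(np.log(lo)), f(np.log(hi))
    if not (f_lo >= 0 >= f_hi):
        raise ValueError(
            f"accuracy {acc:.4f} outside the equivalent-noise family's "
            f"range [{f_hi + acc:.4f}, {f_lo + acc:.4f}] on this design")
    return float(np.exp(brentq(f, np.log(lo), np.log(hi), xtol=1e-10)) ** 2)


def equivalent_noise(target: CFCParams, design, n_nodes: int = 64,
                     tau_bracket: tuple[float, float] = (1e-4, 1e3),
                     ) -> float:
    """Equivalent-noise variance tau^2 of a confidence model on a design.

    Finds ``tau >= 0`` such that the all-noise model (alpha = 1,
    sigma_c = tau, no bias) matches the target model's overall probability of
    choosing the interval with the correct response (scalar root-find on
    log tau).  ``design`` is ``(mu1, mu2, weights)`` giving the distribution
    of normalized strength pairs.
    """
    mu1, mu2, w = design
    mu1 = np.asarray(mu1, float)
    mu2 = np.asarray(mu2, float)
    probs = pair_choice_probability(mu1, mu2, target, n_nodes=n_nodes)
    target_acc = choice_accuracy(mu1, mu2, probs, w)

    lo, hi = tau_bracket
    f = lambda log_tau: _alpha1_accuracy(np.exp(log_tau), mu1, mu2, w) - target_acc
    f_lo, f_hi = f(np.log(lo)), f(np.log(hi))
    if not (f_lo >= 0 >= f_hi):
        raise ValueError(
            f"target accuracy {target_acc:.4f} not bracketed by the "
            f"equivalent-noise family on tau in [{lo}, {hi}] "
            f"(range [{f_hi + target_acc:.4f}, {f_lo + target_acc:.4f}])")
    log_tau = brentq(f, np.log(lo), np.log(hi), xtol=1e-10)
    return float(np.exp(log_tau) ** 2)


def efficiency(params: CFCParams, design, n_nodes: int = 64) -> float:
    """Confidence efficiency eta = tau^2_ideal / tau^2_human on a design."""
    t_i = equivalent_noise(IDEAL, design, n_nodes=n_nodes)
    t_h = equivalent_noise(params, design, n_nodes=n_nodes)
    return t_i / t_h


# ---------------------------------------------------------------------------
# participant bootstrap
# ---------------------------------------------------------------------------

def bootstrap_fit(records: pd.DataFrame, n_boot: int = 1000,
                  seed: int | np.random.Generator | None = None,
                  bin_width: float = 0.2, n_nodes: int = 24,
                  start: CFCParams | None = None,
                  fix_alpha: float | None = None) -> BootstrapSummary:
    """Resample participants with replacement; re-aggregate and re-fit.

    Returns sampling distributions of sigma_c, alpha, interval bias and
    efficiency.  Efficiency per resample is computed on the full-sample
    design (the distribution of normalized strength pairs), so resamples
    differ only through the fitted parameters.  Failed resample fits are
    excluded and counted.
    """
    rng = np.random.default_rng(seed)
    pids = np.array(sorted(records["participant"].unique()))
    if pids.size < 1:
        raise ValueError("no participants to resample")
    by_pid = {p: df for p, df in records.groupby("participant")}

    full_counts = aggregate_pairs(records, bin_width=bin_width)
    mu1, mu2, mat = _count_matrix(full_counts)
    design = (mu1, mu2, mat.sum(axis=1))
    tau2_i = equivalent_noise(IDEAL, design, n_nodes=n_nodes)
    if start is None:
        start = fit_cfc(full_counts, n_nodes=n_nodes, fix_alpha=fix_alpha,
                        compute_efficiency=False).params

    keys = ("sigma_c", "alpha", "interval_bias", "efficiency")
    samples: dict[str, list[float]] = {k: [] for k in keys}
    n_failed = 0
    for _ in range(n_boot):
        take = rng.choice(pids, size=pids.size, replace=True)
        boot = pd.concat([by_pid[p] for p in take], ignore_index=True)
        try:
            boot_counts = aggregate_pairs(boot, bin_width=bin_width)
            fit = fit_cfc(boot_counts, n_nodes=n_nodes, start=start,
                          fix_alpha=fix_alpha, compute_efficiency=False)
            tau2_h = _tau2_matching_accuracy(
                empirical_accuracy(boot_counts), design)
        except (ValueError, RuntimeError):
            n_failed += 1
            continue
        samples["sigma_c"].append(fit.params.sigma_c)
        samples["alpha"].append(fit.params.alpha)
        samples["interval_bias"].append(fit.params.interval_bias)
        samples["efficiency"].append(tau2_i / tau2_h)

    arrays = {k: np.asarray(v) for k, v in samples.items()}
    mean = {k: float(v.mean()) if v.size else float("nan")
            for k, v in arrays.items()}
    sd = {k: float(v.std(ddof=1)) if v.size > 1 else 0.0
          for k, v in arrays.items()}
    ci = {k: (tuple(np.percentile(v, [2.5, 97.5])) if v.size
              else (float("nan"), float("nan")))
          for k, v in arrays.items()}
    return BootstrapSummary(samples=arrays, mean=mean, sd=sd,
                            ci95={k: (float(a), float(b)) for k, (a, b) in ci.items()},
                            n_boot=n_boot, n_failed=n_failed)
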