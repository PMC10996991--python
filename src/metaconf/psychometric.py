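"""Psychometric fitting, observer exclusion, normalization and RT summaries.

The proportion of rightward (+1) responses as a function of signed stimulus
strength is fit with a cumulative Gaussian ``P(+1 | x) = Phi((x - mu) / sigma)``
by maximum likelihood.  ``mu`` estimates the perceptual response criterion and
``sigma`` (the inverse slope) indexes perceptual sensitivity.  Stimulus
strengths are then recentered on ``mu`` and rescaled by ``sigma`` so data can
be aggregated across observers in criterion-centered standard-deviation units.

Observers whose responses do not track the stimulus (fitted ``sigma`` larger
than half the stimulus range) or who use one confidence response on more than
78% of pairs are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr, ndtri

__all__ = [
    "PsychometricFit", "ExclusionReport", "RTSummary",
    "fit_psychometric", "apply_exclusions", "normalize_strengths",
    "summarize_rts", "split_by_rt",
]


@dataclass(frozen=True)
class PsychometricFit:
    """Maximum-likelihood cumulative-Gaussian fit.

    ``sigma_pinned`` flags degenerate data (e.g. all responses identical)
    where sigma sits at the optimization bound rather than a true optimum.
    """

    mu: float
    sigma: float
    n_trials: int
    nll: float
    converged: bool
    sigma_pinned: bool = False

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not self.sigma > 0:
            raise ValueError("sigma must be > 0")


@dataclass(frozen=True)
class ExclusionReport:
    participant: str
    excluded: bool
    reason: str  # "slope_rule" | "confidence_bias_rule" | "none" | "unevaluable"
    slope: float
    max_choice_proportion: float


@dataclass(frozen=True)
class RTSummary:
    participant: str
    median_rt_ms: float
    log_rt_z: tuple[float, ...] = ()
    available: bool = True


# upper sigma bound, as a multiple of the stimulus range (or of 1 when the
# range is degenerate); generous enough that only flat responders hit it
_SIGMA_CAP_FACTOR = 20.0


def _nll(mu: float, sigma: float, x: np.ndarray, k: np.ndarray,
         n: np.ndarray) -> float:
    p = ndtr((x - mu) / sigma)
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Fit ``P(response=+1 | mu_s) = Phi((mu_s - mu) / sigma)`` by ML.

    Bounded quasi-Newton on ``(mu, log sigma)`` with multistart from moment
    estimates; deterministic given the data.  Degenerate data (all responses
    identical) pin sigma at the upper bound and are flagged, not raised.
    """
    g = trials.groupby("mu_s")["response"]
    x = np.array(sorted(g.groups))
    if x.size < 2:
        raise ValueError("need responses at >= 2 distinct stimulus levels")
    n = g.count().reindex(x).to_numpy(float)
    k = g.apply(lambda r: (r > 0).sum()).reindex(x).to_numpy(float)

    span = float(x.max() - x.min()) or 1.0
    cap = _SIGMA_CAP_FACTOR * span

    if k.sum() == 0 or k.sum() == n.sum():
        # all responses identical: the likelihood is flat in any direction
        # that saturates the curve; report an explicit flat fit with sigma
        # pinned at the cap so the slope exclusion rule catches it
        return PsychometricFit(mu=float(np.median(x)), sigma=cap,
                               n_trials=int(n.sum()),
                               nll=_nll(float(np.median(x)), cap, x, k, n),
                               converged=True, sigma_pinned=True)

    # moment starts: probit-linearized least squares
    p_obs = np.clip((k + 0.5) / (n + 1.0), 1e-3, 1 - 1e-3)
    z = ndtri(p_obs)
    slope, icpt = np.polyfit(x, z, 1) if x.size > 1 else (1.0 / span, 0.0)
    sig0 = min(cap, max(1e-3 * span, 1.0 / slope)) if slope > 1e-12 else cap
    mu0 = float(np.clip(-icpt * sig0, x.min() - span, x.max() + span))

    def obj(theta):
        return _nll(theta[0], np.exp(theta[1]), x, k, n)

    bounds = [(x.min() - 5 * span, x.max() + 5 * span),
              (np.log(1e-3 * span), np.log(cap))]
    starts = [(mu0, np.log(sig0)), (0.0, np.log(span / 2)),
              (float(np.median(x)), np.log(span / 4))]
    best = None
    for s in starts:
        s = (float(np.clip(s[0], *bounds[0])), float(np.clip(s[1], *bounds[1])))
        res = minimize(obj, s, method="L-BFGS-B", bounds=bounds)
        if best is None or res.fun < best.fun:
            best = res
    mu, log_sigma = best.x
    sigma = float(np.exp(log_sigma))
    pinned = log_sigma >= bounds[1][1] - 1e-6
    return PsychometricFit(mu=float(mu), sigma=sigma, n_trials=int(n.sum()),
                           nll=float(best.fun), converged=bool(best.success),
                           sigma_pinned=bool(pinned))


def apply_exclusions(fits: Mapping[str, PsychometricFit],
                     pair_tables: Mapping[str, pd.DataFrame],
                     stimulus_range: float,
                     bias_threshold: float = 0.78) -> list[ExclusionReport]:
    """Apply the slope and confidence-bias exclusion rules per participant.

    A participant is excluded when the fitted sigma strictly exceeds half the
    stimulus range (responses do not vary with the stimulus), or when one
    confidence response is used on strictly more than ``bias_threshold`` of
    pairs.  A participant without a pair table is reported unevaluable.
    """
    reports = []
    for pid in sorted(fits):
        fit = fits[pid]
        pairs = pair_tables.get(pid)
        if pairs is None:
            reports.append(ExclusionReport(pid, True, "unevaluable",
                                           fit.sigma, float("nan")))
            continue
        choice = pairs["confidence_choice"].to_numpy()
        p1 = float(np.mean(choice == 1))
        max_prop = max(p1, 1.0 - p1)
        if fit.sigma > stimulus_range / 2.0:
            reports.append(ExclusionReport(pid, True, "slope_rule",
                                           fit.sigma, max_prop))
        elif max_prop > bias_threshold:
            reports.append(ExclusionReport(pid, True, "confidence_bias_rule",
                                           fit.sigma, max_prop))
        else:
            reports.append(ExclusionReport(pid, False, "none",
                                           fit.sigma, max_prop))
    return reports


def normalize_strengths(trials: pd.DataFrame,
                        fit: PsychometricFit) -> pd.DataFrame:
    """Recenter stimulus strengths on the criterion and rescale by the slope.

    After normalization the participant's psychometric function is the
    standard cumulative Gaussian, so data can be aggregated across observers.
    """
    out = trials.copy()
    out["mu_s"] = (out["mu_s"] - fit.mu) / fit.sigma
    if "s_latent" in out.columns:
        out["s_latent"] = (out["s_latent"] - fit.mu) / fit.sigma
    return out


def summarize_rts(trials: pd.DataFrame, half_block: int = 167) -> RTSummary:
    """Median RT from the half-block of trials closest to the session middle.

    RTs drift downward over a session; restricting the median to a centered
    window removes the confound between block order and apparent speed.  The
    ``log_rt_z`` field carries the z-scored log RTs of the same window.
    """
    pid = str(trials["participant"].iloc[0])
    rt = trials["rt_ms"].to_numpy(float)
    if np.isnan(rt).all():
        return RTSummary(pid, float("nan"), (), available=False)
    n = rt.size
    half = min(half_block, n)
    start = max(0, (n - half) // 2)
    window = rt[start:start + half]
    window = window[~np.isnan(window)]
    if window.size == 0:
        return RTSummary(pid, float("nan"), (), available=False)
    log_rt = np.log(window)
    sd = log_rt.std()
    z = (log_rt - log_rt.mean()) / sd if sd > 0 else np.zeros_like(log_rt)
    return RTSummary(pid, float(np.median(window)), tuple(z))


def split_by_rt(summaries: Sequence[RTSummary], k: int = 3) -> dict[str, int]:
    """Assign participants to ``k`` equal groups by median RT (0 = fastest).

    Ties at a group boundary are resolved by participant id after a stable
    sort, so the assignment is deterministic.
    """
    avail = [s for s in summaries if s.available]
    if len(avail) < k:
        raise ValueError("fewer participants than groups")
    ordered = sorted(avail, key=lambda s: (s.median_rt_ms, s.participant))
    n = len(ordered)
    edges = [round(i * n / k) for i in range(k + 1)]
    groups: dict[str, int] = {}
    for gi in range(k):
        for s in ordered[edges[gi]:edges[gi + 1]]:
            groups[s.participant] = gi
    return groups
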