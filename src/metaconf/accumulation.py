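"""Two-stage dynamic signal detection: drift to collapsing bounds, then
post-decisional accumulation whose signal content is a permeability knob.

Pre-decision, evidence follows a discretized diffusion

    s(t + dt) = s(t) + mu * dt + eps,   eps ~ N(0, sigma^2 * dt),

and the observer commits when |s| reaches a collapsing bound
``b(t) = b0 * exp(-t / tau_b) + b_floor`` (choice = sign of s; the recorded
response time adds nondecision time).  After commitment, accumulation
continues with drift ``lambda_perm * mu`` and the same diffusion noise until
confidence is read out at the start of the next decision: the permeability
``lambda_perm = 1`` reproduces classic two-stage theory (same signal-to-noise
as pre-decision), ``lambda_perm = 0`` accumulates noise only.  A backward
mask multiplies the diffusion SD from mask onset onward, injecting extra
noise into the ongoing accumulation.

Because the post-decision stage has no absorbing bound, its increment over a
window of length T is exactly Gaussian with mean ``lambda * mu * T`` and
variance ``integral of sigma(t)^2 dt``; it is sampled in closed form rather
than stepped.

Predicted confidence efficiency treats the simulator's final evidence as the
confidence variable of a forced-choice pair and reuses the equivalent-noise
machinery of :mod:`metaconf.cfc_model` against the ideal observer at
decision time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from metaconf.cfc_model import IDEAL, _alpha1_accuracy, equivalent_noise
from metaconf.psychometric import fit_psychometric

__all__ = [
    "AccumulationModel", "simulate_decision", "simulate_postdecision",
    "predicted_efficiency", "rt_group_prediction",
]


@dataclass(frozen=True)
class AccumulationModel:
    """Parameters of the two-stage accumulation simulator.

    Times are in milliseconds; evidence units are arbitrary (the bound and
    diffusion SD set the scale).  ``drift_gain`` maps stimulus strength to
    drift per ms.  Defaults produce median RTs in the 400-1,200 ms range
    typical of speeded two-choice psychophysics; they are calibrated values
    of this package, not estimates from any data set.
    """

    dt_ms: float = 1.0
    sigma_per_sqrt_ms: float = 0.009
    drift_gain: float = 0.00015
    bound_initial: float = 1.0
    bound_tau_ms: float = 450.0
    bound_floor: float = 0.15
    ndt_mean_ms: float = 300.0
    ndt_sd_ms: float = 30.0
    iti_ms: float = 200.0
    cue_delay_ms: float = 100.0
    stim_duration_ms: float = 400.0
    mask_onset_after_offset_ms: float = 500.0
    mask_noise_factor: float = 1.0
    lambda_perm: float = 1.0
    max_decision_ms: float = 5000.0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be > 0")
        if not 0.0 <= self.lambda_perm <= 1.0:
            raise ValueError("lambda_perm must lie in [0, 1]")
        if self.mask_noise_factor < 1.0:
            raise ValueError("mask_noise_factor must be >= 1")
        if self.bound_initial <= 0 or self.bound_floor < 0:
            raise ValueError("bounds must be positive")

    def bound(self, t_ms: np.ndarray) -> np.ndarray:
        """Collapsing decision bound b(t), positive and non-increasing."""
        return (self.bound_initial - self.bound_floor) * np.exp(
            -np.asarray(t_ms, float) / self.bound_tau_ms) + self.bound_floor


def simulate_decision(model: AccumulationModel, mu_s,
                      seed: int | np.random.Generator | None = None,
                      ) -> pd.DataFrame:
    """Simulate drift to the collapsing bound for each stimulus strength.

    Euler-Maruyama with step ``dt_ms``, plus a Brownian-bridge correction:
    between consecutive samples the path may have touched the bound even if
    both endpoints lie inside, with probability
    ``exp(-2 (b - s_t)(b - s_{t+dt}) / (sigma^2 dt))`` per barrier.  Sampling
    these in-step crossings removes the O(sqrt(dt)) first-passage bias of the
    naive scheme.  Trials that never reach the bound within
    ``max_decision_ms`` are forced to the sign of the running evidence and
    flagged ``censored``.
    """
    rng = np.random.default_rng(seed)
    mu = np.atleast_1d(np.asarray(mu_s, float))
    n = mu.size
    drift = model.drift_gain * mu * model.dt_ms
    step_var = model.sigma_per_sqrt_ms ** 2 * model.dt_ms
    noise_sd = np.sqrt(step_var)

    s = np.zeros(n)
    done = np.zeros(n, bool)
    choice = np.zeros(n, int)
    t_dec = np.full(n, model.max_decision_ms)
    ev_at_bound = np.zeros(n)
    n_steps = int(np.ceil(model.max_decision_ms / model.dt_ms))
    active = np.arange(n)
    for step in range(1, n_steps + 1):
        t = step * model.dt_ms
        s_old = s[active]
        s_new = s_old + drift[active] + noise_sd * rng.standard_normal(active.size)
        s[active] = s_new
        b = float(model.bound(t))
        hit = np.abs(s_new) >= b
        up = s_new >= b
        # in-step barrier touches for interior endpoints (bridge crossing)
        interior = ~hit
        if interior.any():
            so, sn = s_old[interior], s_new[interior]
            p_up = np.exp(-2.0 * np.clip(b - so, 0, None)
                          * np.clip(b - sn, 0, None) / step_var)
            p_dn = np.exp(-2.0 * np.clip(b + so, 0, None)
                          * np.clip(b + sn, 0, None) / step_var)
            u = rng.uniform(size=so.size)
            crossed = u < p_up + p_dn
            bridge_up = u < p_up
            hit[interior] |= crossed
            up[interior] = bridge_up
            sub = np.flatnonzero(interior)[crossed]
            s[active[sub]] = np.where(bridge_up[crossed], b, -b)
        if hit.any():
            idx = active[hit]
            choice[idx] = np.where(up[hit], 1, -1)
            t_dec[idx] = t
            ev_at_bound[idx] = np.where(up[hit], np.abs(s[idx]), -np.abs(s[idx]))
            done[idx] = True
            active = active[~hit]
            if active.size == 0:
                break
    censored = ~done
    if censored.any():
        idx = np.flatnonzero(censored)
        sign = np.where(s[idx] > 0, 1, np.where(s[idx] < 0, -1, 0))
        zero = sign == 0
        if zero.any():
            sign[zero] = rng.choice([-1, 1], zero.sum())
        choice[idx] = sign
        ev_at_bound[idx] = s[idx]
    ndt = np.clip(rng.normal(model.ndt_mean_ms, model.ndt_sd_ms, n), 0.0, None)
    return pd.DataFrame({
        "mu_s": mu,
        "choice": choice,
        "decision_time_ms": t_dec,
        "ndt_ms": ndt,
        "response_time_ms": t_dec + ndt,
        "evidence_at_bound": ev_at_bound,
        "censored": censored,
    })


def _postdecision_window(model: AccumulationModel, t_dec: np.ndarray,
                         ndt: np.ndarray, condition: str) -> np.ndarray:
    """Length of continued accumulation, ending at the next decision's cue.

    short : response cued promptly; window = NDT + inter-trial interval.
    long / mask : the observer additionally waits for the response cue when
    the decision beats it; waiting time = cue delay measured from stimulus
    offset minus the post-offset decision time, floored at 0.
    """
    if condition == "short":
        wait = 0.0
    elif condition in ("long", "mask"):
        post_offset = np.clip(t_dec - model.stim_duration_ms, 0.0, None)
        wait = np.clip(model.cue_delay_ms - post_offset, 0.0, None)
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return ndt + wait + model.iti_ms


def simulate_postdecision(model: AccumulationModel, outcome: pd.DataFrame,
                          condition: str = "short",
                          seed: int | np.random.Generator | None = None,
                          ) -> pd.DataFrame:
    """Continue accumulation after commitment and fill ``final_evidence``.

    Drift is scaled by the permeability ``lambda_perm``; diffusion noise
    continues at the pre-decision rate, multiplied by ``mask_noise_factor``
    from mask onset (``mask_onset_after_offset_ms`` after stimulus offset)
    onward in the ``mask`` condition.  With no absorbing bound the increment
    is Gaussian, so the window is integrated in closed form.
    """
    rng = np.random.default_rng(seed)
    out = outcome.copy()
    t_dec = out["decision_time_ms"].to_numpy(float)
    ndt = out["ndt_ms"].to_numpy(float)
    mu = out["mu_s"].to_numpy(float)
    T = _postdecision_window(model, t_dec, ndt, condition)

    var_rate = model.sigma_per_sqrt_ms ** 2
    if condition == "mask" and model.mask_noise_factor > 1.0:
        mask_on = model.stim_duration_ms + model.mask_onset_after_offset_ms
        # overlap of [t_dec, t_dec + T] with [mask_on, inf)
        t_masked = np.clip(t_dec + T - np.maximum(t_dec, mask_on), 0.0, None)
        t_clean = T - t_masked
        var = var_rate * (t_clean + model.mask_noise_factor ** 2 * t_masked)
    else:
        var = var_rate * T

    drift = model.lambda_perm * model.drift_gain * mu
    incr = drift * T + np.sqrt(var) * rng.standard_normal(mu.size)
    out["postdecision_duration_ms"] = T
    out["final_evidence"] = out["evidence_at_bound"].to_numpy(float) + incr
    return out


def _pairs_from_design(design, n_pairs: int, rng: np.random.Generator):
    """Draw (mu1, mu2) pair strengths proportional to the design counts."""
    combos = sorted(design.pair_counts)
    weights = np.array([design.pair_counts[c] for c in combos], float)
    weights /= weights.sum()
    take = rng.choice(len(combos), size=n_pairs, p=weights)
    mu1 = np.array([combos[i][0] for i in take])
    mu2 = np.array([combos[i][1] for i in take])
    return mu1, mu2


def _efficiency_from_sim(mu_all: np.ndarray, choice_all: np.ndarray,
                         mu1: np.ndarray, mu2: np.ndarray,
                         conf_first: np.ndarray) -> float:
    """Confidence efficiency of simulated pairs vs the decision-time ideal.

    Perceptual sensitivity is estimated from the simulated choices by a
    psychometric fit; strengths are normalized by it, the ideal confidence
    observer's accuracy on the realized design is computed analytically, and
    both accuracies are converted to equivalent noise by root-finding in the
    all-noise (boost = 1) family.
    """
    trials = pd.DataFrame({"mu_s": mu_all, "response": choice_all})
    fit = fit_psychometric(trials)
    z1 = (mu1 - fit.mu) / fit.sigma
    z2 = (mu2 - fit.mu) / fit.sigma

    r1 = choice_all[0::2]
    r2 = choice_all[1::2]
    c1 = r1 * z1 > 0
    c2 = r2 * z2 > 0
    one = c1 ^ c2
    if one.sum() == 0:
        raise ValueError("no pairs with exactly one correct response")
    acc_human = float(np.where(conf_first[one], c1[one], c2[one]).mean())

    tau2_ideal = equivalent_noise(IDEAL, (z1, z2, np.ones(z1.size)))
    from scipy.optimize import brentq
    f = lambda lt: _alpha1_accuracy(np.exp(lt), z1, z2, np.ones(z1.size)) - acc_human
    lo, hi = np.log(1e-4), np.log(1e3)
    if not (f(lo) >= 0 >= f(hi)):
        raise ValueError("simulated confidence accuracy outside the "
                         "equivalent-noise family's range")
    tau2_human = float(np.exp(brentq(f, lo, hi, xtol=1e-10)) ** 2)
    return tau2_ideal / tau2_human


def predicted_efficiency(model: AccumulationModel, design, condition: str,
                         lambda_perm: float | None = None,
                         n_pairs: int = 20000,
                         seed: int | np.random.Generator | None = None,
                         ) -> float:
    """Predicted confidence efficiency for a condition and permeability.

    Simulates ``n_pairs`` forced-choice pairs; confidence selects the
    interval whose final evidence, signed by its own choice, is larger.
    """
    rng = np.random.default_rng(seed)
    if lambda_perm is not None:
        model = replace(model, lambda_perm=lambda_perm)
    mu1, mu2 = _pairs_from_design(design, n_pairs, rng)
    mu_all = np.empty(2 * n_pairs)
    mu_all[0::2], mu_all[1::2] = mu1, mu2
    dec = simulate_decision(model, mu_all, rng)
    post = simulate_postdecision(model, dec, condition, rng)
    fe = post["final_evidence"].to_numpy(float)
    ch = post["choice"].to_numpy(int)
    w = fe * ch
    conf_first = w[0::2] > w[1::2]
    ties = w[0::2] == w[1::2]
    if ties.any():
        conf_first = conf_first.copy()
        conf_first[ties] = rng.uniform(size=int(ties.sum())) < 0.5
    return _efficiency_from_sim(mu_all, ch, mu1, mu2, conf_first)


def rt_group_prediction(model_low: AccumulationModel,
                        model_high: AccumulationModel, design,
                        n_observers: int = 30, n_pairs_per_obs: int = 600,
                        n_groups: int = 3, condition: str = "short",
                        drift_gain_spread: float = 0.9,
                        seed: int | np.random.Generator | None = None,
                        ) -> pd.DataFrame:
    """Predicted efficiency by task and median-RT tercile.

    Observers share the timing of the two models but differ in a speed
    factor ``g`` (log-normal spread) that scales drift by ``g`` and the
    diffusion variance by ``g``: slower responders accumulate a lower
    signal-to-noise ratio for a longer duration while perceptual accuracy
    stays flat across speed groups, as observed empirically.  Each observer
    is simulated under both permeability regimes (high task: ``model_high``;
    low task: ``model_low``), split into ``n_groups`` by median RT, and
    efficiency is computed per (task, group) on the pooled pairs of the
    group.
    """
    rng = np.random.default_rng(seed)
    # deterministic ladder of speed factors (central quantiles of the
    # log-normal population): group composition is then a design property
    # and the seed only drives trial-level noise
    from scipy.special import ndtri
    q = (np.arange(1, n_observers + 1) - 0.5) / n_observers
    speed = np.exp(drift_gain_spread * ndtri(q))

    sims: dict[str, list] = {"low": [], "high": []}
    med_rt = np.empty(n_observers)
    for i in range(n_observers):
        mu1, mu2 = _pairs_from_design(design, n_pairs_per_obs, rng)
        mu_all = np.empty(2 * n_pairs_per_obs)
        mu_all[0::2], mu_all[1::2] = mu1, mu2
        # common random numbers across tasks: the regimes are counterfactual
        # readouts of the same observer, so sharing the noise stream removes
        # spurious between-task Monte-Carlo differences
        task_seed = int(rng.integers(2**31))
        rts = []
        for task, base in (("low", model_low), ("high", model_high)):
            m = replace(base,
                        drift_gain=float(base.drift_gain * speed[i]),
                        sigma_per_sqrt_ms=float(
                            base.sigma_per_sqrt_ms * np.sqrt(speed[i])))
            trng = np.random.default_rng(task_seed)
            dec = simulate_decision(m, mu_all, trng)
            post = simulate_postdecision(m, dec, condition, trng)
            sims[task].append((mu_all, mu1, mu2, post))
            rts.append(post["response_time_ms"].to_numpy(float))
        med_rt[i] = float(np.median(np.concatenate(rts)))

    order = np.argsort(med_rt, kind="stable")
    edges = [round(g * n_observers / n_groups) for g in range(n_groups + 1)]
    rows = []
    for g in range(n_groups):
        members = order[edges[g]:edges[g + 1]]
        for task in ("low", "high"):
            mu_all = np.concatenate([sims[task][i][0] for i in members])
            mu1 = np.concatenate([sims[task][i][1] for i in members])
            mu2 = np.concatenate([sims[task][i][2] for i in members])
            post = pd.concat([sims[task][i][3] for i in members],
                             ignore_index=True)
            fe = post["final_evidence"].to_numpy(float)
            ch = post["choice"].to_numpy(int)
            w = fe * ch
            conf_first = w[0::2] > w[1::2]
            eta = _efficiency_from_sim(mu_all, ch, mu1, mu2, conf_first)
            rows.append({"rt_group": g, "task": task, "efficiency": eta,
                         "median_rt_ms": float(np.median(med_rt[members])),
                         "n_pairs": mu1.size})
    return pd.DataFrame(rows)
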