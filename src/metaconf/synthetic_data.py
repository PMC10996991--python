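"""Forward simulation of confidence forced-choice (CFC) experiments.

The generative model follows classical signal detection theory. On each trial
the stimulus carries a signed strength ``mu_s`` and the observer receives a
noisy sensory sample ``s = mu_s + eps_s`` with ``eps_s ~ N(0, sigma_s^2)``,
responding "right" (+1) when ``s`` exceeds the criterion ``c`` and "left" (-1)
otherwise.  Every two trials form a pair; the observer then judges which of
the two decisions is more likely correct.  The confidence evidence of trial
``i`` is

    w_i = alpha * mu_tilde_i + (1 - alpha) * (s_i - c) / sigma_s + eps_c,

where ``mu_tilde = (mu_s - c) / sigma_s`` is the normalized stimulus strength,
``eps_c ~ N(0, sigma_c^2)`` is confidence noise and ``alpha`` in [0, 1] is the
confidence boost (the fraction of confidence evidence drawn from stimulus
information not used by the perceptual decision).  Interval 1 is chosen when
``w_1 * r_1 + interval_bias > w_2 * r_2``, i.e. confidence compares the
evidence in favour of each chosen response.

Setting ``alpha = 0``, ``sigma_c = 0`` and ``interval_bias = 0`` recovers the
ideal confidence observer, whose confidence uses exactly the evidence of the
perceptual decision.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusDesign", "GenerativeObserver", "ConditionEffect", "PopulationSpec",
    "build_pair_design", "exp1_design", "online_design", "scaled_design",
    "sample_observers", "simulate_trials", "simulate_confidence",
    "apply_condition",
    "EXP1_LEVELS", "CONTRAST_LEVELS",
]

#: Unsigned gaze-deviation magnitudes (degrees) of the face stimuli; the full
#: signed level set is 0 plus +/- each nonzero magnitude.
EXP1_LEVELS = (0.0, 1.75, 3.5, 5.25, 7.0)

#: Unsigned iris-contrast-difference magnitudes (percent Michelson contrast).
CONTRAST_LEVELS = (0.0, 5.0, 10.0, 15.0, 20.0)

TRIALS_PER_PAIR = 2


def _signed_levels(magnitudes: Sequence[float]) -> tuple[float, ...]:
    """Expand unsigned magnitudes to the signed level set (0 included once)."""
    mags = sorted(set(abs(float(m)) for m in magnitudes))
    return tuple([-m for m in reversed(mags) if m > 0] + list(mags))


@dataclass(frozen=True)
class StimulusDesign:
    """A method-of-constant-stimuli pairing design.

    ``pair_counts`` maps ordered combinations ``(level_1, level_2)`` of signed
    stimulus strengths to the number of pairs presented at that combination.
    Every pair contributes exactly two trials (interval 1 and interval 2).
    """

    signed_levels: tuple[float, ...]
    pair_counts: dict[tuple[float, float], int]
    label: str = "custom"
    trials_per_pair: int = TRIALS_PER_PAIR

    def __post_init__(self) -> None:
        levels = set(self.signed_levels)
        for (l1, l2), n in self.pair_counts.items():
            if l1 not in levels or l2 not in levels:
                raise ValueError(f"pair level {(l1, l2)} not in signed_levels")
            if n < 0:
                raise ValueError(f"negative pair count for {(l1, l2)}")
        if self.trials_per_pair != 2:
            raise ValueError("a confidence forced choice pairs exactly 2 trials")

    @property
    def n_pairs(self) -> int:
        return int(sum(self.pair_counts.values()))

    @property
    def n_trials(self) -> int:
        return self.trials_per_pair * self.n_pairs


def build_pair_design(
    levels: Sequence[float],
    base_count: int = 4,
    matched_extra: int = 8,
    adjacent_extra: int = 4,
    count_overrides: Mapping[tuple[float, float], int] | None = None,
    label: str = "custom",
) -> StimulusDesign:
    """Enumerate a pairing design from signed stimulus levels.

    Every ordered combination of signed levels receives ``base_count`` pairs;
    combinations of equal unsigned strength receive ``matched_extra`` more and
    combinations whose unsigned strengths differ by exactly one step of the
    magnitude ladder receive ``adjacent_extra`` more.  ``count_overrides``
    adds to (or, with negative values, subtracts from) individual ordered
    combinations after the enumeration; the resulting count must stay >= 0.

    Pairs of very unequal difficulty yield ceiling confidence choices and are
    deliberately under-represented relative to matched and near-matched pairs.
    """
    signed = tuple(sorted(set(float(v) for v in levels)))
    if not signed:
        raise ValueError("levels must be non-empty")
    if set(signed) != set(-v for v in signed):
        raise ValueError("signed levels must be symmetric about 0")
    if min(base_count, matched_extra, adjacent_extra) < 0:
        raise ValueError("pair counts must be non-negative")

    mags = sorted(set(abs(v) for v in signed))
    step = {m: i for i, m in enumerate(mags)}

    counts: dict[tuple[float, float], int] = {}
    for l1, l2 in itertools.product(signed, signed):
        n = base_count
        if abs(l1) == abs(l2):
            n += matched_extra
        if abs(step[abs(l1)] - step[abs(l2)]) == 1:
            n += adjacent_extra
        counts[(l1, l2)] = n

    for combo, extra in (count_overrides or {}).items():
        key = (float(combo[0]), float(combo[1]))
        counts[key] = counts.get(key, 0) + int(extra)
        if counts[key] < 0:
            raise ValueError(f"override drives count below zero at {key}")

    return StimulusDesign(signed_levels=signed, pair_counts=counts, label=label)


def exp1_design(magnitudes: Sequence[float] = EXP1_LEVELS) -> StimulusDesign:
    """The laboratory design: 576 pairs / 1,152 trials over 9 signed levels.

    The counting rules (4 pairs per ordered combination, + 8 for matched
    unsigned strength, + 4 for strengths one step apart) enumerate to 572
    pairs; the shipped default adds one pair to each of the four ordered
    combinations of 0 with the smallest nonzero magnitude so the total is
    exactly 576 pairs.
    """
    signed = _signed_levels(magnitudes)
    first = min(m for m in (abs(v) for v in signed) if m > 0)
    overrides = {
        (0.0, first): 1, (0.0, -first): 1, (first, 0.0): 1, (-first, 0.0): 1,
    }
    return build_pair_design(signed, 4, 8, 4, count_overrides=overrides,
                             label="exp1")


def scaled_design(design: StimulusDesign, n_pairs: int, label: str | None = None,
                  ) -> StimulusDesign:
    """Rescale a design to a target pair total by largest-remainder rounding."""
    if n_pairs < 0:
        raise ValueError("n_pairs must be >= 0")
    total = design.n_pairs
    keys = sorted(design.pair_counts)
    exact = np.array([design.pair_counts[k] * n_pairs / total for k in keys])
    floor = np.floor(exact).astype(int)
    short = n_pairs - int(floor.sum())
    # hand the remaining pairs to the largest fractional parts (stable order)
    order = np.argsort(-(exact - floor), kind="stable")[:short]
    floor[order] += 1
    counts = {k: int(n) for k, n in zip(keys, floor) if n > 0}
    return StimulusDesign(design.signed_levels, counts,
                          label=label or f"{design.label}_scaled")


def online_design(magnitudes: Sequence[float] = EXP1_LEVELS,
                  n_pairs: int = 167) -> StimulusDesign:
    """The online design: 167 pairs (334 trials) per task, scaled from exp1."""
    return scaled_design(exp1_design(magnitudes), n_pairs, label="online")


@dataclass(frozen=True)
class GenerativeObserver:
    """Latent observer parameters for the CFC generative model.

    sigma_s : sensory noise SD, stimulus units
    criterion : perceptual response criterion c, stimulus units
    sigma_c : confidence noise SD, normalized-evidence units
    alpha : confidence boost in [0, 1]
    interval_bias : additive preference for interval 1 at the confidence stage
    """

    sigma_s: float
    criterion: float = 0.0
    sigma_c: float = 0.0
    alpha: float = 0.0
    interval_bias: float = 0.0
    id: str = "obs"

    def __post_init__(self) -> None:
        if not self.sigma_s > 0:
            raise ValueError("sigma_s must be > 0")
        if self.sigma_c < 0:
            raise ValueError("sigma_c must be >= 0")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


@dataclass(frozen=True)
class ConditionEffect:
    """Additive shift of confidence parameters representing a condition.

    The mechanistic account of such shifts (masking, post-decision time) lives
    in :mod:`metaconf.accumulation`; this is the reduced static description.
    """

    delta_sigma_c: float = 0.0
    delta_alpha: float = 0.0
    label: str = "condition"


@dataclass(frozen=True)
class PopulationSpec:
    """Independent Gaussian population distributions per observer field.

    Each entry is ``(mean, sd)``.  Draws are clipped into the valid parameter
    ranges (``sigma_s > 0``, ``sigma_c >= 0``, ``alpha`` in [0, 1]).
    """

    sigma_s: tuple[float, float] = (3.5, 0.7)
    criterion: tuple[float, float] = (0.0, 0.5)
    sigma_c: tuple[float, float] = (0.5, 0.15)
    alpha: tuple[float, float] = (0.2, 0.1)
    interval_bias: tuple[float, float] = (0.0, 0.1)

    def __post_init__(self) -> None:
        for name in ("sigma_s", "criterion", "sigma_c", "alpha", "interval_bias"):
            mean, sd = getattr(self, name)
            if sd < 0:
                raise ValueError(f"{name}: population SD must be >= 0")


def sample_observers(n: int, population_spec: PopulationSpec | None = None,
                     seed: int | np.random.Generator | None = None,
                     ) -> list[GenerativeObserver]:
    """Draw ``n`` independent observers from a population specification."""
    if n < 1:
        raise ValueError("n must be >= 1")
    spec = population_spec or PopulationSpec()
    rng = np.random.default_rng(seed)

    def draw(pair, lo=-np.inf, hi=np.inf):
        mean, sd = pair
        return np.clip(rng.normal(mean, sd, n), lo, hi)

    sigma_s = draw(spec.sigma_s, lo=1e-6)
    criterion = draw(spec.criterion)
    sigma_c = draw(spec.sigma_c, lo=0.0)
    alpha = draw(spec.alpha, lo=0.0, hi=1.0)
    bias = draw(spec.interval_bias)
    return [
        GenerativeObserver(sigma_s=float(sigma_s[i]), criterion=float(criterion[i]),
                           sigma_c=float(sigma_c[i]), alpha=float(alpha[i]),
                           interval_bias=float(bias[i]), id=f"obs{i:03d}")
        for i in range(n)
    ]


def apply_condition(observers: Sequence[GenerativeObserver],
                    effect: ConditionEffect) -> list[GenerativeObserver]:
    """Return modified copies of the observers; originals are untouched."""
    out = []
    for obs in observers:
        out.append(replace(
            obs,
            sigma_c=max(0.0, obs.sigma_c + effect.delta_sigma_c),
            alpha=float(np.clip(obs.alpha + effect.delta_alpha, 0.0, 1.0)),
        ))
    return out


TRIAL_COLUMNS = ["participant", "task", "condition", "pair", "interval",
                 "mu_s", "response", "rt_ms", "block", "s_latent"]
PAIR_COLUMNS = ["participant", "pair", "confidence_choice",
                "correct_1", "correct_2"]


def simulate_trials(design: StimulusDesign, observer: GenerativeObserver,
                    seed: int | np.random.Generator | None = None,
                    task: str = "task", condition: str = "none",
                    rt_lognormal: tuple[float, float] | None = None,
                    ) -> pd.DataFrame:
    """Simulate the perceptual stage of a CFC session.

    Returns a trial table with two rows per pair (intervals 1 and 2), in
    randomized pair order.  The realized sensory sample is kept in the
    ``s_latent`` column so the confidence stage can reuse the same evidence;
    it is not part of what a real experiment records.

    ``rt_lognormal`` optionally draws nuisance reaction times with the given
    ``(median_ms, sigma_log)``; accumulation-derived RTs come from
    :mod:`metaconf.accumulation`.
    """
    rng = np.random.default_rng(seed)
    combos = sorted(design.pair_counts)
    mu1 = np.repeat([c[0] for c in combos],
                    [design.pair_counts[c] for c in combos])
    mu2 = np.repeat([c[1] for c in combos],
                    [design.pair_counts[c] for c in combos])
    n_pairs = mu1.size
    order = rng.permutation(n_pairs)
    mu1, mu2 = mu1[order], mu2[order]

    mu = np.empty(2 * n_pairs)
    mu[0::2], mu[1::2] = mu1, mu2
    s = mu + rng.normal(0.0, observer.sigma_s, mu.size)
    response = np.where(s > observer.criterion, 1, -1)

    rt = np.full(mu.size, np.nan)
    if rt_lognormal is not None:
        med, slog = rt_lognormal
        rt = np.exp(rng.normal(np.log(med), slog, mu.size))

    pair_ids = np.repeat(np.arange(n_pairs), 2)
    return pd.DataFrame({
        "participant": observer.id,
        "task": task,
        "condition": condition,
        "pair": pair_ids,
        "interval": np.tile([1, 2], n_pairs),
        "mu_s": mu,
        "response": response,
        "rt_ms": rt,
        "block": pair_ids * 2 // max(1, n_pairs),  # two half-session blocks
        "s_latent": s,
    })


def simulate_confidence(trials: pd.DataFrame, observer: GenerativeObserver,
                        seed: int | np.random.Generator | None = None,
                        ) -> pd.DataFrame:
    """Simulate the confidence forced choice for each pair of trials.

    Reuses the latent sensory sample recorded by :func:`simulate_trials`
    (single-channel assumption: the same evidence drives the decision and,
    up to boost and confidence noise, the confidence judgment).  When the
    latent column is absent, evidence is re-drawn from the truncated Gaussian
    consistent with each recorded response.
    """
    rng = np.random.default_rng(seed)
    t = trials.sort_values(["pair", "interval"], kind="stable")
    counts = t.groupby("pair")["interval"].agg(["count", "sum"])
    if not ((counts["count"] == 2).all() and (counts["sum"] == 3).all()):
        raise ValueError("every pair must have exactly intervals 1 and 2")

    mu = t["mu_s"].to_numpy(float)
    resp = t["response"].to_numpy(int)
    if "s_latent" in t.columns and not t["s_latent"].isna().any():
        s = t["s_latent"].to_numpy(float)
    else:
        s = _redraw_evidence(mu, resp, observer, rng)

    mu_tilde = (mu - observer.criterion) / observer.sigma_s
    ev = (s - observer.criterion) / observer.sigma_s
    w = (observer.alpha * mu_tilde + (1.0 - observer.alpha) * ev
         + rng.normal(0.0, observer.sigma_c, mu.size))

    w1, w2 = w[0::2], w[1::2]
    r1, r2 = resp[0::2], resp[1::2]
    lhs = w1 * r1 + observer.interval_bias
    rhs = w2 * r2
    choice = np.where(lhs > rhs, 1, 2)
    ties = lhs == rhs
    if ties.any():  # probability-zero under continuous noise
        choice[ties] = rng.integers(1, 3, ties.sum())

    mu1, mu2 = mu[0::2], mu[1::2]
    return pd.DataFrame({
        "participant": observer.id,
        "pair": t["pair"].to_numpy()[0::2],
        "confidence_choice": choice,
        "correct_1": r1 * mu1 > 0,
        "correct_2": r2 * mu2 > 0,
    })


def _redraw_evidence(mu: np.ndarray, resp: np.ndarray,
                     observer: GenerativeObserver,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw s ~ N(mu, sigma_s^2) truncated to the side of the criterion
    implied by each recorded response (inverse-CDF sampling)."""
    from scipy.special import ndtr, ndtri
    z_c = (observer.criterion - mu) / observer.sigma_s
    p_below = ndtr(z_c)
    u = rng.uniform(size=mu.size)
    q = np.where(resp > 0, p_below + u * (1 - p_below), u * p_below)
    q = np.clip(q, 1e-14, 1 - 1e-14)
    return mu + observer.sigma_s * ndtri(q)
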