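"""End-to-end orchestration: generate -> fit -> exclude/normalize -> CFC ->
bootstrap -> Bayesian effects, with stable delimited-text formats.

Experiment templates mirror the study designs they emulate:

========  =========================================================
exp1      laboratory design, 576 pairs/task, backward mask, within-
          subject high- vs low-level task comparison
exp2      online design, 167 pairs/task, response cue 100 ms after
          stimulus offset, high vs low task
exp3      online, 800 ms cue delay, mask vs no-mask within subjects
exp4      online, 100 vs 800 ms cue delay within subjects
exp5      as exp4 with the biological-motion stimulus levels
========  =========================================================

Every stochastic stage derives its RNG stream from the master seed plus the
stage name, so a config + seed reproduces a run bit for bit.
"""

from __future__ import annotations

import hashlib
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from metaconf import cfc_model, hbayes, psychometric, synthetic_data
from metaconf.synthetic_data import ConditionEffect, PopulationSpec

__all__ = [
    "RunConfig", "ResultsBundle", "run_experiment",
    "read_trials", "write_trials", "read_pairs", "write_pairs",
    "write_results", "stage_rng",
]

log = logging.getLogger("metaconf")

_TEMPLATES = {
    "exp1": dict(design="exp1", n_observers=20, contrasts=("high", "low")),
    "exp2": dict(design="online", n_observers=92, contrasts=("high", "low")),
    "exp3_low": dict(design="online", n_observers=93,
                     contrasts=("mask", "nomask")),
    "exp3_high": dict(design="online", n_observers=92,
                      contrasts=("mask", "nomask")),
    "exp4": dict(design="online", n_observers=90, contrasts=("short", "long")),
    "exp5": dict(design="online", n_observers=81, contrasts=("short", "long")),
}


@dataclass
class RunConfig:
    """Configuration of an end-to-end synthetic run."""

    template: str = "exp2"
    n_observers: int | None = None
    n_pairs: int | None = None
    population: PopulationSpec = field(default_factory=PopulationSpec)
    condition_effects: dict[str, ConditionEffect] = field(default_factory=dict)
    n_boot: int = 1000
    bin_width: float = 0.2
    mcmc: hbayes.MCMCConfig = field(default_factory=hbayes.MCMCConfig)
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("template", "n_observers", "n_pairs", "n_boot",
                    "bin_width", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "population" in raw:
            pop = {k: tuple(v) for k, v in raw["population"].items()}
            kwargs["population"] = PopulationSpec(**pop)
        if "condition_effects" in raw:
            kwargs["condition_effects"] = {
                name: ConditionEffect(label=name, **eff)
                for name, eff in raw["condition_effects"].items()}
        if "mcmc" in raw:
            kwargs["mcmc"] = hbayes.MCMCConfig(**raw["mcmc"])
        return cls(**kwargs)


@dataclass
class ResultsBundle:
    config: RunConfig
    exclusions: pd.DataFrame
    psychometric_fits: dict[str, dict[str, psychometric.PsychometricFit]]
    cfc_fits: dict[str, cfc_model.CFCFit]
    effect: hbayes.EffectPosterior | None
    n_pairs_aggregated: dict[str, int]
    provenance: dict


def stage_rng(master_seed: int, stage: str) -> np.random.Generator:
    """Derive a stage-specific RNG stream from the master seed."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:4], "little"))


# ---------------------------------------------------------------------------
# delimited-text formats
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    """Read a trial table, validating the declared schema.

    Unknown columns are preserved; schema violations are reported with their
    location.
    """
    df = pd.read_csv(path)
    required = ["participant", "pair", "interval", "mu_s", "response"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["response"].isin([-1, 1])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: invalid response "
                         f"{df['response'].iloc[row]!r} at row {row} "
                         "(must be -1 or +1)")
    bad = ~df["interval"].isin([1, 2])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: invalid interval at row {row}")
    return df


def write_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    pairs.to_csv(path, index=False)


def read_pairs(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = ["participant", "pair", "confidence_choice"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["confidence_choice"].isin([1, 2])
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"{path}: invalid confidence_choice at row {row}")
    return df


def write_results(bundle: ResultsBundle, out_dir: str | Path) -> list[Path]:
    """Write the bundle as delimited text + nested structured results."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    p = out / "exclusions.csv"
    bundle.exclusions.to_csv(p, index=False)
    written.append(p)

    results: dict = {"provenance": bundle.provenance, "cfc": {}}
    for label, fit in bundle.cfc_fits.items():
        entry = {
            "sigma_c": fit.params.sigma_c, "alpha": fit.params.alpha,
            "interval_bias": fit.params.interval_bias, "nll": fit.nll,
            "n_pairs": fit.n_pairs, "tau2_ideal": fit.tau2_ideal,
            "tau2_human": fit.tau2_human, "efficiency": fit.efficiency,
        }
        if fit.bootstrap is not None:
            entry["bootstrap"] = {
                "n_boot": fit.bootstrap.n_boot,
                "n_failed": fit.bootstrap.n_failed,
                "mean": fit.bootstrap.mean, "sd": fit.bootstrap.sd,
                "ci95": {k: list(v) for k, v in fit.bootstrap.ci95.items()},
            }
        results["cfc"][label] = entry
    if bundle.effect is not None:
        eff = bundle.effect
        results["effect"] = {
            "posterior_mean_delta": eff.posterior_mean,
            "hdi_95": list(eff.hdi_95), "bf10": eff.bf10,
            "ess": eff.ess, "rhat": eff.rhat,
            "mcmc": asdict(eff.config),
        }
    p = out / "results.yaml"
    p.write_text(yaml.safe_dump(results, sort_keys=True))
    written.append(p)
    return written


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def _design_for(config: RunConfig):
    tpl = _TEMPLATES[config.template]
    if tpl["design"] == "exp1":
        design = synthetic_data.exp1_design()
    else:
        design = synthetic_data.online_design()
    if config.n_pairs is not None:
        design = synthetic_data.scaled_design(design, config.n_pairs)
    return design, tpl


def run_experiment(config: RunConfig) -> ResultsBundle:
    """Execute the full analysis chain on synthetic data.

    Stages: sample observers, simulate both conditions, fit psychometric
    functions, apply exclusions, normalize, aggregate, fit the CFC model per
    condition with a participant bootstrap, and estimate the within-subject
    effect size of condition on confidence efficiency.
    """
    t0 = time.time()
    design, tpl = _design_for(config)
    n_obs = config.n_observers or tpl["n_observers"]
    cond_a, cond_b = tpl["contrasts"]
    log.info("template=%s design=%s pairs=%d observers=%d",
             config.template, design.label, design.n_pairs, n_obs)

    observers = synthetic_data.sample_observers(
        n_obs, config.population, stage_rng(config.seed, "observers"))

    records: dict[str, list[pd.DataFrame]] = {cond_a: [], cond_b: []}
    pair_tables: dict[str, pd.DataFrame] = {}
    fits: dict[str, dict[str, psychometric.PsychometricFit]] = {
        cond_a: {}, cond_b: {}}
    stim_range = float(max(design.signed_levels) - min(design.signed_levels))

    for cond in (cond_a, cond_b):
        effect = config.condition_effects.get(cond)
        cond_observers = (synthetic_data.apply_condition(observers, effect)
                          if effect else observers)
        for obs in cond_observers:
            rng = stage_rng(config.seed, f"simulate:{cond}:{obs.id}")
            trials = synthetic_data.simulate_trials(
                design, obs, rng, task=cond, condition=cond,
                rt_lognormal=(600.0, 0.3))
            pairs = synthetic_data.simulate_confidence(trials, obs, rng)
            fit = psychometric.fit_psychometric(trials)
            fits[cond][obs.id] = fit
            norm = psychometric.normalize_strengths(trials, fit)
            records[cond].append(
                cfc_model.pair_records(norm, pairs).assign(condition=cond))
            key = obs.id if cond == cond_a else f"{obs.id}:{cond}"
            pair_tables[key] = pairs
    log.info("simulation + psychometric fits done (%.1f s)", time.time() - t0)

    exclusions = psychometric.apply_exclusions(
        fits[cond_a], {o.id: pair_tables[o.id] for o in observers},
        stimulus_range=stim_range)
    excluded = {r.participant for r in exclusions if r.excluded}
    exclusions_df = pd.DataFrame([asdict(r) for r in exclusions])

    cfc_fits: dict[str, cfc_model.CFCFit] = {}
    n_aggregated: dict[str, int] = {}
    boot_samples: dict[str, np.ndarray] = {}
    for cond in (cond_a, cond_b):
        rec = pd.concat(records[cond], ignore_index=True)
        rec = rec[~rec["participant"].isin(excluded)]
        counts = cfc_model.aggregate_pairs(rec, bin_width=config.bin_width)
        fit = cfc_model.fit_cfc(counts)
        # both conditions share the bootstrap stream (and hence the same
        # participant resamples), so effect distributions are paired
        boot = cfc_model.bootstrap_fit(
            rec, n_boot=config.n_boot,
            seed=stage_rng(config.seed, "bootstrap"),
            bin_width=config.bin_width, start=fit.params)
        cfc_fits[cond] = fit.with_bootstrap(boot)
        n_aggregated[cond] = fit.n_pairs
        boot_samples[cond] = boot.samples["efficiency"]
        log.info("CFC fit %s: sigma_c=%.3f alpha=%.3f eta=%.3f (%.1f s)",
                 cond, fit.params.sigma_c, fit.params.alpha, fit.efficiency,
                 time.time() - t0)

    effect = None
    n_included = n_obs - len(excluded)
    if (boot_samples[cond_a].size == boot_samples[cond_b].size
            and boot_samples[cond_a].size >= max(2, n_included)
            and n_included >= 2):
        data = hbayes.paired_pseudosubjects(
            boot_samples[cond_a], boot_samples[cond_b], n_included,
            family="gamma")
        effect = hbayes.fit_within_effect(
            data, config.mcmc, stage_rng(config.seed, "effect"))
        log.info("effect: delta=%.3f hdi=%s bf10=%.3g (%.1f s)",
                 effect.posterior_mean, effect.hdi_95, effect.bf10,
                 time.time() - t0)

    provenance = {
        "template": config.template, "seed": config.seed,
        "n_observers": n_obs, "n_excluded": len(excluded),
        "design_pairs": design.n_pairs,
        "config_hash": hashlib.sha256(repr(sorted(
            (k, v) for k, v in asdict(config).items() if k != "out_dir"
        )).encode()).hexdigest()[:16],
        "elapsed_s": round(time.time() - t0, 2),
    }
    bundle = ResultsBundle(config=config, exclusions=exclusions_df,
                           psychometric_fits=fits, cfc_fits=cfc_fits,
                           effect=effect, n_pairs_aggregated=n_aggregated,
                           provenance=provenance)
    if config.out_dir:
        write_results(bundle, config.out_dir)
    return bundle
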