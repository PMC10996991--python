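"""Designs, generative observers, and forward simulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import ndtr

import metaconf as mc


class TestPairDesign:
    @pytest.mark.parametrize("factory,n_pairs,n_trials", [
        (mc.exp1_design, 576, 1152),
        (mc.online_design, 167, 334),
    ])
    def test_shipped_design_totals(self, factory, n_pairs, n_trials):
        d = factory()
        assert d.n_pairs == n_pairs
        assert d.n_trials == n_trials

    def test_minimal_enumeration(self):
        # 3 signed levels, one pair per ordered combination
        d = mc.build_pair_design([-1, 0, 1], base_count=1, matched_extra=0,
                                 adjacent_extra=0)
        assert d.n_pairs == 9
        assert d.n_trials == 18

    def test_literal_exp1_counting_gives_572(self):
        # without the override the stated counting rules undershoot by 4
        d = mc.build_pair_design(
            [-7, -5.25, -3.5, -1.75, 0, 1.75, 3.5, 5.25, 7], 4, 8, 4)
        assert d.n_pairs == 572

    def test_asymmetric_levels_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            mc.build_pair_design([0, 1, 2], base_count=1)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mc.build_pair_design([-1, 0, 1], base_count=-1)
        with pytest.raises(ValueError, match="below zero"):
            mc.build_pair_design([-1, 0, 1], base_count=1, matched_extra=0,
                                 adjacent_extra=0,
                                 count_overrides={(0.0, 0.0): -2})

    def test_scaled_design_totals_conserved(self):
        d = mc.scaled_design(mc.exp1_design(), 167)
        assert d.n_pairs == 167
        assert d.n_trials == 334

    @given(st.lists(st.floats(0.5, 10), min_size=1, max_size=4, unique=True),
           st.integers(0, 5), st.integers(0, 5), st.integers(0, 5))
    @settings(max_examples=40, deadline=None)
    def test_trials_are_twice_pairs(self, mags, base, matched, adjacent):
        levels = sorted({-m for m in mags} | {0.0} | set(mags))
        d = mc.build_pair_design(levels, base, matched, adjacent)
        assert d.n_trials == 2 * d.n_pairs
        assert all(v >= 0 for v in d.pair_counts.values())
        assert all(l1 in d.signed_levels and l2 in d.signed_levels
                   for l1, l2 in d.pair_counts)


class TestObservers:
    def test_zero_variance_population_is_identical(self):
        spec = mc.PopulationSpec(sigma_s=(3.5, 0), criterion=(0, 0),
                                 sigma_c=(0.5, 0), alpha=(0.2, 0),
                                 interval_bias=(0, 0))
        obs = mc.sample_observers(20, spec, seed=0)
        assert len(obs) == 20
        assert len({(o.sigma_s, o.criterion, o.sigma_c, o.alpha,
                     o.interval_bias) for o in obs}) == 1

    def test_cohort_size(self):
        assert len(mc.sample_observers(92, seed=1)) == 92

    def test_seed_reproducibility(self):
        a = mc.sample_observers(10, seed=42)
        b = mc.sample_observers(10, seed=42)
        assert a == b

    def test_invalid_hyperparameters(self):
        with pytest.raises(ValueError):
            mc.PopulationSpec(sigma_s=(3.5, -1.0))
        with pytest.raises(ValueError):
            mc.sample_observers(0)

    def test_parameter_invariants_enforced(self):
        with pytest.raises(ValueError):
            mc.GenerativeObserver(sigma_s=-1.0)
        with pytest.raises(ValueError):
            mc.GenerativeObserver(sigma_s=1.0, alpha=1.5)

    def test_apply_condition_identity_and_clipping(self):
        obs = [mc.GenerativeObserver(sigma_s=3.0, sigma_c=0.4, alpha=0.3)]
        same = mc.apply_condition(obs, mc.ConditionEffect(0.0, 0.0))
        assert same[0].sigma_c == obs[0].sigma_c
        assert same[0].alpha == obs[0].alpha
        clipped = mc.apply_condition(obs, mc.ConditionEffect(-1.0, -1.0))
        assert clipped[0].sigma_c == 0.0
        assert clipped[0].alpha == 0.0
        assert obs[0].alpha == 0.3  # original untouched


class TestSimulateTrials:
    def test_psychometric_proportions_match_gaussian(self):
        # forward-simulated response rates vs the closed-form oracle
        design = mc.build_pair_design([-3.5, 0, 3.5], base_count=2000,
                                      matched_extra=0, adjacent_extra=0)
        obs = mc.GenerativeObserver(sigma_s=3.5, criterion=0.7, id="o")
        trials = mc.simulate_trials(design, obs, seed=3)
        for mu, sub in trials.groupby("mu_s"):
            p_hat = (sub["response"] > 0).mean()
            p = ndtr((mu - obs.criterion) / obs.sigma_s)
            se = np.sqrt(p * (1 - p) / len(sub))
            assert abs(p_hat - p) < 3 * se

    def test_noiseless_limit(self):
        design = mc.build_pair_design([-7, 0, 7], base_count=50,
                                      matched_extra=0, adjacent_extra=0)
        obs = mc.GenerativeObserver(sigma_s=1e-9, criterion=0.0)
        trials = mc.simulate_trials(design, obs, seed=0)
        strong = trials[trials["mu_s"] == 7.0]
        assert (strong["response"] == 1).all()

    def test_at_criterion_is_chance(self):
        design = mc.build_pair_design([-2, 0, 2], base_count=3000,
                                      matched_extra=0, adjacent_extra=0)
        obs = mc.GenerativeObserver(sigma_s=1.0, criterion=2.0)
        trials = mc.simulate_trials(design, obs, seed=5)
        at_c = trials[trials["mu_s"] == 2.0]
        p = (at_c["response"] > 0).mean()
        assert abs(p - 0.5) < 3 * np.sqrt(0.25 / len(at_c))

    def test_pair_structure_and_determinism(self):
        design = mc.online_design()
        obs = mc.GenerativeObserver(sigma_s=3.5, id="x")
        a = mc.simulate_trials(design, obs, seed=9)
        b = mc.simulate_trials(design, obs, seed=9)
        assert a.to_csv() == b.to_csv()  # byte-identical under a fixed seed
        counts = a.groupby("pair")["interval"].agg(["count", "sum"])
        assert (counts["count"] == 2).all() and (counts["sum"] == 3).all()
        assert len(a) == design.n_trials


class TestSimulateConfidence:
    def _sim(self, observer, seed=0, n=4000):
        design = mc.build_pair_design([-3.5, -1.75, 0, 1.75, 3.5],
                                      base_count=n // 25, matched_extra=0,
                                      adjacent_extra=0)
        trials = mc.simulate_trials(design, observer, seed=seed)
        pairs = mc.simulate_confidence(trials, observer, seed=seed + 1)
        return trials, pairs

    def test_ideal_observer_reproduces_evidence_rule(self):
        # alpha=0, sigma_c=0, no bias: the choice must deterministically
        # follow the latent normalized evidence signed by each response
        obs = mc.GenerativeObserver(sigma_s=2.0, criterion=0.3)
        trials, pairs = self._sim(obs, seed=11)
        t = trials.sort_values(["pair", "interval"])
        ev = ((t["s_latent"] - obs.criterion) / obs.sigma_s).to_numpy()
        r = t["response"].to_numpy()
        w = ev * r
        expect = np.where(w[0::2] > w[1::2], 1, 2)
        assert (pairs.sort_values("pair")["confidence_choice"].to_numpy()
                == expect).all()

    def test_extreme_confidence_noise_is_chance(self):
        obs = mc.GenerativeObserver(sigma_s=2.0, sigma_c=1e6)
        _, pairs = self._sim(obs, seed=2, n=8000)
        p1 = (pairs["confidence_choice"] == 1).mean()
        assert abs(p1 - 0.5) < 3 * np.sqrt(0.25 / len(pairs))

    def test_large_bias_exceeds_exclusion_threshold(self):
        obs = mc.GenerativeObserver(sigma_s=2.0, sigma_c=0.5,
                                    interval_bias=5.0)
        _, pairs = self._sim(obs, seed=3)
        assert (pairs["confidence_choice"] == 1).mean() > 0.78

    def test_inconsistent_pair_structure_rejected(self):
        obs = mc.GenerativeObserver(sigma_s=2.0)
        trials, _ = self._sim(obs, seed=4, n=100)
        broken = trials.drop(trials.index[0])
        with pytest.raises(ValueError, match="pair"):
            mc.simulate_confidence(broken, obs, seed=0)

    def test_redrawn_evidence_consistent_with_responses(self):
        # without the latent column, confidence evidence is re-drawn from the
        # response-conditioned truncated Gaussian; choices stay near-ideal
        # in distribution for the ideal observer
        obs = mc.GenerativeObserver(sigma_s=2.0)
        trials, pairs_latent = self._sim(obs, seed=6, n=8000)
        blind = trials.drop(columns=["s_latent"])
        pairs_blind = mc.simulate_confidence(blind, obs, seed=7)
        p_lat = (pairs_latent["confidence_choice"] == 1).mean()
        p_bld = (pairs_blind["confidence_choice"] == 1).mean()
        assert abs(p_lat - p_bld) < 0.05
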