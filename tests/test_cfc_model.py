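"""Pair-choice probabilities, CFC fitting, equivalent noise, bootstrap."""

import numpy as np
import pandas as pd
import pytest

import metaconf as mc
from metaconf.cfc_model import (
    IDEAL, OUTCOMES, _alpha1_probability, _alpha1_accuracy, _count_matrix,
)


def mc_outcome_freqs(mu1, mu2, params, n, rng):
    """Monte-Carlo oracle for the 8-outcome law (independent route)."""
    s1 = rng.normal(mu1, 1.0, n)
    s2 = rng.normal(mu2, 1.0, n)
    r1 = np.where(s1 > 0, 1, -1)
    r2 = np.where(s2 > 0, 1, -1)
    w1 = params.alpha * mu1 + (1 - params.alpha) * s1 \
        + rng.normal(0, params.sigma_c, n)
    w2 = params.alpha * mu2 + (1 - params.alpha) * s2 \
        + rng.normal(0, params.sigma_c, n)
    lhs = w1 * r1 + params.interval_bias
    rhs = w2 * r2
    ch1 = lhs > rhs
    ties = lhs == rhs  # only possible in the degenerate noiseless family
    if ties.any():
        ch1 = ch1 | (ties & (rng.uniform(size=n) < 0.5))
    freqs = np.empty(8)
    for j, (a, b, ch) in enumerate(OUTCOMES):
        m = (r1 == a) & (r2 == b)
        freqs[j] = np.mean(m & (ch1 if ch == 1 else ~ch1))
    return freqs


def normalized_online_design():
    """The online design expressed in normalized units for a sigma_s = 3.5
    observer: signed levels [0, 0.5, 1, 1.5, 2]."""
    return mc.online_design(magnitudes=(0.0, 0.5, 1.0, 1.5, 2.0))


def simulate_cohort(n_obs, sigma_c, alpha, seed, design=None, bias=0.0):
    """Pair records from identical observers in exact normalized units."""
    design = design or normalized_online_design()
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n_obs):
        obs = mc.GenerativeObserver(sigma_s=1.0, criterion=0.0,
                                    sigma_c=sigma_c, alpha=alpha,
                                    interval_bias=bias, id=f"o{i:03d}")
        t = mc.simulate_trials(design, obs, rng)
        p = mc.simulate_confidence(t, obs, rng)
        recs.append(mc.cfc_model.pair_records(t, p))
    return pd.concat(recs, ignore_index=True)


PARAM_GRID = [
    mc.CFCParams(0.0, 0.0, 0.0),
    mc.CFCParams(0.5, 0.3, 0.0),
    mc.CFCParams(1.0, 0.0, 0.2),
    mc.CFCParams(0.0, 0.5, -0.1),
    mc.CFCParams(0.3, 1.0, 0.0),
    mc.CFCParams(2.0, 0.2, 0.3),
]


class TestPairChoiceProbability:
    @pytest.mark.parametrize("params", PARAM_GRID)
    def test_valid_distribution(self, params):
        mu1 = np.array([0.0, 0.5, -1.0, 2.0, 0.0])
        mu2 = np.array([0.0, -0.5, 1.0, 0.0, 1.5])
        p = mc.pair_choice_probability(mu1, mu2, params)
        assert (p >= 0).all()
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    @pytest.mark.parametrize("params", [mc.CFCParams(0.5, 0.3, 0.0),
                                        mc.CFCParams(2.0, 0.0, 0.0)])
    def test_symmetric_pair_is_chance(self, params):
        # mu1 = mu2 = 0, no bias: interval 1 chosen half the time
        p = mc.pair_choice_probability([0.0], [0.0], params)[0]
        p_ch1 = sum(p[j] for j, (_, _, ch) in enumerate(OUTCOMES) if ch == 1)
        assert p_ch1 == pytest.approx(0.5, abs=1e-5)

    def test_ideal_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        for mu1, mu2 in [(0.3, -0.8), (1.2, 0.0), (0.0, 0.0)]:
            p = mc.pair_choice_probability([mu1], [mu2], IDEAL)[0]
            f = mc_outcome_freqs(mu1, mu2, IDEAL, 400000, rng)
            assert np.abs(p - f).max() < 0.004

    @pytest.mark.parametrize("params", PARAM_GRID[1:4])
    def test_against_mc_oracle(self, params):
        rng = np.random.default_rng(1)
        p = mc.pair_choice_probability([0.7], [-0.4], params)[0]
        f = mc_outcome_freqs(0.7, -0.4, params, 200000, rng)
        assert np.abs(p - f).max() < 0.006

    def test_alpha1_closed_form_matches_quadrature(self):
        # dual route: the boost-1 family has an exact closed form
        mu1 = np.array([0.0, 0.6, -1.1])
        mu2 = np.array([0.4, -0.6, 0.0])
        for tau in (0.3, 1.0):
            a = _alpha1_probability(mu1, mu2, tau)
            b = mc.pair_choice_probability(mu1, mu2,
                                           mc.CFCParams(tau, 1.0, 0.0))
            assert np.abs(a - b).max() < 1e-6

    def test_quadrature_converged(self):
        params = mc.CFCParams(0.0, 0.4, 0.1)  # kinked inner integrand
        a = mc.pair_choice_probability([0.7], [-0.3], params, n_nodes=64)
        b = mc.pair_choice_probability([0.7], [-0.3], params, n_nodes=256)
        assert np.abs(a - b).max() < 1e-4

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            mc.pair_choice_probability([np.inf], [0.0], IDEAL)
        with pytest.raises(ValueError):
            mc.pair_choice_probability([0.0, 1.0], [0.0], IDEAL)


class TestFitCFC:
    def test_recovery_from_simulated_cohort(self):
        rec = simulate_cohort(40, sigma_c=0.5, alpha=0.2, seed=2)
        counts = mc.aggregate_pairs(rec)
        fit = mc.fit_cfc(counts)
        assert fit.converged
        mu1, mu2, mat = _count_matrix(counts)
        design = (mu1, mu2, mat.sum(axis=1))
        eta_gen = mc.efficiency(mc.CFCParams(0.5, 0.2, 0.0), design)
        assert abs(fit.efficiency - eta_gen) / eta_gen < 0.2

    def test_ideal_data_recovers_unit_efficiency(self):
        # sigma_c and alpha trade off along a likelihood ridge, so the point
        # estimate need not sit at (0, 0) in finite samples; what the data
        # identify is efficiency, and the ideal point must be statistically
        # indistinguishable from the optimum
        rec = simulate_cohort(30, sigma_c=0.0, alpha=0.0, seed=3)
        counts = mc.aggregate_pairs(rec)
        fit = mc.fit_cfc(counts)
        assert fit.efficiency == pytest.approx(1.0, abs=0.1)
        mu1, mu2, mat = _count_matrix(counts)
        p = mc.pair_choice_probability(mu1, mu2, IDEAL)
        nll_ideal = float(-(mat * np.log(np.clip(p, 1e-300, None))).sum())
        assert nll_ideal - fit.nll < 3.0

    def test_permuted_choices_destroy_information(self):
        rec = simulate_cohort(30, sigma_c=0.3, alpha=0.1, seed=4)
        rng = np.random.default_rng(5)
        rec["choice"] = rng.permutation(rec["choice"].to_numpy())
        fit = mc.fit_cfc(mc.aggregate_pairs(rec))
        assert fit.params.sigma_c > 2.0
        assert fit.efficiency < 0.2

    def test_posterior_predictive_consistency(self):
        # frequencies implied by the fitted model match the observed ones
        rec = simulate_cohort(40, sigma_c=0.4, alpha=0.3, seed=6)
        counts = mc.aggregate_pairs(rec)
        fit = mc.fit_cfc(counts)
        mu1, mu2, mat = _count_matrix(counts)
        keep = mat.sum(axis=1) >= 50
        p_model = mc.pair_choice_probability(mu1[keep], mu2[keep], fit.params)
        n_cell = mat[keep].sum(axis=1, keepdims=True)
        f_obs = mat[keep] / n_cell
        z = (f_obs - p_model) / np.sqrt(
            np.clip(p_model * (1 - p_model), 1e-9, None) / n_cell)
        assert np.mean(np.abs(z) < 3) > 0.95

    def test_single_cell_warns(self):
        counts = pd.DataFrame({"mu1": [0.5] * 2, "mu2": [0.5] * 2,
                               "r1": [1, 1], "r2": [1, -1],
                               "choice": [1, 2], "count": [10, 12]})
        with pytest.warns(RuntimeWarning, match="identifiable"):
            mc.fit_cfc(counts, compute_efficiency=False)


class TestEquivalentNoise:
    def _design(self, seed=0, n=300):
        rng = np.random.default_rng(seed)
        mu1 = rng.normal(0, 1.2, n)
        mu2 = rng.normal(0, 1.2, n)
        return (mu1, mu2, np.ones(n))

    def test_ideal_efficiency_is_unity(self):
        for seed in range(3):
            eta = mc.efficiency(IDEAL, self._design(seed))
            assert eta == pytest.approx(1.0, abs=0.02)

    def test_rootfind_matches_grid_scan(self):
        design = self._design(1)
        target = mc.CFCParams(0.6, 0.1, 0.0)
        tau2 = mc.equivalent_noise(target, design)
        # independent route: coarse grid scan of the matching accuracy
        probs = mc.pair_choice_probability(design[0], design[1], target)
        acc = mc.choice_accuracy(design[0], design[1], probs, design[2])
        taus = np.geomspace(1e-3, 100, 3000)
        accs = np.array([_alpha1_accuracy(t, design[0], design[1], design[2])
                         for t in taus])
        tau_grid = taus[np.argmin(np.abs(accs - acc))]
        assert abs(np.sqrt(tau2) - tau_grid) / tau_grid < 0.01

    def test_efficiency_monotone_in_sigma_c(self):
        design = self._design(2)
        etas = [mc.efficiency(mc.CFCParams(s, 0.0, 0.0), design)
                for s in (0.25, 0.5, 1.0, 2.0)]
        assert all(a > b for a, b in zip(etas, etas[1:]))

    def test_efficiency_monotone_in_alpha(self):
        design = self._design(3)
        etas = [mc.efficiency(mc.CFCParams(0.5, a, 0.0), design)
                for a in (0.0, 0.3, 0.7, 1.0)]
        assert all(a < b for a, b in zip(etas, etas[1:]))

    def test_doubling_noise_reduces_efficiency(self):
        design = self._design(4)
        t2_a = mc.equivalent_noise(mc.CFCParams(0.5, 0.0, 0.0), design)
        t2_b = mc.equivalent_noise(mc.CFCParams(1.0, 0.0, 0.0), design)
        assert t2_b > t2_a

    def test_degenerate_design_rejected(self):
        zeros = (np.zeros(5), np.zeros(5), np.ones(5))
        with pytest.raises(ValueError, match="degenerate"):
            mc.equivalent_noise(IDEAL, zeros)


class TestBootstrap:
    def test_resample_count_and_determinism(self):
        rec = simulate_cohort(8, sigma_c=0.5, alpha=0.2, seed=7,
                              design=mc.scaled_design(mc.online_design(), 40))
        a = mc.bootstrap_fit(rec, n_boot=12, seed=11)
        b = mc.bootstrap_fit(rec, n_boot=12, seed=11)
        assert a.samples["efficiency"].size + a.n_failed == 12
        assert np.array_equal(a.samples["sigma_c"], b.samples["sigma_c"])

    def test_single_participant_degenerate(self):
        rec = simulate_cohort(1, sigma_c=0.4, alpha=0.1, seed=8)
        boot = mc.bootstrap_fit(rec, n_boot=5, seed=0)
        assert boot.sd["sigma_c"] == pytest.approx(0.0, abs=1e-12)
        assert np.unique(boot.samples["efficiency"]).size == 1
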