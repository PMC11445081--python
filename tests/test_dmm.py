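import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.special import logsumexp
from scipy.stats import multinomial

from neostate.dmm import (component_drivers, dm_logpmf, fit_dmm, laplace_score,
                          select_k_dmm)
from neostate.simulate import CommunityConfig, simulate_states_counts
from neostate.tables import CountTable


def make_counts(rows, depth=None):
    rows = np.asarray(rows, dtype=np.int64)
    depth = depth or int(rows.sum(axis=1).max())
    return CountTable(pd.DataFrame(
        rows, index=[f"s{i}" for i in range(rows.shape[0])],
        columns=[f"sp{j}" for j in range(rows.shape[1])]), depth=depth)


def polya_urn_logpmf(x, alpha):
    """Independent oracle: enumerate all ordered draw sequences of the urn."""
    x = tuple(int(v) for v in x)
    n = sum(x)
    total = 0.0
    for seq in itertools.product(range(len(x)), repeat=n):
        if tuple(seq.count(j) for j in range(len(x))) != x:
            continue
        prob = 1.0
        counts = [0] * len(x)
        for t, j in enumerate(seq):
            prob *= (alpha[j] + counts[j]) / (sum(alpha) + t)
            counts[j] += 1
        total += prob
    return np.log(total)


class TestDmLogpmf:
    def test_one_draw_from_symmetric_urn(self):
        assert dm_logpmf([1, 0], [1.0, 1.0]) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_two_draws_sequential_urn_product(self):
        # P((2,0)) = 1/2 * 2/3 = 1/3 by the sequential urn argument
        assert dm_logpmf([2, 0], [1.0, 1.0]) == pytest.approx(np.log(1 / 3), abs=1e-12)

    def test_matches_polya_urn_enumeration(self):
        alpha = [0.7, 1.3, 2.0]
        for x in itertools.product(range(4), repeat=3):
            if not 0 < sum(x) <= 4:
                continue
            assert dm_logpmf(x, alpha) == pytest.approx(
                polya_urn_logpmf(x, alpha), abs=1e-10)

    def test_large_concentration_approaches_multinomial(self):
        p = np.array([0.2, 0.3, 0.5])
        x = np.array([4, 6, 10])
        got = dm_logpmf(x, 1e6 * p)
        ref = multinomial.logpmf(x, n=20, p=p)
        assert got == pytest.approx(ref, abs=1e-3)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            dm_logpmf([0.5, 0.5], [1, 1])
        with pytest.raises(ValueError):
            dm_logpmf([1, 1], [1, 0])


class TestFitDmm:
    def test_single_component_matches_direct_optimizer(self):
        rng = np.random.default_rng(5)
        p = rng.dirichlet([5.0, 3.0, 2.0], size=10)  # finite overdispersion
        counts = make_counts(np.array([rng.multinomial(200, pi) for pi in p]), depth=200)
        fit = fit_dmm(counts, 1, tol=1e-8)
        X = counts.values

        def negll(log_alpha):
            return -sum(dm_logpmf(row, np.exp(log_alpha)) for row in X)

        res = minimize(negll, np.zeros(3), method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000})
        assert fit.loglik == pytest.approx(-res.fun, abs=1e-4)

    def test_identical_samples_give_identical_responsibility_rows(self):
        counts = make_counts(np.tile([50, 30, 20], (8, 1)), depth=100)
        fit = fit_dmm(counts, 2, max_iter=50)
        assert np.isfinite(fit.loglik)
        assert np.allclose(fit.responsibilities, fit.responsibilities[0], atol=1e-6)

    def test_planted_three_components_recovered(self, small_mixture):
        counts, _, truth = small_mixture
        fit = fit_dmm(counts, 3, seed=0)
        hard = np.argmax(fit.responsibilities, axis=1)
        # optimal label matching, then assignment accuracy
        best = 0
        for perm in itertools.permutations(range(3)):
            mapped = np.array([("BB", "EF", "BL")[perm[h]] for h in hard])
            best = max(best, np.mean(mapped == truth["state"].to_numpy()))
        assert best >= 0.9

    def test_responsibility_rows_sum_to_one(self, small_mixture):
        counts, _, _ = small_mixture
        fit = fit_dmm(counts, 2, seed=1)
        assert np.allclose(fit.responsibilities.sum(axis=1), 1.0, atol=1e-8)
        assert fit.pi.sum() == pytest.approx(1.0, abs=1e-8)
        assert np.all(fit.alpha > 0)

    def test_more_components_than_samples_rejected(self):
        counts = make_counts([[60, 40], [30, 70]], depth=100)
        with pytest.raises(ValueError):
            fit_dmm(counts, 5)


class TestLaplaceScore:
    def test_matches_independent_scalar_assembly_for_k1(self):
        rng = np.random.default_rng(7)
        p = rng.dirichlet([6.0, 4.0], size=5)
        counts = make_counts(np.array([rng.multinomial(150, pi) for pi in p]), depth=150)
        fit = fit_dmm(counts, 1, tol=1e-8)
        X = counts.values
        sd = 3.0

        def neg_log_post(theta):
            alpha = np.exp(theta)
            ll = sum(dm_logpmf(row, alpha) for row in X)
            lp = -0.5 * len(theta) * np.log(2 * np.pi * sd ** 2) \
                - 0.5 * (theta ** 2).sum() / sd ** 2
            return -(ll + lp)

        theta = np.log(fit.alpha[0])
        d = theta.size
        h = 1e-4
        H = np.zeros((d, d))
        for i in range(d):
            for j in range(d):
                ei = np.eye(d)[i] * h
                ej = np.eye(d)[j] * h
                H[i, j] = (neg_log_post(theta + ei + ej) - neg_log_post(theta + ei - ej)
                           - neg_log_post(theta - ei + ej)
                           + neg_log_post(theta - ei - ej)) / (4 * h * h)
        log_prior = -0.5 * d * np.log(2 * np.pi * sd ** 2) - 0.5 * (theta ** 2).sum() / sd ** 2
        expected = -(fit.loglik + log_prior + 0.5 * d * np.log(2 * np.pi)
                     - 0.5 * np.linalg.slogdet(H)[1])
        assert laplace_score(fit, counts, prior_sd=sd) == pytest.approx(expected, rel=1e-4)

    def test_one_component_data_prefers_k1(self):
        rng = np.random.default_rng(3)
        p = rng.dirichlet(np.full(5, 10.0), size=40)
        counts = make_counts(np.array([rng.multinomial(500, pi) for pi in p]), depth=500)
        fit1 = fit_dmm(counts, 1)
        fit2 = fit_dmm(counts, 2)
        assert laplace_score(fit1, counts) < laplace_score(fit2, counts)

    def test_unconverged_fit_rejected(self, small_mixture):
        counts, _, _ = small_mixture
        fit = fit_dmm(counts, 2, seed=1)
        fit.converged = False
        with pytest.raises(ValueError):
            laplace_score(fit, counts)


class TestSelectK:
    def test_planted_two_components_chosen(self):
        cfg = CommunityConfig(n_samples=120, n_species=8, depth=2000,
                              states=("BB", "EF"), pi=(0.5, 0.5),
                              dominance=(0.6, 0.25))
        counts, _, _ = simulate_states_counts(cfg, seed=4)
        K, scores, _ = select_k_dmm(counts, range(1, 5), seed=4)
        assert K == 2

    def test_singleton_range_trivial(self, small_mixture):
        counts, _, _ = small_mixture
        K, scores, _ = select_k_dmm(counts, [1])
        assert K == 1


class TestComponentDrivers:
    def test_expected_abundance_ranking(self, small_mixture):
        counts, _, _ = small_mixture
        fit = fit_dmm(counts, 1)
        fit.alpha = np.array([[8.0, 1.0, 1.0]])
        fit.species_ids = ["a", "b", "c"]
        drivers = component_drivers(fit, m=2)
        assert drivers["C0"][0] == ("a", pytest.approx(0.8))

    def test_ties_break_by_species_order(self, small_mixture):
        counts, _, _ = small_mixture
        fit = fit_dmm(counts, 1)
        fit.alpha = np.array([[2.0, 2.0, 2.0]])
        fit.species_ids = ["a", "b", "c"]
        assert [s for s, _ in component_drivers(fit, m=3)["C0"]] == ["a", "b", "c"]

    def test_planted_drivers_recovered_rank_one(self, small_mixture):
        counts, _, truth = small_mixture
        fit = fit_dmm(counts, 3, seed=0)
        tops = {component_drivers(fit, m=1)[f"C{k}"][0][0] for k in range(3)}
        assert tops == {"B_breve", "E_faecalis", "B_longum"}
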