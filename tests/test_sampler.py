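"""Exact conditional-distribution checks for the Gibbs blocks.

Each block's conditional is compared against brute-force enumeration of
prior × likelihood on tiny cases (1 person / few items), at 1e-10.
"""

import numpy as np
import pytest
from scipy.stats import beta as beta_dist

from rtcdm import _sampler
from rtcdm.core import enumerate_latent_classes, mastery_matrix, validate_qmatrix
from rtcdm.model import PriorSpec, dic_from_deviance
from rtcdm.rtf import logdensity_rt


def make_data(q_raw, Y, logRT, model_form="DINA", rg=True, priors=None):
    q = validate_qmatrix(np.asarray(q_raw))
    profiles = enumerate_latent_classes(q.n_attributes)
    eta = mastery_matrix(q, profiles, model_form)
    return _sampler.SamplerData(
        Y=np.atleast_2d(Y), logRT=np.atleast_2d(logRT), eta=eta,
        profiles=profiles, q=q.q, rg=rg, priors=priors or PriorSpec(),
    )


def base_state(data, **overrides):
    I, J = data.I, data.J
    state = {
        "alpha_idx": np.zeros(I, dtype=int),
        "xi": np.ones((I, J), dtype=np.int8),
        "g": np.full(J, 0.2),
        "s": np.full(J, 0.1),
        "beta": np.full(J, 3.0),
        "kappa": np.ones(J),
        "tau": np.zeros(I),
        "sigma_tau": 0.3,
        "class_w": np.full(data.C, 1.0 / data.C),
        "pi": np.full(J, 0.9),
        "beta0": 2.0,
        "kappa0": 1.6,
    }
    state.update(overrides)
    return state


class TestAlphaConditional:
    def test_single_item_two_classes(self):
        """One item, g=0.2, s=0.1, uniform prior, Y=1, ξ=1 → P(mastery)=9/11."""
        data = make_data([[1]], [[1]], [[1.0]])
        state = base_state(data)
        probs = _sampler.alpha_conditional_probs(state, data)
        assert probs[0, 1] == pytest.approx(9 / 11, abs=1e-10)

    def test_all_rapid_guesses_return_class_prior(self):
        """ξ ≡ 0: responses carry no attribute information."""
        data = make_data([[1, 0], [0, 1]], [[1, 0]], [[1.0, 1.0]])
        w = np.array([0.1, 0.2, 0.3, 0.4])
        state = base_state(data, xi=np.zeros((1, 2), dtype=np.int8), class_w=w)
        probs = _sampler.alpha_conditional_probs(state, data)
        np.testing.assert_allclose(probs[0], w, atol=1e-9)

    def test_matches_brute_force_enumeration(self):
        """K=2, 3 items: conditional pmf equals the explicit product over classes."""
        q = [[1, 0], [0, 1], [1, 1]]
        Y = [[1, 0, 1], [0, 1, 1]]
        logRT = np.log([[2.0, 3.0, 4.0], [1.0, 1.5, 9.0]])
        data = make_data(q, Y, logRT)
        g = np.array([0.15, 0.25, 0.2])
        s = np.array([0.1, 0.05, 0.12])
        xi = np.array([[1, 1, 0], [1, 1, 1]], dtype=np.int8)
        w = np.array([0.4, 0.3, 0.2, 0.1])
        state = base_state(data, g=g, s=s, xi=xi, class_w=w)
        probs = _sampler.alpha_conditional_probs(state, data)

        profiles = enumerate_latent_classes(2)
        for i in range(2):
            brute = np.zeros(4)
            for c, prof in enumerate(profiles):
                lik = w[c]
                for j in range(3):
                    if xi[i, j] == 1:
                        mastered = all(prof[k] for k in range(2) if q[j][k])
                        p = 1 - s[j] if mastered else g[j]
                    else:
                        p = g[j]
                    lik *= p if Y[i][j] == 1 else 1 - p
                brute[c] = lik
            brute /= brute.sum()
            np.testing.assert_allclose(probs[i], brute, atol=1e-10)


class TestXiConditional:
    def test_worked_cell(self):
        """π=0.9, P(Y|ξ=1)=0.9, P(Y|ξ=0)=0.2, RT density ratio 2 → 1.62/1.64."""
        # κ=2 vs κ₀=1 with rt at both means gives an exact density ratio of 2
        data = make_data([[1]], [[1]], [[2.0]])
        state = base_state(data, alpha_idx=np.array([1]), kappa=np.array([2.0]),
                           beta=np.array([2.0]), beta0=2.0, kappa0=1.0)
        prob = _sampler.xi_conditional_probs(state, data)
        assert prob[0, 0] == pytest.approx(1.62 / 1.64, abs=1e-10)

    def test_pi_one_forces_solution_attempt(self):
        data = make_data([[1]], [[0]], [[0.5]])
        state = base_state(data, pi=np.array([1.0]))
        assert _sampler.xi_conditional_probs(state, data)[0, 0] == 1.0

    def test_equal_likelihoods_return_pi(self):
        """Identical likelihood under both branches → P(ξ=1) = π exactly."""
        # non-mastery profile: response likelihood is g either way; match RT laws
        data = make_data([[1]], [[1]], [[1.3]])
        state = base_state(data, alpha_idx=np.array([0]), beta=np.array([2.0]),
                           kappa=np.array([1.6]), tau=np.zeros(1), beta0=2.0, kappa0=1.6,
                           pi=np.array([0.73]))
        assert _sampler.xi_conditional_probs(state, data)[0, 0] == pytest.approx(0.73, abs=1e-12)

    def test_uses_observed_scale_densities(self):
        """The branch odds reproduce two-term Bayes with the module's RT density."""
        rt, beta, kappa, tau, b0, k0, pi = 3.7, 3.1, 0.8, 0.25, 2.0, 1.6, 0.85
        data = make_data([[1]], [[0]], [[np.log(rt)]])
        state = base_state(data, alpha_idx=np.array([1]), beta=np.array([beta]),
                           kappa=np.array([kappa]), tau=np.array([tau]),
                           beta0=b0, kappa0=k0, pi=np.array([pi]))
        f1 = np.exp(logdensity_rt(rt, tau, beta, kappa, 1))
        f0 = np.exp(logdensity_rt(rt, tau, beta, kappa, 0, beta0=b0, kappa0=k0))
        num = pi * 0.1 * f1          # Y=0 with mastery: probability s=0.1
        den = num + (1 - pi) * 0.8 * f0  # Y=0 under rapid guess: 1−g=0.8
        got = _sampler.xi_conditional_probs(state, data)[0, 0]
        assert got == pytest.approx(num / den, abs=1e-10)


class TestConjugateCounts:
    def test_gs_cell_partition(self):
        """g-cells = rapid guesses plus failed-gate attempts; s-cells = passed-gate attempts."""
        q = [[1], [1]]
        Y = [[1, 0], [1, 1]]
        data = make_data(q, Y, np.zeros((2, 2)))
        xi = np.array([[1, 0], [1, 1]], dtype=np.int8)
        state = base_state(data, alpha_idx=np.array([0, 1]), xi=xi)
        succ_g, fail_g, succ_s, fail_s = _sampler.gs_success_counts(state, data)
        # person 0 non-mastery: both cells g-cells (one ξ=0); person 1 mastery, ξ=1: s-cells
        np.testing.assert_array_equal(succ_g, [1, 0])
        np.testing.assert_array_equal(fail_g, [0, 1])
        np.testing.assert_array_equal(succ_s, [1, 1])
        np.testing.assert_array_equal(fail_s, [0, 0])

    def test_beta_binomial_posterior_matches_enumeration(self):
        """30 successes / 70 failures with Beta(1,1) → Beta(31,71), mean ≈ 0.3039;
        the truncated-Beta sampler reproduces exactly that CDF below the bound."""
        a, b = 1 + 30, 1 + 70
        assert a / (a + b) == pytest.approx(0.30392156862, abs=1e-9)
        # inverse-CDF draw with a stubbed uniform recovers the analytic quantile
        class StubRng:
            def random(self, shape=None):
                return np.full(shape, 0.5) if shape else 0.5
        x = _sampler._truncated_beta(np.array([a]), np.array([b]), 0.0, np.array([1.0]),
                                     StubRng())
        assert x[0] == pytest.approx(beta_dist.ppf(0.5, a, b), abs=1e-10)

    def test_truncation_never_violates_support(self, rng):
        x = _sampler._truncated_beta(np.full(200, 2.0), np.full(200, 2.0),
                                     0.3, np.full(200, 0.5), rng)
        assert ((x > 0.3) & (x < 0.5)).all()

    def test_pi_posterior_mean(self, rng):
        """800/1000 solution attempts with Beta(1,1) → Beta(801,201), mean ≈ 0.7994."""
        I = 1000
        data = make_data([[1]], np.ones((I, 1), dtype=int), np.zeros((I, 1)))
        xi = np.zeros((I, 1), dtype=np.int8)
        xi[:800] = 1
        state = base_state(data, xi=xi)
        draws = []
        for _ in range(4000):
            _sampler.update_pi(state, data, rng)
            draws.append(state["pi"][0])
        assert 801 / 1002 == pytest.approx(0.79940, abs=1e-4)
        assert np.mean(draws) == pytest.approx(801 / 1002, abs=3 * 0.0127 / np.sqrt(4000))

    def test_prior_recovered_with_no_cells(self, rng):
        """All ξ=1 leaves zero rapid-guess evidence? No — zero-count case: a
        one-person dataset with ξ absent from an item is impossible, so test
        π with zero ξ=1 cells: posterior = Beta(a, b + I)."""
        I = 50
        data = make_data([[1]], np.ones((I, 1), dtype=int), np.zeros((I, 1)))
        state = base_state(data, xi=np.zeros((I, 1), dtype=np.int8))
        draws = []
        for _ in range(4000):
            _sampler.update_pi(state, data, rng)
            draws.append(state["pi"][0])
        expected = 1 / (1 + 1 + I)
        assert np.mean(draws) == pytest.approx(expected, abs=5e-3)


class TestTauConditional:
    def test_three_cell_weighted_average(self):
        """Precision = 1/σ_τ² + Σκ²; mean = weighted residual average (oracle)."""
        q = [[1], [1], [1]]
        logRT = np.array([[1.0, 2.0, 3.0]])
        data = make_data(q, [[1, 1, 0]], logRT)
        beta = np.array([3.0, 2.5, 4.0])
        kappa = np.array([1.0, 2.0, 0.5])
        state = base_state(data, beta=beta, kappa=kappa, sigma_tau=0.3)
        mean, prec = _sampler.tau_posterior_params(state, data)
        k2 = kappa ** 2
        prec_oracle = 1 / 0.09 + k2.sum()
        mean_oracle = (k2 * (beta - logRT[0])).sum() / prec_oracle
        assert prec[0] == pytest.approx(prec_oracle, abs=1e-10)
        assert mean[0] == pytest.approx(mean_oracle, abs=1e-10)

    def test_all_rapid_guesses_fall_back_to_prior(self):
        data = make_data([[1]], [[1]], [[2.0]])
        state = base_state(data, xi=np.zeros((1, 1), dtype=np.int8), sigma_tau=0.3)
        mean, prec = _sampler.tau_posterior_params(state, data)
        assert mean[0] == pytest.approx(0.0, abs=1e-12)
        assert prec[0] == pytest.approx(1 / 0.09, abs=1e-10)


class TestMarginalDeviance:
    def test_matches_brute_force_mixture(self):
        """2 persons × 2 items, K=1: enumerate α and ξ explicitly."""
        q = [[1], [1]]
        Y = np.array([[1, 0], [1, 1]])
        RT = np.array([[2.0, 8.0], [1.0, 4.0]])
        data = make_data(q, Y, np.log(RT))
        state = base_state(data, g=np.array([0.2, 0.3]), s=np.array([0.1, 0.15]),
                           beta=np.array([2.5, 3.0]), kappa=np.array([1.0, 0.8]),
                           tau=np.array([0.2, -0.1]), pi=np.array([0.9, 0.8]),
                           class_w=np.array([0.45, 0.55]))
        got = _sampler.marginal_deviance(state, data)

        total = 0.0
        for i in range(2):
            person_lik = 0.0
            for c, alpha in enumerate([0, 1]):
                lik = state["class_w"][c]
                for j in range(2):
                    cell = 0.0
                    for xi in (0, 1):
                        p = (1 - state["s"][j] if alpha else state["g"][j]) if xi else state["g"][j]
                        py = p if Y[i, j] else 1 - p
                        f = np.exp(logdensity_rt(RT[i, j], state["tau"][i], state["beta"][j],
                                                 state["kappa"][j], xi, 2.0, 1.6))
                        w = state["pi"][j] if xi else 1 - state["pi"][j]
                        cell += w * py * f
                    lik *= cell
                person_lik += lik
            total += np.log(person_lik)
        assert got == pytest.approx(-2 * total, rel=1e-9)


class TestDicHelper:
    def test_degenerate_posterior_zero_pd(self):
        dev = np.full(200, 123.4)
        dic, _ = dic_from_deviance(dev, 123.4)
        assert dic == pytest.approx(123.4)

    def test_single_bernoulli_half(self):
        """y=1, every draw p=0.5, no RT term → DIC = −2 log 0.5 ≈ 1.3863."""
        d = -2 * np.log(0.5)
        dic, pd_ = dic_from_deviance(np.full(150, d), d)
        assert dic == pytest.approx(1.3862943611, abs=1e-9)
        assert pd_ == pytest.approx(0.0, abs=1e-12)

    def test_requires_enough_draws(self):
        with pytest.raises(ValueError):
            dic_from_deviance(np.ones(50), 1.0)
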