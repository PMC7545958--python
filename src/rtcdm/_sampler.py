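"""Metropolis-within-Gibbs kernel for the joint response/response-time models.

The sampler alternates exact conditional draws for

* attribute profiles α_i — categorical over all 2^K latent classes,
* behavior indicators ξ_ij — Bernoulli from the two-branch likelihood ratio,
* class probabilities — Dirichlet from class counts,
* solution-attempt probabilities π_j — Beta from ξ counts,
* guessing/slipping (g_j, 1−s_j) — truncated Betas keeping g_j < 1−s_j,
* person speeds τ_i, time intensities β_j, β₀ — normal–normal updates,
* time discriminations κ_j², κ₀² — Gamma from squared residuals,

plus one random-walk Metropolis step on log σ_τ (half-normal prior on σ_τ).

Everything is vectorized over persons, items and classes.  The conditional
*distributions* (not just the draws) are exposed so tests can compare them
against brute-force enumeration.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp
from scipy.stats import beta as beta_dist
from scipy.stats import norm as norm_dist

__all__ = [
    "SamplerData",
    "init_state",
    "alpha_conditional_probs",
    "update_alpha",
    "xi_conditional_probs",
    "update_xi",
    "update_class_probs",
    "update_pi",
    "gs_success_counts",
    "tau_posterior_params",
    "update_item_response_params",
    "update_rt_params",
    "marginal_deviance",
    "run_chain",
]

_LOG_2PI = np.log(2.0 * np.pi)
_EPS = 1e-12


class SamplerData:
    """Precomputed, immutable per-fit quantities."""

    def __init__(self, Y, logRT, eta, profiles, q, rg, priors):
        self.Y = np.asarray(Y, dtype=np.float64)
        self.Ybar = 1.0 - self.Y
        self.logRT = np.asarray(logRT, dtype=np.float64)
        self.eta = np.asarray(eta, dtype=bool)          # (C, J) gate per class×item
        self.profiles = np.asarray(profiles)            # (C, K)
        self.q = np.asarray(q)                          # (J, K)
        self.rg = bool(rg)
        self.priors = priors
        self.I, self.J = self.Y.shape
        self.C = self.eta.shape[0]


def init_state(data: SamplerData, rng) -> dict:
    """Data-driven starting point.

    Attributes from a per-attribute correct-rate split, ξ = 1 everywhere,
    g/s/κ/π at values interior to their supports, β_j at the per-item mean
    log RT, and β₀ at the 10th percentile of pooled log RT (rapid guesses
    sit in the short-time tail, which also anchors the mixture labels).
    """
    I, J, K = data.I, data.J, data.profiles.shape[1]
    q = data.q
    score = np.zeros((I, K))
    for k in range(K):
        items = np.flatnonzero(q[:, k] == 1)
        score[:, k] = data.Y[:, items].mean(axis=1)
    alpha0 = (score > np.median(score, axis=0, keepdims=True)).astype(np.int8)
    bits = 1 << np.arange(K)
    state = {
        "alpha_idx": alpha0 @ bits,
        "xi": np.ones((I, J), dtype=np.int8),
        "g": np.full(J, 0.2),
        "s": np.full(J, 0.1),
        "beta": data.logRT.mean(axis=0),
        "kappa": np.ones(J),
        "tau": np.zeros(I),
        "sigma_tau": 0.3,
        "class_w": np.full(data.C, 1.0 / data.C),
    }
    if data.rg:
        state["pi"] = np.full(J, 0.9)
        state["beta0"] = float(np.quantile(data.logRT, 0.10))
        state["kappa0"] = 1.0
    return state


# ---------------------------------------------------------------------------
# attribute profiles
# ---------------------------------------------------------------------------

def alpha_conditional_probs(state: dict, data: SamplerData) -> np.ndarray:
    """Exact conditional pmf of each person's latent class, shape (I, C).

    Proportional to class-prior × Π_j P(Y_ij | α, ξ_ij); response times do
    not depend on α, and cells with ξ_ij = 0 contribute a factor constant
    in α (the guessing intercept) that cancels in the normalization.
    """
    lp = np.where(data.eta, np.log(1.0 - state["s"]), np.log(state["g"]))   # (C, J)
    lq = np.where(data.eta, np.log(state["s"]), np.log(1.0 - state["g"]))
    xi = state["xi"]
    A = data.Y * xi
    B = data.Ybar * xi
    loglik = A @ lp.T + B @ lq.T                                            # (I, C)
    loglik += np.log(state["class_w"] + _EPS)[None, :]
    loglik -= loglik.max(axis=1, keepdims=True)
    p = np.exp(loglik)
    p /= p.sum(axis=1, keepdims=True)
    return p


def update_alpha(state: dict, data: SamplerData, rng) -> None:
    p = alpha_conditional_probs(state, data)
    # Gumbel-max categorical draw, vectorized over persons
    g = rng.gumbel(size=p.shape)
    state["alpha_idx"] = np.argmax(np.log(p + _EPS) + g, axis=1)


# ---------------------------------------------------------------------------
# behavior indicators
# ---------------------------------------------------------------------------

def _log_f1(state, data):
    mean = state["beta"][None, :] - state["tau"][:, None]
    kap = state["kappa"][None, :]
    z = (data.logRT - mean) * kap
    return np.log(kap) - 0.5 * _LOG_2PI - 0.5 * z * z - data.logRT


def _log_f0(state, data):
    z = (data.logRT - state["beta0"]) * state["kappa0"]
    return np.log(state["kappa0"]) - 0.5 * _LOG_2PI - 0.5 * z * z - data.logRT


def xi_conditional_probs(state: dict, data: SamplerData) -> np.ndarray:
    """P(ξ_ij = 1 | ·): posterior odds π_j·P(Y|ξ=1)·f₁(RT) : (1−π_j)·P(Y|ξ=0)·f₀(RT).

    Both RT factors are observed-scale lognormal densities; the 1/rt terms
    cancel in the ratio but are kept for clarity of convention.
    """
    eta_i = data.eta[state["alpha_idx"]]                                    # (I, J)
    p1 = np.where(eta_i, 1.0 - state["s"][None, :], state["g"][None, :])
    p0 = state["g"][None, :]
    lpy1 = np.where(data.Y == 1, np.log(p1), np.log(1.0 - p1))
    lpy0 = np.where(data.Y == 1, np.log(p0), np.log(1.0 - p0))
    pi = state["pi"][None, :]
    with np.errstate(divide="ignore"):
        logodds = (
            np.log(pi) - np.log1p(-pi) + lpy1 - lpy0 + _log_f1(state, data) - _log_f0(state, data)
        )
    prob = 1.0 / (1.0 + np.exp(-logodds))
    prob = np.where(pi == 1.0, 1.0, prob)
    return prob


def update_xi(state: dict, data: SamplerData, rng) -> None:
    prob = xi_conditional_probs(state, data)
    state["xi"] = (rng.random(prob.shape) < prob).astype(np.int8)


# ---------------------------------------------------------------------------
# conjugate blocks
# ---------------------------------------------------------------------------

def update_class_probs(state: dict, data: SamplerData, rng) -> None:
    counts = np.bincount(state["alpha_idx"], minlength=data.C)
    state["class_w"] = rng.dirichlet(data.priors.dirichlet_conc + counts)


def update_pi(state: dict, data: SamplerData, rng) -> None:
    n1 = state["xi"].sum(axis=0)
    n0 = data.I - n1
    state["pi"] = rng.beta(data.priors.pi_a + n1, data.priors.pi_b + n0)


def _truncated_beta(a, b, lo, hi, rng):
    """Inverse-CDF draw from Beta(a, b) truncated to (lo, hi), vectorized."""
    clo = beta_dist.cdf(lo, a, b)
    chi = beta_dist.cdf(hi, a, b)
    u = clo + (chi - clo) * rng.random(np.shape(a))
    x = beta_dist.ppf(np.clip(u, 1e-15, 1.0 - 1e-15), a, b)
    return np.clip(x, lo + 1e-10, hi - 1e-10)


def gs_success_counts(state: dict, data: SamplerData) -> tuple:
    """Per-item (successes, failures) in the g-cells and the (1−s)-cells.

    g-cells: rapid guesses (ξ=0) plus solution attempts by persons failing
    the gate; (1−s)-cells: solution attempts by persons passing the gate.
    """
    eta_i = data.eta[state["alpha_idx"]]
    xi1 = state["xi"] == 1
    g_mask = (~xi1) | (xi1 & ~eta_i)
    s_mask = xi1 & eta_i
    return (
        (data.Y * g_mask).sum(axis=0),
        (data.Ybar * g_mask).sum(axis=0),
        (data.Y * s_mask).sum(axis=0),
        (data.Ybar * s_mask).sum(axis=0),
    )


def tau_posterior_params(state: dict, data: SamplerData) -> tuple:
    """Mean and precision of each τ_i conditional: each ξ=1 cell contributes
    the observation β_j − log RT_ij with precision κ_j²; prior N(0, σ_τ²)."""
    xi1 = (state["xi"] == 1).astype(float)
    kap2 = state["kappa"] ** 2
    prec = 1.0 / state["sigma_tau"] ** 2 + xi1 @ kap2
    resid = state["beta"][None, :] - data.logRT
    mean = ((xi1 * resid) @ kap2) / prec
    return mean, prec


def update_item_response_params(state: dict, data: SamplerData, rng) -> None:
    """Truncated-Beta Gibbs draws for (g_j, 1−s_j) keeping g_j < 1−s_j."""
    pr = data.priors
    succ_g, fail_g, succ_s, fail_s = gs_success_counts(state, data)
    one_minus_s = 1.0 - state["s"]
    g = _truncated_beta(pr.g_a + succ_g, pr.g_b + fail_g, 0.0, one_minus_s, rng)
    one_minus_s = _truncated_beta(pr.s_a + succ_s, pr.s_b + fail_s, g, 1.0, rng)
    state["g"] = g
    state["s"] = 1.0 - one_minus_s


def update_rt_params(state: dict, data: SamplerData, rng) -> dict:
    """Normal/Gamma conjugate draws for τ, β_j, κ_j (and β₀, κ₀, σ_τ with RG).

    Returns a small diagnostics dict (items with no solution-attempt cells,
    σ_τ Metropolis acceptance).
    """
    pr = data.priors
    xi1 = (state["xi"] == 1).astype(float)
    kap2 = state["kappa"] ** 2
    diag = {"empty_items": 0, "sigma_tau_accept": 0.0}

    mean, prec = tau_posterior_params(state, data)
    state["tau"] = rng.normal(mean, 1.0 / np.sqrt(prec))

    # β_j | · over ξ=1 cells (prior when an item has none)
    n_j = xi1.sum(axis=0)
    target = data.logRT + state["tau"][:, None]          # log RT + τ ≈ β_j
    sum_t = (xi1 * target).sum(axis=0)
    prior_prec = 1.0 / pr.beta_sd ** 2
    prec_b = prior_prec + n_j * kap2
    mean_b = (prior_prec * pr.beta_mean + kap2 * sum_t) / prec_b
    state["beta"] = rng.normal(mean_b, 1.0 / np.sqrt(prec_b))
    diag["empty_items"] = int((n_j == 0).sum())

    # κ_j² | · from squared residuals on ξ=1 cells
    ssr = (xi1 * (target - state["beta"][None, :]) ** 2).sum(axis=0)
    kap2_new = rng.gamma(pr.kappa_shape + 0.5 * n_j, 1.0 / (pr.kappa_rate + 0.5 * ssr))
    state["kappa"] = np.sqrt(kap2_new)

    if data.rg:
        xi0 = 1.0 - xi1
        n0 = xi0.sum()
        sum0 = (xi0 * data.logRT).sum()
        k02 = state["kappa0"] ** 2
        prec0 = prior_prec + n0 * k02
        mean0 = (prior_prec * pr.beta_mean + k02 * sum0) / prec0
        sd0 = 1.0 / np.sqrt(prec0)
        if pr.constrain_beta0:
            # β₀ ≤ min_j β_j pins the short-time mixture component
            ub = (state["beta"].min() - mean0) / sd0
            u = rng.uniform(0.0, norm_dist.cdf(ub))
            state["beta0"] = mean0 + sd0 * norm_dist.ppf(max(u, 1e-15))
        else:
            state["beta0"] = rng.normal(mean0, sd0)
        ssr0 = (xi0 * (data.logRT - state["beta0"]) ** 2).sum()
        state["kappa0"] = np.sqrt(
            rng.gamma(pr.kappa_shape + 0.5 * n0, 1.0 / (pr.kappa_rate + 0.5 * ssr0))
        )

    # σ_τ | τ : random-walk Metropolis on log σ_τ, half-normal(σ_hn) prior
    tau = state["tau"]
    sig = state["sigma_tau"]
    prop = sig * np.exp(0.15 * rng.standard_normal())

    def logpost(sg):
        return (
            -tau.size * np.log(sg)
            - 0.5 * np.sum(tau ** 2) / sg ** 2
            - 0.5 * (sg / pr.sigma_tau_scale) ** 2
            + np.log(sg)  # Jacobian of the log transform
        )

    if np.log(rng.random()) < logpost(prop) - logpost(sig):
        state["sigma_tau"] = prop
        diag["sigma_tau_accept"] = 1.0
    return diag


# ---------------------------------------------------------------------------
# deviance
# ---------------------------------------------------------------------------

def marginal_deviance(state: dict, data: SamplerData) -> float:
    """−2 log L(Y, RT) with α and ξ marginalized at the given parameters.

    Per cell the two behavior branches are mixed with weights (π_j, 1−π_j);
    per person the 2^K classes are mixed with the class probabilities.  RT
    densities are on the observed-seconds scale.
    """
    f1 = np.exp(_log_f1(state, data))
    Y1 = data.Y == 1
    py_mast = np.where(Y1, 1.0 - state["s"], state["s"])
    py_non = np.where(Y1, state["g"], 1.0 - state["g"])
    if data.rg:
        f0 = np.exp(_log_f0(state, data))
        pi = state["pi"][None, :]
        guess_term = (1.0 - pi) * f0 * py_non
        L_mast = pi * f1 * py_mast + guess_term
        L_non = pi * f1 * py_non + guess_term
    else:
        L_mast = f1 * py_mast
        L_non = f1 * py_non
    logL_non = np.log(L_non + _EPS)
    D = np.log(L_mast + _EPS) - logL_non                                   # (I, J)
    base = logL_non.sum(axis=1)                                            # (I,)
    per_class = base[:, None] + D @ data.eta.T.astype(float)               # (I, C)
    ll = logsumexp(per_class + np.log(state["class_w"] + _EPS)[None, :], axis=1)
    return float(-2.0 * ll.sum())


# ---------------------------------------------------------------------------
# chain driver
# ---------------------------------------------------------------------------

def run_chain(data: SamplerData, chain_cfg, rng, progress=False):
    """Run one chain; return kept draws and running posterior means of latents."""
    state = init_state(data, rng)
    I, J, K = data.I, data.J, data.profiles.shape[1]
    n_keep = (chain_cfg.n_iterations - chain_cfg.n_burnin) // chain_cfg.thin
    keep = {
        name: np.empty((n_keep, J))
        for name in ("g", "s", "beta", "kappa") + (("pi",) if data.rg else ())
    }
    for name in ("beta0", "kappa0") if data.rg else ():
        keep[name] = np.empty(n_keep)
    keep["sigma_tau"] = np.empty(n_keep)
    keep["class_w"] = np.empty((n_keep, data.C))
    deviance = np.empty(n_keep)
    alpha_probs = np.zeros((I, K))
    xi_probs = np.zeros((I, J))
    tau_sum = np.zeros(I)
    tau_sumsq = np.zeros(I)
    diag = {"empty_items": 0, "sigma_tau_accept": 0.0}

    kept = 0
    for it in range(chain_cfg.n_iterations):
        update_alpha(state, data, rng)
        if data.rg:
            update_xi(state, data, rng)
            update_pi(state, data, rng)
        update_class_probs(state, data, rng)
        update_item_response_params(state, data, rng)
        d = update_rt_params(state, data, rng)
        diag["empty_items"] += d["empty_items"]
        diag["sigma_tau_accept"] += d["sigma_tau_accept"]
        if it >= chain_cfg.n_burnin and (it - chain_cfg.n_burnin) % chain_cfg.thin == 0:
            for name in ("g", "s", "beta", "kappa"):
                keep[name][kept] = state[name]
            if data.rg:
                keep["pi"][kept] = state["pi"]
                keep["beta0"][kept] = state["beta0"]
                keep["kappa0"][kept] = state["kappa0"]
            keep["sigma_tau"][kept] = state["sigma_tau"]
            keep["class_w"][kept] = state["class_w"]
            deviance[kept] = marginal_deviance(state, data)
            alpha_probs += data.profiles[state["alpha_idx"]]
            xi_probs += state["xi"]
            tau_sum += state["tau"]
            tau_sumsq += state["tau"] ** 2
            kept += 1

    alpha_probs /= kept
    xi_probs /= kept
    tau_mean = tau_sum / kept
    tau_var = np.maximum(tau_sumsq / kept - tau_mean ** 2, 0.0)
    diag["sigma_tau_accept"] /= chain_cfg.n_iterations
    return {
        "draws": keep,
        "deviance": deviance,
        "alpha_probs": alpha_probs,
        "xi_probs": xi_probs,
        "tau_mean": tau_mean,
        "tau_sd": np.sqrt(tau_var),
        "diagnostics": diag,
    }
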