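"""Model/Results interface for Bayesian estimation of the joint models.

:class:`RTCDModel` wraps a dataset (binary responses Y, response times RT,
Q-matrix) together with a response rule (DINA or DINO) and an optional
rapid-guessing mixture; :meth:`RTCDModel.fit` runs the Gibbs sampler and
returns an :class:`RTCDMResults` holding posterior draws, posterior-mean
latent summaries, convergence diagnostics, a ``summary()`` table and DIC.

The four estimable variants:

===============  ========  ===========
model            rule      RG mixture
===============  ========  ===========
RT-DINA          DINA      no
RT-DINO          DINO      no
RT-DINA-RG       DINA      yes
RT-DINO-RG       DINO      yes
===============  ========  ===========

The saturated (G-DINA) response rule is available in the forward model
(:mod:`rtcdm.irf`, :mod:`rtcdm.simulate` accepts DINA/DINO) but is not
estimated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from . import _sampler
from .core import Dataset, enumerate_latent_classes, mastery_matrix

__all__ = ["PriorSpec", "ChainConfig", "RTCDModel", "RTCDMResults", "dic_from_deviance"]


@dataclass(frozen=True)
class PriorSpec:
    """Weakly-informative default priors, conjugate where possible.

    g_j ~ Beta(g_a, g_b); 1−s_j ~ Beta(s_a, s_b) truncated to exceed g_j;
    π_j ~ Beta(pi_a, pi_b); β_j, β₀ ~ N(beta_mean, beta_sd²);
    κ_j², κ₀² ~ Gamma(kappa_shape, rate=kappa_rate); latent-class
    probabilities ~ Dirichlet(dirichlet_conc·1); σ_τ ~ half-normal(sigma_tau_scale).

    ``constrain_beta0`` keeps β₀ ≤ min_j β_j during sampling, pinning the
    rapid-guess component to the short-time side of the mixture.
    """

    g_a: float = 1.0
    g_b: float = 1.0
    s_a: float = 1.0
    s_b: float = 1.0
    pi_a: float = 1.0
    pi_b: float = 1.0
    beta_mean: float = 3.0
    beta_sd: float = 10.0
    kappa_shape: float = 0.01
    kappa_rate: float = 0.01
    dirichlet_conc: float = 1.0
    sigma_tau_scale: float = 1.0
    constrain_beta0: bool = True

    def __post_init__(self) -> None:
        for name in ("g_a", "g_b", "s_a", "s_b", "pi_a", "pi_b",
                     "beta_sd", "kappa_shape", "kappa_rate",
                     "dirichlet_conc", "sigma_tau_scale"):
            if not getattr(self, name) > 0:
                raise ValueError(f"prior hyperparameter {name} must be positive")


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings; a seed is required (no wall-clock seeding)."""

    n_chains: int = 2
    n_iterations: int = 6000
    n_burnin: int = 3000
    thin: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not 0 <= self.n_burnin < self.n_iterations:
            raise ValueError("burn-in must be shorter than the chain")
        if self.thin < 1:
            raise ValueError("thin must be ≥ 1")


class RTCDModel:
    """Joint response/response-time cognitive diagnostic model.

    Parameters
    ----------
    dataset : Dataset
        Complete I×J responses and response times with a validated Q-matrix.
    model_form : {"DINA", "DINO"}
        Response rule for solution attempts.
    rg : bool
        Include the rapid-guessing mixture (latent ξ, π_j, β₀, κ₀).
    priors : PriorSpec, optional
    """

    MAX_K = 10  # exact enumeration over 2^K classes

    def __init__(self, dataset: Dataset, model_form: str = "DINA", rg: bool = True,
                 priors: Optional[PriorSpec] = None):
        if model_form not in ("DINA", "DINO"):
            raise ValueError("estimable response rules are DINA and DINO")
        K = dataset.qmatrix.n_attributes
        if K > self.MAX_K:
            raise ValueError(f"K={K} exceeds the exact-enumeration limit ({self.MAX_K})")
        self.dataset = dataset
        self.model_form = model_form
        self.rg = bool(rg)
        self.priors = priors or PriorSpec()
        self.profiles = enumerate_latent_classes(K)
        self.eta = mastery_matrix(dataset.qmatrix, self.profiles, model_form)

    @classmethod
    def from_dataframes(cls, Y: pd.DataFrame, RT: pd.DataFrame, qmatrix, **kwargs):
        """Build from pandas DataFrames (columns = item labels) and a raw Q table."""
        from .core import validate_qmatrix

        ds = Dataset(
            Y=Y.to_numpy(), RT=RT.to_numpy(),
            qmatrix=validate_qmatrix(np.asarray(qmatrix)),
            item_labels=list(Y.columns),
        )
        return cls(ds, **kwargs)

    @property
    def name(self) -> str:
        return f"RT-{self.model_form}" + ("-RG" if self.rg else "")

    def fit(self, chain: Optional[ChainConfig] = None, seed: Optional[int] = None,
            **chain_kwargs) -> "RTCDMResults":
        """Run the Metropolis-within-Gibbs sampler.

        ``chain`` or keyword overrides (``n_chains=...`` etc.) configure the
        run; ``seed`` overrides the config seed.  Returns an
        :class:`RTCDMResults`.
        """
        if chain is None:
            cfg = dict(n_chains=2, n_iterations=6000, n_burnin=3000, thin=1, seed=0)
            cfg.update(chain_kwargs)
            if seed is not None:
                cfg["seed"] = seed
            chain = ChainConfig(**cfg)
        elif seed is not None:
            chain = ChainConfig(n_chains=chain.n_chains, n_iterations=chain.n_iterations,
                                n_burnin=chain.n_burnin, thin=chain.thin, seed=seed)
        logY = self.dataset.Y
        if not np.isfinite(self.dataset.RT).all():
            raise ValueError("non-finite response times")
        data = _sampler.SamplerData(
            Y=logY, logRT=np.log(self.dataset.RT), eta=self.eta,
            profiles=self.profiles, q=self.dataset.qmatrix.q,
            rg=self.rg, priors=self.priors,
        )
        ss = np.random.SeedSequence(chain.seed)
        chains = []
        for child in ss.spawn(chain.n_chains):
            rng = np.random.default_rng(child)
            chains.append(_sampler.run_chain(data, chain, rng))
        return RTCDMResults(self, chain, chains, data)


def dic_from_deviance(deviance_draws: np.ndarray, deviance_at_mean: float) -> tuple[float, float]:
    """DIC and effective parameter count from a deviance sample.

    DIC = D̄ + p_D with p_D = D̄ − D(plug-in); lower is better.  Requires at
    least 100 post-burn-in draws for a stable mean.
    """
    dev = np.asarray(deviance_draws, dtype=float).ravel()
    if dev.size < 100:
        raise ValueError("need ≥ 100 post-burn-in deviance draws")
    dbar = dev.mean()
    p_d = dbar - deviance_at_mean
    return dbar + p_d, p_d


def _split_rhat(chains_draws: np.ndarray) -> float:
    """Split-R̂ for one scalar: shape (n_chains, n_draws)."""
    x = np.asarray(chains_draws, dtype=float)
    n = x.shape[1] // 2
    if n < 2:
        return np.nan
    halves = np.concatenate([x[:, :n], x[:, n: 2 * n]], axis=0)
    m = halves.shape[0]
    means = halves.mean(axis=1)
    vars_ = halves.var(axis=1, ddof=1)
    W = vars_.mean()
    B = n * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


class RTCDMResults:
    """Posterior sample and summaries from :meth:`RTCDModel.fit`.

    Attributes
    ----------
    draws : dict
        Per-parameter arrays of kept draws, shape (n_chains, n_kept, ...).
    deviance : ndarray, (n_chains, n_kept)
        Marginalized deviance (α and ξ integrated out) per kept draw.
    alpha_probs : ndarray, (I, K)
        Posterior attribute-mastery probabilities per person.
    xi_probs : ndarray, (I, J)
        Posterior solution-attempt probabilities per cell (RG models).
    tau_mean, tau_sd : ndarray, (I,)
        Posterior mean/SD of person speed.
    """

    def __init__(self, model: RTCDModel, chain: ChainConfig, chain_results: list, data):
        self.model = model
        self.chain_config = chain
        self._data = data
        nc = len(chain_results)
        self.draws = {
            name: np.stack([c["draws"][name] for c in chain_results])
            for name in chain_results[0]["draws"]
        }
        self.deviance = np.stack([c["deviance"] for c in chain_results])
        self.alpha_probs = np.mean([c["alpha_probs"] for c in chain_results], axis=0)
        self.xi_probs = (
            np.mean([c["xi_probs"] for c in chain_results], axis=0) if model.rg else None
        )
        self.tau_mean = np.mean([c["tau_mean"] for c in chain_results], axis=0)
        within = np.mean([c["tau_sd"] ** 2 for c in chain_results], axis=0)
        between = np.var([c["tau_mean"] for c in chain_results], axis=0)
        self.tau_sd = np.sqrt(within + between)
        self.diagnostics = {
            "sigma_tau_accept": float(
                np.mean([c["diagnostics"]["sigma_tau_accept"] for c in chain_results])
            ),
            "empty_item_updates": int(
                sum(c["diagnostics"]["empty_items"] for c in chain_results)
            ),
        }

    # -- point estimates ----------------------------------------------------

    def posterior_mean(self, name: str) -> np.ndarray:
        """Posterior mean of a stored parameter, pooled across chains."""
        d = self.draws[name]
        return d.reshape(-1, *d.shape[2:]).mean(axis=0)

    @property
    def params(self) -> dict:
        """Posterior means of all stored parameters."""
        return {name: self.posterior_mean(name) for name in self.draws}

    def rhat(self, name: str) -> np.ndarray:
        """Split-R̂ per scalar component of a stored parameter."""
        d = self.draws[name]
        if d.ndim == 2:
            return np.array(_split_rhat(d))
        return np.array([_split_rhat(d[:, :, j]) for j in range(d.shape[2])])

    # -- tables -------------------------------------------------------------

    def summary(self) -> pd.DataFrame:
        """Posterior summary table: mean, sd, central 95% interval, R̂."""
        rows = []
        labels = self.model.dataset.item_labels
        for name, d in self.draws.items():
            flat = d.reshape(-1, *d.shape[2:])
            if flat.ndim == 1:
                rows.append((name, flat.mean(), flat.std(ddof=1),
                             *np.quantile(flat, [0.025, 0.975]), float(self.rhat(name))))
            elif name == "class_w":
                continue  # 2^K entries summarized separately via class_probabilities()
            else:
                rh = self.rhat(name)
                for j in range(flat.shape[1]):
                    rows.append((f"{name}[{labels[j]}]", flat[:, j].mean(),
                                 flat[:, j].std(ddof=1),
                                 *np.quantile(flat[:, j], [0.025, 0.975]), rh[j]))
        return pd.DataFrame(rows, columns=["parameter", "mean", "sd", "2.5%", "97.5%", "rhat"])

    def class_probabilities(self) -> pd.DataFrame:
        """Posterior mean probability of each of the 2^K latent classes."""
        w = self.posterior_mean("class_w")
        pats = ["".join(map(str, p)) for p in self.model.profiles]
        return pd.DataFrame({"class": pats, "probability": w})

    # -- model fit ----------------------------------------------------------

    def dic(self) -> float:
        """Deviance information criterion (lower = better fit).

        Mean marginalized deviance plus p_D, with the plug-in deviance taken
        at posterior means of the continuous parameters and the discrete
        latents (α, ξ) marginalized — plug-in deviance at discrete modes is
        unstable for mixtures.
        """
        state = {k: self.posterior_mean(k) for k in
                 ("g", "s", "beta", "kappa", "sigma_tau", "class_w")}
        state["tau"] = self.tau_mean
        if self.model.rg:
            for k in ("pi", "beta0", "kappa0"):
                state[k] = self.posterior_mean(k)
        plug = _sampler.marginal_deviance(state, self._data)
        dic, self._p_d = dic_from_deviance(self.deviance, plug)
        return dic

    @property
    def p_d(self) -> float:
        """Effective number of parameters from the last :meth:`dic` call."""
        if not hasattr(self, "_p_d"):
            self.dic()
        return self._p_d

    # -- plots --------------------------------------------------------------

    def plot_rt_densities(self, ax=None):
        """Observed-scale RT densities: each item's solution-attempt law and
        the global rapid-guess law (RG models), at posterior means."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t = np.linspace(0.05, 120, 600)
        beta = self.posterior_mean("beta")
        kappa = self.posterior_mean("kappa")
        for j in range(beta.size):
            z = (np.log(t) - beta[j]) * kappa[j]
            ax.plot(t, kappa[j] / t * np.exp(-0.5 * z ** 2) / np.sqrt(2 * np.pi),
                    color="gray", alpha=0.4, lw=0.8)
        if self.model.rg:
            b0 = float(self.posterior_mean("beta0"))
            k0 = float(self.posterior_mean("kappa0"))
            z = (np.log(t) - b0) * k0
            ax.plot(t, k0 / t * np.exp(-0.5 * z ** 2) / np.sqrt(2 * np.pi),
                    color="crimson", lw=2, label="rapid guess")
            ax.legend()
        ax.set_xlabel("response time (s)")
        ax.set_ylabel("density")
        ax.set_title(f"{self.model.name}: response-time densities")
        return ax
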