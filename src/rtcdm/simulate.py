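"""Synthetic-data generator for the joint response/response-time models.

The generator reproduces two benchmark recovery designs for a 30-item test
measuring five correlated attributes (~1,000 test-takers):

* item quality: g ~ U(0.05, 0.3), s ~ U(0.05, 0.2), so the item
  discrimination index 1−s−g is supported on (0.5, 0.9) — a high-quality test;
* response times: β_j ~ U(2, 4), κ_j ~ U(0.15, 2) for solution attempts;
  rapid guesses use the fixed global law β₀ = 2, κ₀ = 1.6 (short,
  person-independent times);
* person speed τ ~ N(0, 0.3²);
* attributes: a 5-variate normal MVN(0.5·1, Σ) with unit variances and
  equicorrelation 0.5, dichotomized at 0.253 (the 40th-percentile z-value),
  giving ≈60% marginal mastery per attribute with positive phi-correlations;
* behavior: ξ_ij ~ Bernoulli(π_j) independently per cell; the benchmark π
  pattern alternates 0.9/0.8 in blocks of five items (rapid-guessing rates
  0.1/0.2), and the "0.2-level" variant shifts every π down by 0.1.

Study 1 uses the non-compensatory (DINA) response rule, study 2 the
compensatory (DINO) rule; everything else is shared.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .core import Dataset, QMatrix, enumerate_latent_classes, mastery_matrix, validate_qmatrix

__all__ = [
    "SimDesign",
    "simulate_attributes",
    "simulate_dataset",
    "table1_design",
    "study2_design",
    "TABLE1_Q",
    "TABLE1_PI",
]

# Benchmark 30×5 Q-matrix: items 1–10 each require one attribute, 11–20 two,
# 21–30 three (every singleton twice, then 10 of the pairs and 10 of the triples).
TABLE1_Q = np.array(
    [
        [1, 0, 0, 0, 0], [0, 1, 0, 0, 0], [0, 0, 1, 0, 0], [0, 0, 0, 1, 0], [0, 0, 0, 0, 1],
        [1, 0, 0, 0, 0], [0, 1, 0, 0, 0], [0, 0, 1, 0, 0], [0, 0, 0, 1, 0], [0, 0, 0, 0, 1],
        [1, 1, 0, 0, 0], [1, 0, 1, 0, 0], [1, 0, 0, 1, 0], [1, 0, 0, 0, 1], [0, 1, 1, 0, 0],
        [0, 1, 0, 1, 0], [0, 1, 0, 0, 1], [0, 0, 1, 1, 0], [0, 0, 1, 0, 1], [0, 0, 0, 1, 1],
        [1, 1, 1, 0, 0], [1, 1, 0, 1, 0], [1, 1, 0, 0, 1], [1, 0, 1, 1, 0], [1, 0, 1, 0, 1],
        [1, 0, 0, 1, 1], [0, 1, 1, 1, 0], [0, 1, 1, 0, 1], [0, 1, 0, 1, 1], [0, 0, 1, 1, 1],
    ],
    dtype=np.int8,
)

# Benchmark solution-attempt probabilities: blocks of five at 0.9 / 0.8.
TABLE1_PI = np.array([0.9] * 5 + [0.8] * 5 + [0.9] * 5 + [0.8] * 5 + [0.9] * 5 + [0.8] * 5)


@dataclass
class SimDesign:
    """Full specification of one synthetic-data condition.

    Every generating distribution is configurable; defaults follow the
    benchmark designs (see module docstring).  ``pi`` is the per-item
    solution-attempt probability vector; with ``rg_enabled=False`` it is
    ignored and ξ ≡ 1 (the base joint model is the generator).
    ``redraw_item_params`` controls whether item parameters are drawn
    afresh for each replication (default) or held fixed after the first.
    """

    qmatrix: QMatrix
    n_persons: int = 1000
    model_form: str = "DINA"
    rg_enabled: bool = True
    pi: Optional[np.ndarray] = None
    g_bounds: tuple = (0.05, 0.3)
    s_bounds: tuple = (0.05, 0.2)
    beta_bounds: tuple = (2.0, 4.0)
    kappa_bounds: tuple = (0.15, 2.0)
    tau_sd: float = 0.3
    beta0: float = 2.0
    kappa0: float = 1.6
    attr_mean: float = 0.5
    attr_rho: float = 0.5
    attr_cutoff: float = 0.253
    n_replications: int = 100
    redraw_item_params: bool = True
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.model_form not in ("DINA", "DINO"):
            raise ValueError("generator supports DINA and DINO response rules")
        for name, (lo, hi) in (("g", self.g_bounds), ("s", self.s_bounds)):
            if not (0.0 < lo < hi < 1.0):
                raise ValueError(f"{name} bounds must satisfy 0 < lo < hi < 1")
        if self.g_bounds[1] + self.s_bounds[1] >= 1.0:
            raise ValueError("g and s supports must guarantee g < 1−s")
        for name, (lo, hi) in (("β", self.beta_bounds), ("κ", self.kappa_bounds)):
            if not lo < hi:
                raise ValueError(f"{name} bounds must be increasing")
        if self.kappa_bounds[0] <= 0:
            raise ValueError("κ support must be positive")
        if not self.tau_sd > 0:
            raise ValueError("σ_τ must be positive")
        if not 0.0 <= self.attr_rho < 1.0:
            raise ValueError("attribute equicorrelation must lie in [0, 1)")
        if self.pi is None:
            self.pi = np.ones(self.qmatrix.n_items)
        else:
            self.pi = np.asarray(self.pi, dtype=float)
            if self.pi.shape != (self.qmatrix.n_items,):
                raise ValueError("π must have one entry per item")
            if ((self.pi <= 0) | (self.pi > 1)).any():
                raise ValueError("π entries must lie in (0, 1]")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qmatrix"] = self.qmatrix.q.tolist()
        d["pi"] = self.pi.tolist()
        return d


def simulate_attributes(
    n_persons: int,
    n_attributes: int,
    mu: float = 0.5,
    rho: float = 0.5,
    cutoff: float = 0.253,
    rng=None,
) -> np.ndarray:
    """Correlated binary attribute profiles via a thresholded Gaussian.

    Draws from MVN(mu·1, Σ) with unit diagonal and constant off-diagonal
    ``rho``, then sets α_ik = 1 iff the draw exceeds ``cutoff``.  With the
    defaults the marginal mastery rate is P(Z > 0.253 − 0.5) ≈ 0.60.
    """
    rng = np.random.default_rng(rng)
    if not -1.0 / max(n_attributes - 1, 1) < rho < 1.0:
        raise ValueError("equicorrelation outside the positive-definite range")
    # one-factor construction of the equicorrelated Gaussian
    common = rng.standard_normal((n_persons, 1))
    idio = rng.standard_normal((n_persons, n_attributes))
    z = mu + np.sqrt(rho) * common + np.sqrt(1.0 - rho) * idio if rho >= 0 else None
    if z is None:  # negative rho: fall back to a Cholesky draw
        cov = np.full((n_attributes, n_attributes), rho)
        np.fill_diagonal(cov, 1.0)
        z = mu + rng.multivariate_normal(np.zeros(n_attributes), cov, size=n_persons)
    return (z > cutoff).astype(np.int8)


def _draw_item_params(design: SimDesign, rng) -> dict:
    J = design.qmatrix.n_items
    g = rng.uniform(*design.g_bounds, size=J)
    s = rng.uniform(*design.s_bounds, size=J)
    beta = rng.uniform(*design.beta_bounds, size=J)
    kappa = rng.uniform(*design.kappa_bounds, size=J)
    return {"g": g, "s": s, "beta": beta, "kappa": kappa}


def simulate_dataset(design: SimDesign, seed=None, item_params=None) -> Dataset:
    """Generate one replication: item parameters, latents, Y and RT.

    Fully reproducible: the same ``seed`` yields a bit-identical dataset.
    The returned :class:`~rtcdm.core.Dataset` carries a ``truth`` block with
    every generating quantity (α, τ, ξ, item and RG-state parameters).
    ``item_params`` (a dict with g, s, beta, kappa) fixes the item
    parameters instead of redrawing them — used when replications share one
    item-parameter draw.
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    q = design.qmatrix
    I, J, K = design.n_persons, q.n_items, q.n_attributes

    item = _draw_item_params(design, rng)  # always consumed, keeps the stream aligned
    if item_params is not None:
        item = {k: np.asarray(item_params[k], dtype=float) for k in ("g", "s", "beta", "kappa")}
    alpha = simulate_attributes(I, K, design.attr_mean, design.attr_rho, design.attr_cutoff, rng)
    tau = rng.normal(0.0, design.tau_sd, size=I)

    if design.rg_enabled:
        xi = (rng.random((I, J)) < design.pi[None, :]).astype(np.int8)
    else:
        xi = np.ones((I, J), dtype=np.int8)

    # deterministic gate per person×item under the design's response rule
    profiles = enumerate_latent_classes(K)
    eta_classes = mastery_matrix(q, profiles, design.model_form)
    class_index = alpha @ (1 << np.arange(K))
    eta = eta_classes[class_index]  # (I, J) boolean

    p_solution = np.where(eta, 1.0 - item["s"][None, :], item["g"][None, :])
    p = np.where(xi == 1, p_solution, item["g"][None, :])
    Y = (rng.random((I, J)) < p).astype(np.int8)

    mean_log = np.where(
        xi == 1, item["beta"][None, :] - tau[:, None], design.beta0
    )
    sd_log = np.where(xi == 1, 1.0 / item["kappa"][None, :], 1.0 / design.kappa0)
    RT = np.exp(rng.normal(mean_log, sd_log))

    truth = {
        "alpha": alpha,
        "tau": tau,
        "xi": xi,
        "pi": design.pi.copy(),
        "beta0": design.beta0,
        "kappa0": design.kappa0,
        "model_form": design.model_form,
        "rg_enabled": design.rg_enabled,
        **item,
    }
    return Dataset(Y=Y, RT=RT, qmatrix=q, truth=truth)


def _benchmark_design(model_form: str, rg_level) -> SimDesign:
    q = validate_qmatrix(TABLE1_Q)
    if rg_level is None or rg_level == "none":
        return SimDesign(qmatrix=q, model_form=model_form, rg_enabled=False)
    if rg_level == 0.1:
        pi = TABLE1_PI.copy()
    elif rg_level == 0.2:
        pi = TABLE1_PI - 0.1
    else:
        raise ValueError("rg_level must be 0.1, 0.2 or None")
    return SimDesign(qmatrix=q, model_form=model_form, rg_enabled=True, pi=pi)


def table1_design(rg_level=0.1) -> SimDesign:
    """Study-1 benchmark design (DINA rule).

    ``rg_level=0.1`` uses the benchmark π pattern (0.9/0.8 blocks);
    ``rg_level=0.2`` shifts every π down by 0.1; ``None`` disables rapid
    guessing (π ≡ 1, the base joint model generates the data).
    """
    return _benchmark_design("DINA", rg_level)


def study2_design(rg_level=0.1) -> SimDesign:
    """Study-2 benchmark design: identical to study 1 but with the DINO rule."""
    return _benchmark_design("DINO", rg_level)
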