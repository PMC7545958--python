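"""Item response functions: G-DINA, DINA, DINO and their rapid-guessing forms.

The saturated G-DINA success probability for item j is, with identity link,
an intercept plus main effects and interactions over the item's required
attributes.  DINA keeps only the intercept (guessing g) and the highest-order
interaction (so full mastery gives 1−s); DINO constrains main effects and
interactions to a common magnitude with alternating signs, which collapses to
"at least one required attribute mastered → 1−s′, else g′".

The rapid-guessing (RG) extension multiplies every term except the intercept
by a binary behavior indicator ξ: during a solution attempt (ξ=1) the base
model applies unchanged; during a rapid guess (ξ=0) the success probability
is a profile-independent δ*_j, tied by default to the intercept (random
guessing among the options).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import reduced_profile

__all__ = [
    "ItemParams",
    "GuessingStateParams",
    "p_correct_gdina",
    "p_correct_dina",
    "p_correct_dino",
    "p_correct_rg",
]


def _check_prob(x: float, name: str) -> None:
    if not 0.0 < x < 1.0:
        raise ValueError(f"{name} must lie strictly in (0, 1); got {x}")


@dataclass(frozen=True)
class ItemParams:
    """Per-item parameters for one response model plus the RT law.

    For ``model_form`` "DINA"/"DINO": guessing ``g`` and slipping ``s``
    with the identifiability constraint g < 1−s (positive item
    discrimination index, IDI = 1−s−g).  For "GDINA": ``deltas`` is a
    vector of length 2^{K*} indexed by the bitmask of a subset of the
    item's required attributes (bit order = required attributes in
    ascending attribute index); the success probability of any reduced
    profile must stay in [0, 1], checked eagerly here.

    ``beta`` (time intensity, mean log-seconds for the population) and
    ``kappa`` (time discrimination, inverse SD of log RT) parameterize the
    lognormal response-time law for solution attempts; ``pi`` is the
    marginal probability of a solution attempt on this item.
    """

    model_form: str
    g: Optional[float] = None
    s: Optional[float] = None
    deltas: Optional[np.ndarray] = None
    beta: float = 3.0
    kappa: float = 1.0
    pi: float = 1.0

    def __post_init__(self) -> None:
        if self.model_form in ("DINA", "DINO"):
            if self.g is None or self.s is None:
                raise ValueError(f"{self.model_form} requires g and s")
            _check_prob(self.g, "g")
            _check_prob(self.s, "s")
            if not self.g < 1.0 - self.s:
                raise ValueError(
                    f"monotonicity violated: need g < 1−s, got g={self.g}, 1−s={1 - self.s}"
                )
        elif self.model_form == "GDINA":
            if self.deltas is None:
                raise ValueError("GDINA requires a δ-vector")
            d = np.asarray(self.deltas, dtype=float)
            n = d.size
            if n < 2 or n & (n - 1):
                raise ValueError("δ-vector length must be 2^{K*} with K* ≥ 1")
            # eager validity check: success probability of every reduced profile
            probs = _gdina_profile_probs(d)
            if (probs < 0).any() or (probs > 1).any():
                raise ValueError("δ configuration yields a success probability outside [0, 1]")
            object.__setattr__(self, "deltas", d)
        else:
            raise ValueError(f"unknown model_form {self.model_form!r}")
        if not self.kappa > 0:
            raise ValueError("time discrimination κ must be positive")
        if not 0.0 < self.pi <= 1.0:  # π = 1 means rapid guessing never occurs
            raise ValueError(f"π must lie in (0, 1]; got {self.pi}")

    @property
    def idi(self) -> float:
        """Item discrimination index 1 − s − g (DINA/DINO only)."""
        if self.model_form == "GDINA":
            raise ValueError("IDI is defined for DINA/DINO parameterizations")
        return 1.0 - self.s - self.g


@dataclass(frozen=True)
class GuessingStateParams:
    """Global rapid-guessing state: RT law N(β₀, 1/κ₀²) on the log scale.

    ``delta_star`` optionally frees the per-item RG success probability
    δ*_j; when None (default) δ*_j is tied to the item intercept
    (g_j / g′_j / δ_j0), i.e. random guessing among the options.
    """

    beta0: float
    kappa0: float
    delta_star: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if not self.kappa0 > 0:
            raise ValueError("κ₀ must be positive")
        if self.delta_star is not None:
            d = np.asarray(self.delta_star, dtype=float)
            if ((d <= 0) | (d >= 1)).any():
                raise ValueError("δ*_j must lie in (0, 1)")
            object.__setattr__(self, "delta_star", d)


def _gdina_profile_probs(deltas: np.ndarray) -> np.ndarray:
    """Success probability for every reduced profile (bitmask order)."""
    n = deltas.size
    masks = np.arange(n)
    # profile m accumulates δ_S over all subsets S ⊆ m
    return np.array([deltas[(masks & m) == masks].sum() for m in range(n)])


def _reduced_mask(profile: np.ndarray, qrow: np.ndarray) -> int:
    """Bitmask of mastered required attributes (ascending attribute index)."""
    red = reduced_profile(profile, qrow)
    return int(np.sum(red * (1 << np.arange(red.size))))


def p_correct_gdina(profile: np.ndarray, params: ItemParams, qrow: np.ndarray) -> float:
    """Saturated success probability: δ_0 + mastered main effects + interactions."""
    if params.model_form != "GDINA":
        raise ValueError("params.model_form must be GDINA")
    m = _reduced_mask(profile, qrow)
    d = params.deltas
    masks = np.arange(d.size)
    return float(d[(masks & m) == masks].sum())


def p_correct_dina(profile: np.ndarray, params: ItemParams, qrow: np.ndarray) -> float:
    """Non-compensatory rule: 1−s with *all* required attributes, g otherwise."""
    if params.model_form != "DINA":
        raise ValueError("params.model_form must be DINA")
    red = reduced_profile(profile, qrow)
    return 1.0 - params.s if red.all() else params.g


def p_correct_dino(profile: np.ndarray, params: ItemParams, qrow: np.ndarray) -> float:
    """Compensatory rule: 1−s′ with *at least one* required attribute, g′ otherwise."""
    if params.model_form != "DINO":
        raise ValueError("params.model_form must be DINO")
    red = reduced_profile(profile, qrow)
    return 1.0 - params.s if red.any() else params.g


def p_correct_rg(
    profile: np.ndarray,
    params: ItemParams,
    qrow: np.ndarray,
    guess_state: GuessingStateParams,
    xi: int,
    item_index: int = 0,
) -> float:
    """Success probability under the rapid-guessing mixture, given ξ.

    ξ=1 reproduces the base model exactly; ξ=0 returns δ*_j — by default the
    item intercept (g, g′ or δ_j0), or ``guess_state.delta_star[item_index]``
    when that hook is used.
    """
    if xi not in (0, 1):
        raise ValueError("ξ must be 0 or 1")
    if xi == 1:
        f = {"DINA": p_correct_dina, "DINO": p_correct_dino, "GDINA": p_correct_gdina}[
            params.model_form
        ]
        return f(profile, params, qrow)
    if guess_state.delta_star is not None:
        return float(guess_state.delta_star[item_index])
    if params.model_form == "GDINA":
        return float(params.deltas[0])
    return params.g
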