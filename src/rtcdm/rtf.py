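"""Lognormal response-time law for solution attempts and rapid guesses.

On a solution attempt (ξ=1), log RT_ij ~ N(β_j − τ_i, 1/κ_j²): the item's
time intensity β_j shifted down by the person's speed τ_i, with SD 1/κ_j.
On a rapid guess (ξ=0), log RT_ij ~ N(β₀, 1/κ₀²) — a global law that does
not involve the person's speed at all.

All likelihood code in this package uses ONE density convention: the
density of the *observed* RT in seconds (lognormal, including the 1/rt
change-of-variable term), not the density of log RT.  Mixture
responsibilities and deviance are therefore on a single, documented scale.
"""

from __future__ import annotations

import numpy as np

__all__ = ["logdensity_rt", "mean_log_rt"]

_LOG_2PI = np.log(2.0 * np.pi)


def logdensity_rt(rt, tau, beta, kappa, xi, beta0=None, kappa0=None):
    """Log-density of the observed RT (seconds) given the behavior state.

    Parameters are broadcastable arrays or scalars; ``xi`` selects the
    branch elementwise.  When every ``xi`` is 1 the rapid-guess parameters
    may be omitted.
    """
    rt = np.asarray(rt, dtype=float)
    if np.any(rt <= 0):
        raise ValueError("response times must be positive")
    xi = np.asarray(xi)
    log_rt = np.log(rt)

    def branch(mean, kap):
        kap = np.asarray(kap, dtype=float)
        if np.any(kap <= 0):
            raise ValueError("time discrimination must be positive")
        z = (log_rt - mean) * kap
        return np.log(kap) - 0.5 * _LOG_2PI - 0.5 * z * z - log_rt

    if np.all(xi == 1):
        out = branch(np.asarray(beta) - np.asarray(tau), kappa)
    else:
        if beta0 is None or kappa0 is None:
            raise ValueError("β₀ and κ₀ are required when any ξ = 0")
        out = np.where(
            xi == 1,
            branch(np.asarray(beta) - np.asarray(tau), kappa),
            branch(np.asarray(beta0), kappa0),
        )
    return out if out.ndim else float(out)


def mean_log_rt(tau, beta, xi, beta0=None):
    """Expected log RT: β − τ on a solution attempt, β₀ on a rapid guess."""
    xi = np.asarray(xi)
    if np.all(xi == 1):
        out = np.asarray(beta, dtype=float) - np.asarray(tau, dtype=float)
    else:
        if beta0 is None:
            raise ValueError("β₀ is required when any ξ = 0")
        out = np.where(
            xi == 1,
            np.asarray(beta, dtype=float) - np.asarray(tau, dtype=float),
            np.asarray(beta0, dtype=float),
        )
    return out if out.ndim else float(out)
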