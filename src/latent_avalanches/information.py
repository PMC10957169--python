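"""Mutual information between population activity and the latent variable.

For a single quasi-static latent h ~ N(0, 1) observed through T time
bins, the maximum-likelihood estimate h* of h from the mean rates s̄_i
is asymptotically Gaussian about the true value with inverse variance
given by the Fisher information

    1/σ² = Σ_i T (η J_i)² / [4 cosh²((η J_i h + ε)/2)],

which is strictly linear in T.  The mutual information between h and
the activity is then approximated by that of two Gaussians,

    I ≈ (1/2) ⟨ ln(1/σ²_h) ⟩_{h ~ N(0,1)},

so I grows by (1/2) ln(T₂/T₁) when the observation window is scaled —
an exact additivity in ln T under this approximation.  The
approximation fails at activity extremes (population nearly silent or
saturated); a configurable heuristic flags those points invalid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import optimize, special

from .simulate import CouplingMatrix
from .theory import _coupling_column

__all__ = [
    "mle_latent",
    "fisher_inv_variance",
    "information_mle",
    "information_surface",
]

DEFAULT_QUAD_ORDER = 101
RATE_SATURATION = 0.45  # mean firing prob above this (at |h|<=2) flags invalid
MIN_INV_VARIANCE = 1.0  # decoder variance wider than the N(0,1) prior flags invalid


def _score(h: float, sbar: np.ndarray, J: np.ndarray, eta: float, epsilon: float) -> float:
    """d/dh of the per-observation log-likelihood (Eq. of the MLE)."""
    x = eta * J * h + epsilon
    return float(np.sum(-eta * sbar * J + eta * J / (1.0 + np.exp(np.clip(x, -500, 500)))))


def mle_latent(
    mean_activity: np.ndarray,
    J,
    eta: float,
    epsilon: float,
    T: int = 1,
) -> float:
    """Maximum-likelihood estimate h* of the latent from mean rates.

    Solves the score equation Σ_i [-η s̄_i J_i + η J_i/(1+e^{ηJ_i h+ε})] = 0
    by bracketed root finding; the log-likelihood is concave in h so the
    root is unique when it exists.  Returns NaN (no-solution flag) when
    the activity is saturated and the score never changes sign.  T only
    scales the likelihood and does not move the optimum.
    """
    sbar = np.asarray(mean_activity, dtype=float)
    Jc = _coupling_column(J)
    if sbar.shape != Jc.shape:
        raise ValueError("mean_activity and J must have matching shapes")
    if np.any((sbar < 0) | (sbar > 1)):
        raise ValueError("mean activities must lie in [0, 1]")
    if np.all(sbar == 0.0) or np.all(sbar == 1.0):
        return float("nan")  # saturated recording carries no latent estimate
    f = lambda h: _score(h, sbar, Jc, eta, epsilon)
    lo, hi = -1.0, 1.0
    flo, fhi = f(lo), f(hi)
    for _ in range(12):  # expand bracket up to |h| = 4096
        if np.sign(flo) != np.sign(fhi):
            break
        lo, hi = 2 * lo, 2 * hi
        flo, fhi = f(lo), f(hi)
    else:
        return float("nan")
    if flo == 0.0:
        return lo
    if fhi == 0.0:
        return hi
    return float(optimize.brentq(f, lo, hi, xtol=1e-12))


def fisher_inv_variance(h: float, J, eta: float, epsilon: float, T: int) -> float:
    """Fisher information 1/σ² = Σ_i T(ηJ_i)²/(4 cosh²((ηJ_i h + ε)/2))."""
    Jc = _coupling_column(J)
    y = np.clip(0.5 * (eta * Jc * h + epsilon), -350, 350)
    return float(np.sum(T * (eta * Jc) ** 2 * 0.25 / np.cosh(y) ** 2))


def _log_inv_variance(hs: np.ndarray, J: np.ndarray, eta: float, epsilon: float, T: int) -> np.ndarray:
    """ln(1/σ²_h) for an array of latent values (vectorised Fisher sum)."""
    y = np.clip(0.5 * (eta * np.outer(hs, J) + epsilon), -350, 350)
    inv_var = (T * (eta * J) ** 2 * 0.25 / np.cosh(y) ** 2).sum(axis=1)
    with np.errstate(divide="ignore"):
        return np.log(inv_var)


def _is_valid(J: np.ndarray, eta: float, epsilon: float, T: int) -> bool:
    """Heuristic validity of the Gaussian-MLE approximation.

    Invalid when the population mean firing probability exceeds
    ``RATE_SATURATION`` anywhere in |h| ≤ 2 (activity saturating), or
    when the decoder at h = 0 is less precise than the N(0,1) prior
    (1/σ² < 1).  This is a package heuristic for the breakdown region,
    not a closed-form boundary.
    """
    hs = np.linspace(-2.0, 2.0, 41)
    x = eta * np.outer(J, hs) + epsilon
    mean_rate = np.max(np.mean(special.expit(-x), axis=0))
    if mean_rate > RATE_SATURATION:
        return False
    if fisher_inv_variance(0.0, J, eta, epsilon, T) < MIN_INV_VARIANCE:
        return False
    return True


def information_mle(
    J,
    eta: float,
    epsilon: float,
    T: int,
    quadrature_order: int = DEFAULT_QUAD_ORDER,
    mc_samples: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, bool]:
    """Gaussian-MLE mutual information (nats) between activity and h.

    Averages (1/2) ln(1/σ²_h) over h ~ N(0, 1) by Gauss–Hermite
    quadrature, or by Monte Carlo when ``mc_samples`` is given.
    Returns (information, valid); the value is still computed when the
    validity heuristic fails, so surfaces can be plotted with a mask.
    """
    if eta < 0:
        raise ValueError("eta must be nonnegative")
    Jc = _coupling_column(J)
    if mc_samples is not None:
        if rng is None:
            rng = np.random.default_rng()
        hs = rng.standard_normal(mc_samples)
        info = 0.5 * float(np.mean(_log_inv_variance(hs, Jc, eta, epsilon, T)))
    else:
        nodes, weights = special.roots_hermite(quadrature_order)
        hs = np.sqrt(2.0) * nodes
        vals = _log_inv_variance(hs, Jc, eta, epsilon, T)
        info = 0.5 * float(np.sum(weights * vals) / np.sqrt(np.pi))
    return info, _is_valid(Jc, eta, epsilon, T)


def information_surface(
    J,
    etas: np.ndarray,
    epsilons: np.ndarray,
    T: int,
    quadrature_order: int = DEFAULT_QUAD_ORDER,
) -> pd.DataFrame:
    """Gridded information surface: one row per (η, ε) with I and validity."""
    rows = []
    for eta in np.asarray(etas, dtype=float):
        for eps in np.asarray(epsilons, dtype=float):
            info, valid = information_mle(J, eta, eps, T, quadrature_order)
            rows.append({"eta": eta, "epsilon": eps, "info_nats": info, "valid": valid})
    return pd.DataFrame(rows)
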