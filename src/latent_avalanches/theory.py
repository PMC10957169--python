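"""Analytic avalanche probabilities and regime structure (quasi-static).

With a single quasi-static latent variable h, time bins are i.i.d.
conditioned on h, so an avalanche initiates exactly when a silent bin
is followed by an active one:

    P_ava(h) = P_silence(h) (1 - P_silence(h)),
    P_silence(h) = Π_i 1/(1 + exp(-η J_i h - ε)).

At h = 0 the silence probability collapses to (1/(1+e^{-ε}))^N,
independent of the couplings, and P_ava(0) is maximised at
ε₀ = -log(2^{1/N} - 1) ~ log N.  Integrating P_ava(h) against the
standard-normal latent density gives the expected per-step avalanche
rate and, times T, the expected avalanche count; the (η, ε) plane
splits into a high-activity no-avalanche region, two avalanche regimes
(Type 1: ε < ε₀, high fit cutoffs; Type 2: ε > ε₀, low cutoffs), and a
silent region.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special

from .simulate import CouplingMatrix

__all__ = [
    "p_silence",
    "p_avalanche",
    "p_avalanche_h0",
    "epsilon0",
    "avalanche_probability",
    "expected_avalanche_count",
    "epsilon_star",
    "classify_regime",
    "regime_map",
]

DEFAULT_QUAD_ORDER = 201
P_THRESHOLD = 0.001


def _coupling_column(J) -> np.ndarray:
    if isinstance(J, CouplingMatrix):
        if J.n_fields != 1:
            raise ValueError("analytic expressions hold for a single latent field only")
        return J.values[:, 0]
    J = np.asarray(J, dtype=float)
    if J.ndim != 1:
        raise ValueError("J must be a 1-D coupling column")
    return J


def _log_p_silence(h: np.ndarray, J: np.ndarray, eta: float, epsilon: float) -> np.ndarray:
    """log Π_i 1/(1+exp(-ηJ_i h - ε)) for an array of h values."""
    h = np.atleast_1d(np.asarray(h, dtype=float))
    x = eta * np.outer(J, h) + epsilon  # (N, H)
    return -np.logaddexp(0.0, -x).sum(axis=0)


def p_silence(h: float, J, eta: float, epsilon: float) -> float:
    """Probability that the whole population is silent at latent value h."""
    Jc = _coupling_column(J)
    return float(np.exp(_log_p_silence(h, Jc, eta, epsilon))[0])


def p_avalanche(h: float, J, eta: float, epsilon: float) -> float:
    """Per-step avalanche-initiation probability P_sil (1 - P_sil) at h."""
    ps = p_silence(h, J, eta, epsilon)
    return ps * (1.0 - ps)


def p_avalanche_h0(epsilon: float, N: int) -> float:
    """Closed form at h = 0: (1/(1+e^{-ε}))^N (1 - (1/(1+e^{-ε}))^N)."""
    if N < 1:
        raise ValueError("N must be >= 1")
    log_ps = -N * np.logaddexp(0.0, -epsilon)
    ps = np.exp(log_ps)
    return float(ps * -np.expm1(log_ps))


def epsilon0(N: int) -> float:
    """ε₀ = -log(2^{1/N} - 1), the ε maximising P_ava at h = 0."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return float(-np.log(np.expm1(np.log(2.0) / N)))


def _half_silence_crossings(J: np.ndarray, eta: float, epsilon: float, H: float = 60.0):
    """Latent values where P_silence crosses 1/2 (P_ava's peaks)."""
    s = lambda h: _log_p_silence(h, J, eta, epsilon)[0] - np.log(0.5)
    pts = []
    s0 = s(0.0)
    for sgn in (-1.0, 1.0):
        if s0 > 0 and s(sgn * H) < 0:
            pts.append(float(optimize.brentq(lambda h: s(h), 0.0 if sgn > 0 else -H,
                                             H if sgn > 0 else 0.0, xtol=1e-10)))
    return sorted(pts)


def avalanche_probability(
    J,
    eta: float,
    epsilon: float,
    quadrature_order: int | None = None,
) -> float:
    """∫ P_ava(h) N(h; 0, 1) dh for a single latent field.

    P_ava(h) can be a pair of peaks in h far narrower than the latent
    prior (width ~1/(η max|J_i|)), so fixed Gauss–Hermite rules
    under-resolve it at large η.  The default is adaptive quadrature on
    [-60, 60] with the P_silence = 1/2 crossings supplied as break
    points; passing ``quadrature_order`` selects the plain
    Gauss–Hermite rule instead (adequate for broad integrands).
    """
    Jc = _coupling_column(J)
    if eta == 0.0:
        return p_avalanche_h0(epsilon, Jc.size)  # integrand constant in h
    if quadrature_order is not None:
        nodes, weights = special.roots_hermite(quadrature_order)
        h = np.sqrt(2.0) * nodes
        ps = np.exp(_log_p_silence(h, Jc, eta, epsilon))
        return float(np.sum(weights * ps * (1.0 - ps)) / np.sqrt(np.pi))
    H = 60.0
    f = lambda h: p_avalanche(h, Jc, eta, epsilon) * np.exp(-0.5 * h * h) / np.sqrt(2 * np.pi)
    pts = _half_silence_crossings(Jc, eta, epsilon, H)
    val, _ = integrate.quad(f, -H, H, points=pts or [0.0], limit=400)
    return float(val)


def expected_avalanche_count(
    J,
    eta: float,
    epsilon: float,
    n_steps: int,
    quadrature_order: int | None = None,
) -> float:
    """Expected number of avalanche initiations in n_steps i.i.d.-bin steps.

    Exact for quasi-static latents in the long-segment limit; for OU
    latents it is only an approximation (bins are then correlated on
    the τ_F timescale).
    """
    return n_steps * avalanche_probability(J, eta, epsilon, quadrature_order)


def epsilon_star(J, eta: float, bounds: tuple[float, float] = (-5.0, 40.0)) -> float:
    """ε*(η): the ε maximising the h-integrated avalanche probability."""
    res = optimize.minimize_scalar(
        lambda e: -avalanche_probability(J, eta, e),
        bounds=bounds,
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def classify_regime(
    eta: float,
    epsilon: float,
    J,
    N: int | None = None,
    p_threshold: float = P_THRESHOLD,
) -> str:
    """Label a point of the (η, ε) plane.

    Below the ``p_threshold`` avalanche probability the point is
    avalanche-free: 'no-avalanche-silent' when the population is silent
    at h = 0 (P_silence(0) ≥ 1/2), otherwise
    'no-avalanche-high-activity'.  Otherwise 'type1' for ε < ε₀(N)
    (avalanches from rare large-|h| excursions, high fit cutoffs) or
    'type2' for ε ≥ ε₀(N) (low cutoffs).
    """
    Jc = _coupling_column(J)
    if N is None:
        N = Jc.size
    if avalanche_probability(Jc, eta, epsilon) < p_threshold:
        if p_silence(0.0, Jc, eta, epsilon) >= 0.5:
            return "no-avalanche-silent"
        return "no-avalanche-high-activity"
    return "type1" if epsilon < epsilon0(N) else "type2"


def regime_map(
    J,
    etas: np.ndarray,
    epsilons: np.ndarray,
    p_threshold: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Gridded phase map: one row per (η, ε) with P_ava, ε₀, and label."""
    Jc = _coupling_column(J)
    N = Jc.size
    eps0 = epsilon0(N)
    rows = []
    for eta in np.asarray(etas, dtype=float):
        for eps in np.asarray(epsilons, dtype=float):
            pava = avalanche_probability(Jc, eta, eps)
            rows.append(
                {
                    "eta": eta,
                    "epsilon": eps,
                    "p_ava": pava,
                    "epsilon0": eps0,
                    "label": classify_regime(eta, eps, Jc, N, p_threshold),
                }
            )
    return pd.DataFrame(rows)
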