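"""Latent-variable population model: couplings, latent dynamics, spikes.

The model is a population of N conditionally independent binary units
s_i(t) ∈ {0, 1} driven by N_F shared latent variables h_μ(t) through
random couplings J_iμ ~ N(0, 1):

    P(s_i = 1 | h(t)) = 1 / (1 + exp(η (J h(t))_i / √N_F + ε)).

η scales the latent drive, ε biases every unit towards silence.  The
1/√N_F normalization keeps the per-neuron input variance equal to η²
(given stationary unit-variance latents) however many fields carry it,
so η is comparable across single- and multi-variable populations; for
N_F = 1 the drive is exactly η J_i h.  Latent
variables are either stationary unit-variance Ornstein–Uhlenbeck
processes with correlation time τ_F (in time steps) or quasi-static:
piecewise constant over segments, redrawn i.i.d. N(0, 1) per segment.

Conditional on h(t) the units are independent across neurons and time,
so rasters are sampled exactly, chunk by chunk, with bounded memory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter
from scipy.special import expit

from .config import SimulationConfig

__all__ = [
    "CouplingMatrix",
    "LatentTrajectory",
    "SpikeRaster",
    "draw_couplings",
    "simulate_latents",
    "firing_probability",
    "sample_raster",
    "simulate_population_counts",
]

_CHUNK_ELEMS = 2**24  # max neurons x steps evaluated per chunk (~128 MiB f64)


@dataclass(frozen=True)
class CouplingMatrix:
    """Latent-to-neuron couplings J, shape (n_neurons, n_fields)."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("couplings must be a 2-D matrix (n_neurons, n_fields)")
        if not np.all(np.isfinite(v)):
            raise ValueError("couplings must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_neurons(self) -> int:
        return self.values.shape[0]

    @property
    def n_fields(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class LatentTrajectory:
    """Latent variables h, shape (n_fields, n_steps).

    ``mode`` is "ou" or "quasistatic"; in quasi-static mode
    ``segment_boundaries`` lists the step indices where a fresh h was
    drawn (excluding 0), so detection can treat segments independently.
    """

    values: np.ndarray
    mode: str
    segment_boundaries: tuple[int, ...] = field(default_factory=tuple)

    @property
    def n_fields(self) -> int:
        return self.values.shape[0]

    @property
    def n_steps(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class SpikeRaster:
    """Binary activity s, shape (n_neurons, n_steps), with provenance."""

    spikes: np.ndarray
    config: SimulationConfig | None = None
    couplings: CouplingMatrix | None = None
    latents: LatentTrajectory | None = None


def draw_couplings(config: SimulationConfig, rng: np.random.Generator) -> CouplingMatrix:
    """Draw J_iμ i.i.d. from the standard normal distribution."""
    return CouplingMatrix(rng.standard_normal((config.n_neurons, config.n_fields)))


def simulate_latents(config: SimulationConfig, rng: np.random.Generator) -> LatentTrajectory:
    """Generate the latent trajectory h_μ(t) for one run.

    OU mode uses the exact stationary one-step update

        h(t+1) = h(t) e^{-1/τ_F} + sqrt(1 - e^{-2/τ_F}) ξ(t),  ξ ~ N(0,1),

    initialised from the stationary N(0, 1) distribution, so marginals
    are exact at every τ_F.  Quasi-static mode emits piecewise-constant
    rows with a fresh N(0, 1) value per segment.
    """
    nf, T = config.n_fields, config.n_steps
    if config.quasistatic:
        seg = config.segment_length
        draws = rng.standard_normal((nf, config.n_segments))
        values = np.repeat(draws, seg, axis=1)
        boundaries = tuple(range(seg, T, seg))
        return LatentTrajectory(values, "quasistatic", boundaries)
    tau = float(config.tau_F)
    a = np.exp(-1.0 / tau)
    b = np.sqrt(-np.expm1(-2.0 / tau))  # sqrt(1 - a^2), accurate for large tau
    h0 = rng.standard_normal(nf)
    values = np.empty((nf, T))
    values[:, 0] = h0
    if T > 1:
        noise = b * rng.standard_normal((nf, T - 1))
        # AR(1) recursion h_t = a h_{t-1} + noise_t as an IIR filter.
        zi = (a * h0)[:, None]
        values[:, 1:], _ = lfilter([1.0], [1.0, -a], noise, axis=1, zi=zi)
    return LatentTrajectory(values, "ou")


def firing_probability(
    J: CouplingMatrix | np.ndarray,
    h: np.ndarray,
    eta: float,
    epsilon: float,
) -> np.ndarray:
    """Per-neuron firing probability P(s_i=1|h) = 1/(1 + exp(η(Jh)_i/√N_F + ε)).

    ``h`` may be a single latent-state vector (n_fields,) giving a
    (n_neurons,) result, or a trajectory slab (n_fields, t) giving
    (n_neurons, t).  Saturates smoothly to 0/1 for extreme arguments.
    """
    Jv = J.values if isinstance(J, CouplingMatrix) else np.asarray(J, dtype=float)
    x = Jv @ np.asarray(h, dtype=float)
    x *= -eta / np.sqrt(Jv.shape[1])
    x -= epsilon
    return expit(x)  # stable logistic: saturates to 0/1 without overflow


def _chunk_edges(n_steps: int, n_neurons: int) -> np.ndarray:
    chunk = max(1, _CHUNK_ELEMS // max(n_neurons, 1))
    return np.arange(0, n_steps + chunk, chunk).clip(max=n_steps)


def _prob_chunk(
    Jv: np.ndarray, latents: np.ndarray, lo: int, hi: int, eta: float, epsilon: float
) -> np.ndarray:
    """Firing probabilities for steps [lo, hi) in (time, neuron) layout.

    The transposed layout keeps the thin matrix product BLAS-friendly on
    long recordings; values equal firing_probability(...).T exactly.
    """
    x = latents[:, lo:hi].T.astype(np.float32) @ Jv.T.astype(np.float32)
    x *= np.float32(-eta / np.sqrt(Jv.shape[1]))
    x -= np.float32(epsilon)
    return expit(x, out=x)


def sample_raster(
    J: CouplingMatrix,
    latents: LatentTrajectory,
    eta: float,
    epsilon: float,
    rng: np.random.Generator,
) -> SpikeRaster:
    """Sample s_i(t) as independent Bernoulli draws given h(t).

    Evaluation is chunked along time so memory stays bounded even for
    T = 2x10^6, N = 1024 (the output raster itself is uint8).
    """
    if J.n_fields != latents.n_fields:
        raise ValueError(
            f"couplings have {J.n_fields} fields but latents have {latents.n_fields}"
        )
    N, T = J.n_neurons, latents.n_steps
    spikes = np.empty((N, T), dtype=np.uint8)
    edges = _chunk_edges(T, N)
    for lo, hi in zip(edges[:-1], edges[1:]):
        p = _prob_chunk(J.values, latents.values, lo, hi, eta, epsilon)
        spikes[:, lo:hi] = (rng.random(p.shape) < p).T
    return SpikeRaster(spikes, couplings=J, latents=latents)


def simulate_population_counts(
    J: CouplingMatrix,
    latents: LatentTrajectory,
    eta: float,
    epsilon: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample the raster chunk-wise and return only per-bin population counts.

    Statistically identical to summing :func:`sample_raster` over neurons
    (same Bernoulli draws in the same order) without materialising the
    N x T raster — the memory-light path for avalanche detection on long
    runs.
    """
    if J.n_fields != latents.n_fields:
        raise ValueError(
            f"couplings have {J.n_fields} fields but latents have {latents.n_fields}"
        )
    N, T = J.n_neurons, latents.n_steps
    counts = np.empty(T, dtype=np.int64)
    edges = _chunk_edges(T, N)
    for lo, hi in zip(edges[:-1], edges[1:]):
        p = _prob_chunk(J.values, latents.values, lo, hi, eta, epsilon)
        counts[lo:hi] = (rng.random(p.shape) < p).sum(axis=1)
    return counts
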