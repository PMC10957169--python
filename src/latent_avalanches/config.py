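"""Run configuration for the latent-variable population model.

A single :class:`SimulationConfig` captures every parameter needed to
regenerate a simulation bit-for-bit: model parameters (N, N_F, eta,
epsilon, tau_F), run length, quasi-static segmenting, and the seed.
Configs round-trip through YAML so every run can write a resolved copy
of its parameters alongside its outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import yaml

QUASISTATIC = "quasistatic"


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    Parameters
    ----------
    n_neurons : int
        Number of binary units N in the population.
    n_fields : int
        Number of latent variables N_F driving the population.
    eta : float
        Input scaling η ≥ 0 multiplying the latent drive J·h.
    epsilon : float
        Bias towards silence ε; larger ε suppresses firing.
    tau_F : float or "quasistatic"
        Latent-variable correlation time in time steps (OU mode), or the
        sentinel ``"quasistatic"`` for piecewise-constant latents redrawn
        every segment.
    n_steps : int
        Total number of time steps T.
    n_segments : int
        Number of independent quasi-static segments (must divide
        ``n_steps``); 1 in OU mode.
    seed : int
        Seed for couplings, latents, and spikes.
    bin_seconds : float, optional
        Declared duration of one time bin in seconds.  Metadata only: it
        converts durations/timescales to physical units but enters no
        computation.
    """

    n_neurons: int
    n_fields: int
    eta: float
    epsilon: float
    tau_F: Union[float, str]
    n_steps: int
    n_segments: int = 1
    seed: int = 0
    bin_seconds: float | None = None

    def __post_init__(self) -> None:
        if self.n_neurons < 1:
            raise ValueError(f"n_neurons must be >= 1, got {self.n_neurons}")
        if self.n_fields < 1:
            raise ValueError(f"n_fields must be >= 1, got {self.n_fields}")
        if self.eta < 0:
            raise ValueError(f"eta must be >= 0, got {self.eta}")
        if self.n_steps < 1:
            raise ValueError(f"n_steps must be >= 1, got {self.n_steps}")
        if self.n_segments < 1:
            raise ValueError(f"n_segments must be >= 1, got {self.n_segments}")
        if self.quasistatic:
            if self.n_steps % self.n_segments != 0:
                raise ValueError(
                    "n_steps must be an integer multiple of n_segments in "
                    f"quasi-static mode (got {self.n_steps} / {self.n_segments})"
                )
        else:
            if not (float(self.tau_F) > 0):
                raise ValueError(f"tau_F must be positive, got {self.tau_F}")
            if self.n_segments != 1:
                raise ValueError("n_segments > 1 is only meaningful in quasi-static mode")
        if self.bin_seconds is not None and not self.bin_seconds > 0:
            raise ValueError("bin_seconds must be positive when given")

    @property
    def quasistatic(self) -> bool:
        return isinstance(self.tau_F, str) and self.tau_F == QUASISTATIC

    @property
    def segment_length(self) -> int:
        return self.n_steps // self.n_segments

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["bin_seconds"] is None:
            del d["bin_seconds"]
        return d

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))
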