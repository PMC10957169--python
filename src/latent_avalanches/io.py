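"""Run containers: chunked HDF5 for rasters, plain text for fixtures."""

from __future__ import annotations

from pathlib import Path
from typing import Union

import h5py
import numpy as np
import yaml

from .config import SimulationConfig
from .simulate import CouplingMatrix, LatentTrajectory, SpikeRaster

__all__ = ["save_run", "load_run", "export_raster_text", "import_raster_text"]


def save_run(
    path: Union[str, Path],
    config: SimulationConfig,
    couplings: CouplingMatrix,
    latents: LatentTrajectory | None = None,
    counts: np.ndarray | None = None,
    raster: SpikeRaster | None = None,
) -> None:
    """Write one run to a chunked, compressed HDF5 container.

    Datasets: couplings, latents, segment_boundaries, counts, spikes
    (whichever are given); the resolved config is stored as a YAML
    string attribute so the file is self-describing.
    """
    with h5py.File(path, "w") as f:
        f.attrs["config_yaml"] = yaml.safe_dump(config.to_dict(), sort_keys=False)
        f.create_dataset("couplings", data=couplings.values)
        if latents is not None:
            f.create_dataset(
                "latents", data=latents.values, chunks=True, compression="gzip"
            )
            f.attrs["latent_mode"] = latents.mode
            f.create_dataset(
                "segment_boundaries", data=np.asarray(latents.segment_boundaries, dtype=np.int64)
            )
        if counts is not None:
            f.create_dataset("counts", data=counts, chunks=True, compression="gzip")
        if raster is not None:
            f.create_dataset(
                "spikes", data=raster.spikes, dtype="u1", chunks=True, compression="gzip"
            )


def load_run(path: Union[str, Path]) -> dict:
    """Read a run container back into in-memory objects."""
    out: dict = {}
    with h5py.File(path, "r") as f:
        config = SimulationConfig(**yaml.safe_load(f.attrs["config_yaml"]))
        out["config"] = config
        out["couplings"] = CouplingMatrix(f["couplings"][...])
        if "latents" in f:
            out["latents"] = LatentTrajectory(
                f["latents"][...],
                str(f.attrs.get("latent_mode", "ou")),
                tuple(int(b) for b in f["segment_boundaries"][...]),
            )
        if "counts" in f:
            out["counts"] = f["counts"][...]
        if "spikes" in f:
            out["raster"] = SpikeRaster(
                f["spikes"][...],
                config=config,
                couplings=out["couplings"],
                latents=out.get("latents"),
            )
    return out


def export_raster_text(raster: Union[SpikeRaster, np.ndarray], path: Union[str, Path]) -> None:
    """Plain-text raster export (one neuron per row of 0/1 digits).

    Intended for small fixture rasters only.
    """
    spikes = raster.spikes if isinstance(raster, SpikeRaster) else np.asarray(raster)
    with Path(path).open("w") as fh:
        for row in spikes:
            fh.write("".join("1" if s else "0" for s in row) + "\n")


def import_raster_text(path: Union[str, Path]) -> np.ndarray:
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    return np.array([[int(c) for c in ln] for ln in lines], dtype=np.uint8)
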