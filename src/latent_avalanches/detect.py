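"""Avalanche detection on population activity.

An avalanche is a maximal run of contiguous time bins in which the
population count exceeds a threshold (default 0, i.e. at least one
active unit), bounded by sub-threshold bins.  Its duration D is the run
length in bins and its size S the summed activity over the run.  Runs
touching the start/end of a recording — or a quasi-static segment
boundary, where the latent variable is redrawn — have unknown true
extent and are discarded (counted in ``truncated_discarded``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

from .simulate import SpikeRaster

__all__ = ["AvalancheCatalog", "population_counts", "detect_avalanches"]

_COLUMNS = ("start", "duration", "size")


@dataclass(frozen=True)
class AvalancheCatalog:
    """Ordered avalanche events from one recording.

    ``events`` has columns (start, duration, size), sorted by start;
    events are non-overlapping and separated by at least one
    sub-threshold bin within a segment.
    """

    events: pd.DataFrame
    n_steps_scanned: int = 0
    truncated_discarded: int = 0

    def __post_init__(self) -> None:
        ev = self.events
        if list(ev.columns) != list(_COLUMNS):
            ev = ev.loc[:, list(_COLUMNS)]
        object.__setattr__(self, "events", ev.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.events)

    @property
    def sizes(self) -> np.ndarray:
        return self.events["size"].to_numpy()

    @property
    def durations(self) -> np.ndarray:
        return self.events["duration"].to_numpy()

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the catalog as columnar text: a '#'-metadata header then
        one row per avalanche (start, duration, size), tab-separated."""
        path = Path(path)
        with path.open("w") as fh:
            fh.write(f"# n_steps_scanned: {self.n_steps_scanned}\n")
            fh.write(f"# truncated_discarded: {self.truncated_discarded}\n")
            self.events.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "AvalancheCatalog":
        path = Path(path)
        meta = {"n_steps_scanned": 0, "truncated_discarded": 0}
        with path.open() as fh:
            pos = fh.tell()
            line = fh.readline()
            while line.startswith("#"):
                key, _, val = line[1:].partition(":")
                key = key.strip()
                if key in meta:
                    meta[key] = int(val)
                pos = fh.tell()
                line = fh.readline()
            fh.seek(pos)
            events = pd.read_csv(fh, sep="\t")
        return cls(events, **meta)

    @classmethod
    def from_events(
        cls,
        events: Iterable[tuple[int, int, int]],
        n_steps_scanned: int = 0,
        truncated_discarded: int = 0,
    ) -> "AvalancheCatalog":
        df = pd.DataFrame(list(events), columns=list(_COLUMNS), dtype=np.int64)
        return cls(df, n_steps_scanned, truncated_discarded)


def population_counts(raster: Union[SpikeRaster, np.ndarray]) -> np.ndarray:
    """Per-bin total activity: column sums of the binary raster."""
    spikes = raster.spikes if isinstance(raster, SpikeRaster) else np.asarray(raster)
    return spikes.sum(axis=0).astype(np.int64)


def _runs(active: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Start (inclusive) and stop (exclusive) indices of True runs."""
    padded = np.concatenate(([False], active, [False]))
    d = np.diff(padded.astype(np.int8))
    return np.flatnonzero(d == 1), np.flatnonzero(d == -1)


def detect_avalanches(
    activity: np.ndarray,
    segment_boundaries: Sequence[int] | None = None,
    threshold: int = 0,
) -> AvalancheCatalog:
    """Extract avalanches from a population-count series.

    Bins with ``activity > threshold`` are active; each maximal active
    run becomes one avalanche with D = run length and S = summed
    activity.  Segments delimited by ``segment_boundaries`` are scanned
    independently; runs touching any segment edge (including the series
    start and end) are discarded and tallied in ``truncated_discarded``.
    """
    activity = np.asarray(activity)
    if activity.ndim != 1:
        raise ValueError("activity must be a 1-D series")
    if np.any(activity < 0):
        raise ValueError("activity counts must be nonnegative")
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    T = activity.shape[0]
    cuts = [0, T]
    if segment_boundaries is not None:
        for b in segment_boundaries:
            if not (0 < b < T):
                raise ValueError(f"segment boundary {b} outside (0, {T})")
            cuts.append(int(b))
    cuts = sorted(set(cuts))

    frames = []
    discarded = 0
    csum = np.concatenate(([0], np.cumsum(activity, dtype=np.int64)))
    for lo, hi in zip(cuts[:-1], cuts[1:]):
        seg = activity[lo:hi] > threshold
        starts, stops = _runs(seg)
        if starts.size == 0:
            continue
        # discard runs touching the segment edges: extent unknown
        keep = np.ones(starts.size, dtype=bool)
        if seg[0]:
            keep[0] = False
        if seg[-1]:
            keep[-1] = False
        discarded += int((~keep).sum())
        starts, stops = starts[keep] + lo, stops[keep] + lo
        if starts.size:
            frames.append(
                pd.DataFrame(
                    {
                        "start": starts,
                        "duration": stops - starts,
                        "size": csum[stops] - csum[starts],
                    }
                )
            )
    if frames:
        events = pd.concat(frames, ignore_index=True).sort_values("start", ignore_index=True)
    else:
        events = pd.DataFrame({c: pd.Series(dtype=np.int64) for c in _COLUMNS})
    return AvalancheCatalog(events, n_steps_scanned=T, truncated_discarded=discarded)
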