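"""Core in-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd


@dataclass
class SpikeData:
    """A spike raster: per-spike unit id and time, over a known duration.

    Used both for cortical neurons and for thalamic fibers. Times are in
    milliseconds and lie in ``[0, duration]``; ``units`` is the registry of
    unit ids that may appear (silent units are legal and must be listed so
    downstream matrices have stable shape).
    """

    unit_ids: np.ndarray
    times: np.ndarray
    units: np.ndarray
    duration: float

    def __post_init__(self) -> None:
        self.unit_ids = np.asarray(self.unit_ids, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=np.float64)
        self.units = np.asarray(self.units, dtype=np.int64)
        if self.unit_ids.shape != self.times.shape:
            raise ValueError("unit_ids and times must be aligned")
        if self.times.size and (self.times.min() < 0 or self.times.max() > self.duration):
            raise ValueError("spike times outside [0, duration]")
        order = np.lexsort((self.unit_ids, self.times))
        self.unit_ids = self.unit_ids[order]
        self.times = self.times[order]

    @property
    def n_units(self) -> int:
        return int(self.units.size)

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    def shifted(self, dt: float) -> "SpikeData":
        """Translate all spikes (and the duration window) by ``dt`` ms."""
        return SpikeData(self.unit_ids, self.times + dt, self.units, self.duration + dt)

    def to_tsv(self, path) -> None:
        pd.DataFrame({"unit_id": self.unit_ids, "time_ms": self.times}).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path, units, duration) -> "SpikeData":
        df = pd.read_csv(path, sep="\t")
        return cls(df["unit_id"].to_numpy(), df["time_ms"].to_numpy(), units, duration)

    def to_hdf5(self, path, group: str = "spikes") -> None:
        with h5py.File(path, "a") as f:
            if group in f:
                del f[group]
            g = f.create_group(group)
            g.create_dataset("unit_ids", data=self.unit_ids)
            g.create_dataset("times", data=self.times)
            g.create_dataset("units", data=self.units)
            g.attrs["duration"] = self.duration

    @classmethod
    def from_hdf5(cls, path, group: str = "spikes") -> "SpikeData":
        with h5py.File(path, "r") as f:
            g = f[group]
            return cls(
                g["unit_ids"][()], g["times"][()], g["units"][()], float(g.attrs["duration"])
            )


@dataclass
class BinnedSpikes:
    """Units x time-bins count matrix.

    Entries are real-valued so that trial-averaged rasters can flow through
    the same detection stages as raw integer counts.
    """

    matrix: np.ndarray  # (n_units, n_bins)
    bin_size: float  # ms
    t0: float  # ms
    units: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("matrix must be 2-D (units x bins)")
        if np.any(self.matrix < 0):
            raise ValueError("negative spike counts")
        if self.units is None:
            self.units = np.arange(self.matrix.shape[0], dtype=np.int64)
        else:
            self.units = np.asarray(self.units, dtype=np.int64)

    @property
    def n_units(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]

    def bin_centers(self) -> np.ndarray:
        return self.t0 + (np.arange(self.n_bins) + 0.5) * self.bin_size
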