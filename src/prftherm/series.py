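"""Multi-echo, multi-coil, two-mode complex image series container."""

from __future__ import annotations

from dataclasses import dataclass, field
import json
from pathlib import Path

import h5py
import numpy as np


@dataclass
class MultiEchoSeries:
    """Complex image time series of the thermometry acquisition.

    ``data`` is indexed ``[mode, coil, echo, repetition, x, y, z]``.
    Echo times must be strictly increasing.  ``voxel_size_mm`` refers to
    the acquisition grid; after k-space zero-padding the reconstructed
    grid is finer (see :mod:`prftherm.recon`).
    """

    data: np.ndarray
    te_ms: tuple[float, ...]
    tr_s: float                       # repetition (dynamic) interval, s
    voxel_size_mm: tuple[float, float, float]
    mode_increments_deg: tuple[float, ...] = (45.0, 0.0)
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 7:
            raise ValueError("data must be [mode, coil, echo, rep, x, y, z]")
        te = np.asarray(self.te_ms, dtype=float)
        if te.size != self.data.shape[2]:
            raise ValueError("TE list length must match the echo axis")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        self.te_ms = tuple(te)

    @property
    def n_modes(self) -> int:
        return self.data.shape[0]

    @property
    def n_coils(self) -> int:
        return self.data.shape[1]

    @property
    def n_echoes(self) -> int:
        return self.data.shape[2]

    @property
    def n_reps(self) -> int:
        return self.data.shape[3]

    @property
    def matrix(self) -> tuple[int, int, int]:
        return tuple(self.data.shape[4:])

    def rep_times_s(self) -> np.ndarray:
        return np.arange(self.n_reps) * self.tr_s

    def save(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("data", data=self.data, compression="gzip",
                             compression_opts=1)
            f.attrs["sidecar"] = json.dumps({
                "te_ms": list(self.te_ms),
                "tr_s": self.tr_s,
                "voxel_size_mm": list(self.voxel_size_mm),
                "mode_increments_deg": list(self.mode_increments_deg),
                "seed": self.seed,
                "meta": self.meta,
            })

    @classmethod
    def load(cls, path: str | Path) -> "MultiEchoSeries":
        with h5py.File(path, "r") as f:
            data = f["data"][...]
            sc = json.loads(f.attrs["sidecar"])
        return cls(data=data, te_ms=tuple(sc["te_ms"]), tr_s=sc["tr_s"],
                   voxel_size_mm=tuple(sc["voxel_size_mm"]),
                   mode_increments_deg=tuple(sc["mode_increments_deg"]),
                   seed=sc.get("seed"), meta=sc.get("meta", {}))
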