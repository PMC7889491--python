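"""Volume, table and configuration I/O.

Volumes (SAR maps, temperature maps, std maps) travel as NIfTI with a
millimetre-unit affine in the phantom frame; probe logs and drift and
sensitivity tables as CSV; run configuration as YAML with explicit unit
suffixes in the keys; run manifests as JSON.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_volume",
    "read_volume",
    "affine_from_voxel_size",
    "write_probe_csv",
    "read_probe_csv",
    "load_yaml",
    "dump_yaml",
    "Manifest",
]


def affine_from_voxel_size(voxel_size_mm, shape=None) -> np.ndarray:
    """mm-unit affine, origin at the volume centre when shape is given."""
    aff = np.diag([*voxel_size_mm, 1.0])
    if shape is not None:
        aff[:3, 3] = [-(n - 1) / 2 * d for n, d in zip(shape, voxel_size_mm)]
    return aff


def write_volume(path: str | Path, volume: np.ndarray,
                 affine: np.ndarray | None = None,
                 voxel_size_mm=None) -> None:
    if affine is None:
        if voxel_size_mm is None:
            raise ValueError("provide an affine or a voxel size")
        affine = affine_from_voxel_size(voxel_size_mm, volume.shape)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume not found: {p}")
    try:
        img = nib.load(str(p))
    except Exception as exc:
        raise IOError(f"could not read NIfTI volume {p}: {exc}") from exc
    return np.asarray(img.dataobj, dtype=np.float64), img.affine


def write_probe_csv(path: str | Path, times_s, temps_C, probe="probe0") -> None:
    pd.DataFrame({"time_s": times_s, "temp_C": temps_C,
                  "probe": probe}).to_csv(path, index=False)


def read_probe_csv(path: str | Path) -> pd.DataFrame:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"probe log not found: {p}")
    df = pd.read_csv(p)
    missing = {"time_s", "temp_C", "probe"} - set(df.columns)
    if missing:
        raise IOError(f"probe log {p} missing columns {sorted(missing)}")
    return df


def load_yaml(path: str | Path) -> dict:
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"config not found: {p}")
    with open(p) as f:
        return yaml.safe_load(f)


def dump_yaml(obj: dict, path: str | Path) -> None:
    with open(path, "w") as f:
        yaml.safe_dump(obj, f, sort_keys=False)


class Manifest:
    """Records every output file of a run with its generating parameters."""

    def __init__(self, out_dir: str | Path, seed: int | None = None,
                 params: dict | None = None):
        self.out_dir = Path(out_dir)
        self.entries: list[dict] = []
        self.seed = seed
        self.params = params or {}

    def add(self, path: str | Path, stage: str, **params) -> None:
        p = Path(path)
        digest = hashlib.sha256(p.read_bytes()).hexdigest() if p.exists() else None
        self.entries.append({"file": p.name, "stage": stage,
                             "sha256": digest, "params": params})

    def write(self, name: str = "manifest.json") -> Path:
        payload = {"seed": self.seed, "params": self.params,
                   "files": self.entries}
        path = self.out_dir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True))
        return path
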