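"""File formats: NIfTI volumes, CSV tables with provenance, YAML configs.

Volumes (maps, masks, labels, raw series) are NIfTI-1; masks are stored as
0/1 integers, cluster/viability labels as integers, maps and series as
float32. Tables are plain CSV with a header row preceded by a provenance
comment line carrying the run's config hash.
"""
from __future__ import annotations

import hashlib
import io as _io
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "FormatError", "write_volume", "read_volume",
    "write_table", "read_table", "config_hash", "load_yaml", "dump_yaml",
]


class FormatError(ValueError):
    """A file does not parse as the expected format."""


def write_volume(path: str | Path, data: np.ndarray,
                 voxel_size_mm: tuple[float, float, float]) -> Path:
    """Write a 3-D (or 4-D) volume as NIfTI-1.

    Boolean data are stored as uint8, integer data as int16 and floating
    point as float32; the affine encodes the voxel size.
    """
    path = Path(path)
    data = np.asarray(data)
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.int16)
    else:
        data = data.astype(np.float32)
    affine = np.diag(list(voxel_size_mm) + [1.0])
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(nib.Nifti1Image(data, affine), str(path))
    return path


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume; returns the array and the voxel size in mm."""
    path = Path(path)
    try:
        img = nib.load(str(path))
        data = np.asarray(img.dataobj)
        zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    except Exception as exc:  # corrupt header, wrong magic, truncated file
        raise FormatError(f"cannot read {path} as NIfTI: {exc}") from exc
    return data, zooms


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_table(df: pd.DataFrame, path: str | Path, cfg_hash: str = "") -> Path:
    """Write a CSV with a leading provenance comment and a header row."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# config_hash={cfg_hash}\n")
    df.to_csv(buf, index=False)
    path.write_text(buf.getvalue())
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` (provenance line skipped)."""
    try:
        return pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"cannot read {path} as CSV: {exc}") from exc


def load_yaml(path: str | Path) -> dict:
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except Exception as exc:
        raise FormatError(f"cannot read {path} as YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise FormatError(f"{path}: expected a mapping at the top level")
    return data


def dump_yaml(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)
    return path
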