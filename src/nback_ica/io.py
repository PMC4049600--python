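"""File formats: NIfTI volumes, tab-separated tables, masks and maps.

All tabular outputs are UTF-8, tab-separated, "."-decimal, Unix
newlines, and carry the config hash and master seed in ``#``-prefixed
header comment lines.  Events use 0-based seconds from run start with
half-open intervals [onset, onset + duration).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file exists but does not match the expected format/schema."""


def read_bold(path: str | Path, tr_override: float | None = None
              ) -> tuple[np.ndarray, np.ndarray, float]:
    """Load a 4D BOLD NIfTI; returns (data (x,y,z,t), affine, TR seconds)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"BOLD file not found: {path}")
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"{path} is not 4D (shape {img.shape})")
    if tr_override is not None:
        tr = float(tr_override)
    else:
        tr = float(img.header.get_zooms()[3])
        if tr <= 0:
            raise FormatError(f"{path}: TR unavailable in header and no "
                              "override given")
    return np.asarray(img.dataobj, dtype=float), img.affine, tr


def write_bold(path: str | Path, data: np.ndarray, tr: float,
               voxel_size: float = 3.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    img.header.set_zooms((voxel_size,) * 3 + (float(tr),))
    img.to_filename(str(path))


def read_mask(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    return np.asarray(img.dataobj) > 0


def write_mask(path: str | Path, mask: np.ndarray,
               voxel_size: float = 3.0) -> None:
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.Nifti1Image(mask.astype(np.uint8), affine).to_filename(str(path))


def write_component_maps(path: str | Path, maps: np.ndarray,
                         mask: np.ndarray, voxel_size: float = 3.0) -> None:
    """Component maps as one 4D NIfTI (component along the 4th axis)."""
    vol = np.zeros(mask.shape + (maps.shape[0],), dtype=np.float32)
    for j in range(maps.shape[0]):
        v = np.zeros(mask.shape, dtype=np.float32)
        v[mask] = maps[j]
        vol[..., j] = v
    affine = np.diag([voxel_size] * 3 + [1.0])
    nib.Nifti1Image(vol, affine).to_filename(str(path))


# ---------------------------------------------------------------------------
# tables

def _check_columns(df: pd.DataFrame, required: dict[str, type],
                   path: Path) -> None:
    for col, typ in required.items():
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
        try:
            df[col] = df[col].astype(typ)
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: column {col!r} is not "
                              f"{typ.__name__}-typed: {exc}") from exc


def write_table(path: str | Path, df: pd.DataFrame, *,
                config_hash: str = "", seed: int | None = None) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_events(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = read_table(path)
    _check_columns(df, {"onset": float, "duration": float, "trial_type": str},
                   path)
    if (df["onset"] < 0).any():
        raise FormatError(f"{path}: negative onset")
    return df


def read_motion(path: str | Path) -> np.ndarray:
    """6-column whitespace-separated motion parameters, one row per scan."""
    path = Path(path)
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise FormatError(f"{path}: expected 6 motion columns, got "
                          f"{arr.shape[1]}")
    return arr


def write_motion(path: str | Path, motion: np.ndarray) -> None:
    np.savetxt(path, np.asarray(motion), fmt="%.6f", delimiter="\t")


def read_behavior(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = read_table(path)
    _check_columns(df, {"subject": str, "condition": str, "rt_ms": float,
                        "correct": bool}, path)
    if (df["rt_ms"].dropna() < 0).any():
        raise FormatError(f"{path}: negative RT value")
    return df


def config_hash(obj) -> str:
    """Short stable hash of a JSON-serializable config representation."""
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]
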