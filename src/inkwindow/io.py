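"""Readers and writers for rheometer exports, construct images and designs.

Rheometer software exports delimited text tables with instrument-specific
column names; readers take an explicit column mapping and declared units.
Images are PNG/TIFF, grayscale or RGB (converted by channel weights), with
the µm-per-pixel calibration supplied alongside.  Results serialize to JSON
(numpy-aware) and design tables to CSV.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .image_analysis import CalibratedImage
from .rheology import FlowCurve, OscSweep

__all__ = [
    "ParseError",
    "read_flow_curve",
    "read_osc_sweep",
    "read_design",
    "read_image",
    "write_image",
    "dump_json",
    "config_hash",
]

# viscosity/modulus unit -> Pa(.s) scale
_UNIT_SCALE = {"Pa.s": 1.0, "Pa*s": 1.0, "Pa s": 1.0, "mPa.s": 1e-3,
               "Pa": 1.0, "kPa": 1e3, "1/s": 1.0, "s^-1": 1.0}


class ParseError(ValueError):
    """A delimited export could not be interpreted."""


def _read_table(path, sep=None) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, engine="python")
    except Exception as exc:
        raise ParseError(f"{path.name}: cannot parse delimited table: {exc}")
    if df.empty:
        raise ParseError(f"{path.name}: empty table")
    return df


def _column(df: pd.DataFrame, name: str, path) -> np.ndarray:
    if name not in df.columns:
        raise ParseError(f"{Path(path).name}: missing column {name!r} "
                         f"(have {list(df.columns)})")
    vals = pd.to_numeric(df[name], errors="coerce").to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ParseError(f"{Path(path).name}: non-numeric cell in {name!r}")
    return vals


def _scale(unit: str) -> float:
    if unit not in _UNIT_SCALE:
        raise ParseError(f"unknown unit {unit!r}; expected one of "
                         f"{sorted(_UNIT_SCALE)}")
    return _UNIT_SCALE[unit]


def read_flow_curve(
    path,
    shear_rate_col: str = "shear_rate",
    viscosity_col: str = "viscosity",
    viscosity_unit: str = "Pa.s",
    sep=None,
    temperature_C: float = 25.0,
) -> FlowCurve:
    """Read a rotational-sweep export (shear rate 1/s vs viscosity)."""
    df = _read_table(path, sep)
    sr = _column(df, shear_rate_col, path)
    visc = _column(df, viscosity_col, path) * _scale(viscosity_unit)
    order = np.argsort(sr)
    return FlowCurve(sr[order], visc[order], temperature_C)


def read_osc_sweep(
    path,
    stress_col: str = "stress",
    storage_col: str = "storage",
    loss_col: str = "loss",
    moduli_unit: str = "Pa",
    sep=None,
) -> OscSweep:
    """Read an oscillatory stress-sweep export (stress Pa vs G', G'')."""
    df = _read_table(path, sep)
    stress = _column(df, stress_col, path)
    scale = _scale(moduli_unit)
    gp = _column(df, storage_col, path) * scale
    gpp = _column(df, loss_col, path) * scale
    order = np.argsort(stress)
    return OscSweep(stress[order], gp[order], gpp[order])


def read_design(path, sep=None) -> pd.DataFrame:
    """Read a design table CSV (factors in declared units + responses)."""
    df = _read_table(path, sep)
    for col in df.columns:
        if col in ("label",):
            continue
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            raise ParseError(f"{Path(path).name}: non-numeric cell in {col!r}")
        df[col] = vals
    return df


_DEFAULT_RGB_WEIGHTS = (0.2125, 0.7154, 0.0721)  # ITU-R 709 luma


def read_image(path, um_per_px: float, rgb_weights=None) -> CalibratedImage:
    """Read a PNG/TIFF construct image with its µm/px calibration."""
    try:
        arr = iio.imread(Path(path))
    except Exception as exc:
        raise OSError(f"cannot read image {path}: {exc}")
    arr = np.asarray(arr, dtype=float)
    if arr.ndim == 3:
        w = np.asarray(rgb_weights if rgb_weights is not None
                       else _DEFAULT_RGB_WEIGHTS, dtype=float)
        arr = arr[..., :3] @ (w / w.sum())
    if arr.max() > 1.0:
        arr = arr / 255.0
    return CalibratedImage(arr, um_per_px)


def write_image(path, img: CalibratedImage) -> None:
    """Write an image as 8-bit PNG/TIFF (calibration goes in a sidecar)."""
    arr = np.clip(img.pixels, 0.0, 1.0)
    iio.imwrite(Path(path), (arr * 255.0 + 0.5).astype(np.uint8))


class _NumpyEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.bool_,)):
            return bool(obj)
        return super().default(obj)


def dump_json(obj, path=None, **kwargs) -> str:
    """Serialize (numpy-aware, stable key order) to string and optional file."""
    text = json.dumps(obj, cls=_NumpyEncoder, indent=2, sort_keys=True,
                      **kwargs)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping, for provenance blocks."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
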