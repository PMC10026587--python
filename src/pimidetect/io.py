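"""File interfaces: TIFF stacks with JSON sidecars, float maps, CSV records.

A polarization stack travels as a multi-page TIFF (one page per polarizer
angle, page order = angle order) next to a JSON sidecar holding the
acquisition metadata (angles, pixel pitch, illumination).  Parameter maps
are single-page 32-bit float TIFFs.  Tabular outputs (asymmetry records,
ground truth) are plain CSV; summaries and manifests are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .grid import UnitGrid
from .pimi import PimiParameterMaps, PolarizationFrameStack

__all__ = [
    "sidecar_path",
    "write_stack",
    "read_stack",
    "write_map",
    "read_map",
    "write_parameter_maps",
    "write_records_csv",
    "read_records_csv",
    "write_truth_csv",
    "read_truth_csv",
    "write_json",
    "read_json",
    "write_unit_montage",
]


def sidecar_path(stack_path: str | Path) -> Path:
    return Path(stack_path).with_suffix(".json")


def write_stack(path: str | Path, stack: PolarizationFrameStack) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames.astype(np.float32))
    meta = {
        "angles_deg": [float(a) for a in stack.angles_deg],
        "pixel_size_nm": float(stack.pixel_size_nm),
        "wavelength_nm": float(stack.wavelength_nm),
        "bandwidth_nm": float(stack.bandwidth_nm),
    }
    sidecar_path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")


def read_stack(path: str | Path) -> PolarizationFrameStack:
    path = Path(path)
    side = sidecar_path(path)
    if not side.exists():
        raise FileNotFoundError(f"missing JSON sidecar for stack: {side}")
    meta = json.loads(side.read_text())
    frames = tifffile.imread(path)
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return PolarizationFrameStack(
        frames=frames,
        angles_deg=np.asarray(meta["angles_deg"], dtype=float),
        pixel_size_nm=float(meta["pixel_size_nm"]),
        wavelength_nm=float(meta.get("wavelength_nm", 600.0)),
        bandwidth_nm=float(meta.get("bandwidth_nm", 35.0)),
    )


def write_map(path: str | Path, map_: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(map_, dtype=np.float32))


def read_map(path: str | Path) -> np.ndarray:
    return np.asarray(tifffile.imread(path), dtype=float)


def write_parameter_maps(directory: str | Path, maps: PimiParameterMaps) -> dict[str, Path]:
    """Write all parametric maps under ``directory``; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name, arr in (
        ("i0", maps.i0_map),
        ("sindelta", maps.sindelta_map),
        ("phi", maps.phi_map),
        ("residual", maps.residual_map),
        ("flags", maps.flag_map),
    ):
        p = directory / f"{name}.tif"
        dtype = np.uint8 if name == "flags" else np.float32
        tifffile.imwrite(p, np.asarray(arr, dtype=dtype))
        out[name] = p
    return out


def write_records_csv(path: str | Path, frame: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, float_format="%.10g", lineterminator="\n")


def read_records_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_truth_csv(path: str | Path, truth: pd.DataFrame) -> None:
    write_records_csv(path, truth)


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(path: str | Path, obj: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def write_unit_montage(path: str | Path, units: np.ndarray | UnitGrid) -> None:
    """Tile a (rows, cols, u, u) unit array into one inspection TIFF."""
    if isinstance(units, UnitGrid):
        units = units.units
    rows, cols, u, _ = units.shape
    montage = units.transpose(0, 2, 1, 3).reshape(rows * u, cols * u)
    write_map(path, montage)
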