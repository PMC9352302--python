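"""File formats: multi-frame TIFF stacks with plain-text sidecars, CSV tables.

Raw camera frames are stored as multi-frame 16-bit TIFF plus a ``.meta.txt``
sidecar of ``key = value`` lines; real-valued intermediate stacks (holograms,
S1 frames) as 32-bit float TIFF.  Tables are CSV with a header row, and
configuration files plain-text key-value with sections (INI style).
"""

from __future__ import annotations

import configparser
from dataclasses import asdict, fields
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import tifffile

from .errors import ConfigurationError
from .reconstruction import ReconstructionResult
from .simulator import FrameStack, GroundTruth, SimulationConfig

__all__ = [
    "write_frame_stack",
    "read_frame_stack",
    "write_float_stack",
    "read_float_stack",
    "write_scalars_csv",
    "read_scalars_csv",
    "write_ground_truth",
    "write_key_values",
    "read_key_values",
    "load_simulation_config",
    "save_simulation_config",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".meta.txt")


def write_frame_stack(stack: FrameStack, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.frames, photometric="minisblack")
    meta = dict(stack.metadata)
    meta["detuning_hz"] = stack.detuning_hz
    meta["n_frames"] = stack.n_frames
    write_key_values(meta, _sidecar(path))
    return path


def read_frame_stack(path: str | Path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta: dict[str, Any] = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = read_key_values(sc)
    det = float(meta.get("detuning_hz", 0.0))
    return FrameStack(frames=frames, detuning_hz=det, metadata=meta)


def write_float_stack(frames: np.ndarray, path: str | Path) -> Path:
    path = Path(path).with_suffix(".tif")
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(frames, dtype=np.float32), photometric="minisblack")
    return path


def read_float_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    return arr[None] if arr.ndim == 2 else arr


def write_scalars_csv(result: ReconstructionResult, detuning_hz: float, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "frame": np.arange(result.n_frames),
            "detuning_hz": detuning_hz,
            "s_plus": result.s_plus,
            "s_minus": result.s_minus,
            "n_bar": result.n_bar,
            "s1_bar": result.s1_bar,
        }
    )
    df.to_csv(path, index=False)
    return path


def read_scalars_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    d = asdict(truth)
    wf = d.pop("clutter_waveform", None)
    d["hop_frames"] = ",".join(str(h) for h in d.get("hop_frames", ()))
    d["has_clutter"] = wf is not None
    return write_key_values(d, path)


def write_key_values(data: dict, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"{k} = {v}" for k, v in data.items()]
    path.write_text("\n".join(lines) + "\n")
    return path


def read_key_values(path: str | Path) -> dict[str, str]:
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or "=" not in line:
            continue
        k, v = line.split("=", 1)
        out[k.strip()] = v.strip()
    return out


_TUPLE_FIELDS = {"carrier_offset", "detuning_list_hz"}
_BOOL_FIELDS = {"shot_noise", "quantise"}


def save_simulation_config(config: SimulationConfig, path: str | Path) -> Path:
    cp = configparser.ConfigParser()
    cp["simulation"] = {}
    for f in fields(config):
        v = getattr(config, f.name)
        if v is None:
            continue
        if f.name in _TUPLE_FIELDS:
            v = ",".join(str(x) for x in v)
        cp["simulation"][f.name] = str(v)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        cp.write(fh)
    return path


def load_simulation_config(path: str | Path) -> SimulationConfig:
    cp = configparser.ConfigParser()
    if not cp.read(Path(path)):
        raise ConfigurationError(f"cannot read configuration file {path}")
    if "simulation" not in cp:
        raise ConfigurationError("configuration file lacks a [simulation] section")
    sec = cp["simulation"]
    kwargs: dict[str, Any] = {}
    type_map = {f.name: f.type for f in fields(SimulationConfig)}
    for key, raw in sec.items():
        if key not in type_map:
            raise ConfigurationError(f"unknown simulation option {key!r}")
        if key in _TUPLE_FIELDS:
            parts = [p for p in raw.replace("(", "").replace(")", "").split(",") if p.strip()]
            vals = tuple(float(p) for p in parts)
            kwargs[key] = tuple(int(v) for v in vals) if key == "carrier_offset" else vals
        elif key in _BOOL_FIELDS:
            kwargs[key] = raw.strip().lower() in ("1", "true", "yes", "on")
        elif key in ("grid_size", "oversample_factor", "substeps_per_exposure", "bit_depth", "n_frames", "rng_seed"):
            kwargs[key] = int(raw)
        elif key in ("g1_model", "pixel_integration"):
            kwargs[key] = raw.strip()
        else:
            kwargs[key] = float(raw)
    return SimulationConfig(**kwargs)
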