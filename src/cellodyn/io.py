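"""Readers and writers for the plain formats the pipeline exchanges.

Competition and hydrolysis series travel as CSV; frame stacks as paired
multi-page TIFFs (height nm / modulus MPa, float32) or as per-frame
whitespace-separated text matrices (the Gwyddion ASCII export dialect);
experiment metadata as a YAML sidecar; ROIs and fit results as JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .afm import FrameStack, MapFrame, NanodomainROI
from .errors import InputError
from .kinetics import CompetitionSeries, HydrolysisSeries

__all__ = [
    "read_competition_csv",
    "write_competition_csv",
    "read_hydrolysis_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_stack_txt",
    "read_stack_txt",
    "load_config",
    "save_config",
    "load_roi",
    "save_roi",
    "write_trajectory_csv",
    "write_json",
]


def read_competition_csv(path) -> CompetitionSeries:
    """Read a competition series; accepts fraction or percent columns."""
    df = pd.read_csv(path)
    if "f12" in df.columns:
        f12 = df["f12"].to_numpy(float)
        f13 = df["f13"].to_numpy(float) if "f13" in df.columns else 1.0 - f12
    elif "pct12" in df.columns:
        f12 = df["pct12"].to_numpy(float) / 100.0
        f13 = (df["pct13"].to_numpy(float) / 100.0) if "pct13" in df.columns else 1.0 - f12
    else:
        raise InputError("competition CSV needs f12/f13 or pct12/pct13 columns")
    g = df["g_total"].to_numpy(float) if "g_total" in df.columns else None
    return CompetitionSeries(times=df["time_min"].to_numpy(float), f12=f12, f13=f13, g_total=g)


def write_competition_csv(series: CompetitionSeries, path) -> None:
    cols = {"time_min": series.times, "f12": series.f12, "f13": series.f13}
    if series.g_total is not None:
        cols["g_total"] = series.g_total
    pd.DataFrame(cols).to_csv(path, index=False)


def read_hydrolysis_csv(path, substrate_0: float = 1.0) -> HydrolysisSeries:
    df = pd.read_csv(path)
    return HydrolysisSeries(
        times=df["time_min"].to_numpy(float),
        glucose=df["glucose"].to_numpy(float),
        substrate_0=substrate_0,
        enzyme_free=df["enzyme_free"].to_numpy(float) if "enzyme_free" in df.columns else None,
    )


# --------------------------------------------------------------------------
# frame stacks
# --------------------------------------------------------------------------

def write_stack_tiff(stack: FrameStack, height_path, modulus_path) -> None:
    """Write height and modulus channels as float32 multi-page TIFFs."""
    tifffile.imwrite(height_path, np.stack([f.height for f in stack.frames]).astype(np.float32),
                     photometric="minisblack")
    tifffile.imwrite(modulus_path, np.stack([f.modulus for f in stack.frames]).astype(np.float32),
                     photometric="minisblack")


def read_stack_tiff(height_path, modulus_path, pixel_size_nm: float,
                    frame_times_min) -> FrameStack:
    h = tifffile.imread(height_path)
    m = tifffile.imread(modulus_path)
    if h.ndim == 2:
        h, m = h[None], m[None]
    if h.shape != m.shape:
        raise InputError("height and modulus stacks differ in shape")
    times = np.asarray(frame_times_min, dtype=float)
    if len(times) != len(h):
        raise InputError("frame_times_min length does not match page count")
    frames = [MapFrame(height=hi.astype(float), modulus=mi.astype(float),
                       pixel_size=pixel_size_nm, time=t)
              for hi, mi, t in zip(h, m, times)]
    return FrameStack(frames)


def write_stack_txt(stack: FrameStack, out_dir) -> None:
    """Per-frame whitespace matrices (Gwyddion ASCII dialect, row-major)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, fr in enumerate(stack.frames):
        np.savetxt(out / f"height_{i:03d}.txt", fr.height, fmt="%.6g")
        np.savetxt(out / f"modulus_{i:03d}.txt", fr.modulus, fmt="%.6g")


def read_stack_txt(in_dir, pixel_size_nm: float, frame_times_min) -> FrameStack:
    d = Path(in_dir)
    h_files = sorted(d.glob("height_*.txt"))
    m_files = sorted(d.glob("modulus_*.txt"))
    if not h_files or len(h_files) != len(m_files):
        raise InputError(f"no paired height/modulus matrices found in {d}")
    times = np.asarray(frame_times_min, dtype=float)
    if len(times) != len(h_files):
        raise InputError("frame_times_min length does not match frame count")
    frames = [MapFrame(height=np.loadtxt(hf), modulus=np.loadtxt(mf),
                       pixel_size=pixel_size_nm, time=t)
              for hf, mf, t in zip(h_files, m_files, times)]
    return FrameStack(frames)


# --------------------------------------------------------------------------
# sidecar config, ROI, results
# --------------------------------------------------------------------------

def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def save_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def save_roi(roi: NanodomainROI, path) -> None:
    payload = {"kind": roi.kind}
    if roi.rect is not None:
        payload["rect"] = list(roi.rect)
    if roi.vertices is not None:
        payload["vertices"] = np.asarray(roi.vertices).tolist()
    write_json(payload, path)


def load_roi(path) -> NanodomainROI:
    with open(path) as fh:
        payload = json.load(fh)
    return NanodomainROI(
        kind=payload["kind"],
        rect=tuple(payload["rect"]) if "rect" in payload else None,
        vertices=np.asarray(payload["vertices"], dtype=float) if "vertices" in payload else None,
    )


def write_trajectory_csv(records, path) -> None:
    pd.DataFrame(records).to_csv(path, index=False)


def write_json(obj, path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(f"not JSON-serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)
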