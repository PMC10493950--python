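"""File I/O for every pipeline artefact.

Formats: multi-page 16-bit TIFF, NPZ or PNG-directory image stacks; CSV
water-potential traces (``time_s, psi_MPa``); CSV mass series
(``time_s, mass_g``) with a JSON metadata sidecar; Newick trees; CSV
trait/climate tables; CSV vulnerability curves and JSON result blobs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .conductance import MassSeries
from .optical import ImageStack, PsiTrace, VulnerabilityCurve

__all__ = [
    "write_stack", "read_stack", "write_psi_trace", "read_psi_trace",
    "write_mass_series", "read_mass_series", "write_curve", "read_table",
    "write_json",
]

DEFAULT_FRAME_INTERVAL_S = 180.0


def write_stack(stack: ImageStack, path) -> None:
    """Write a stack as multi-page TIFF or NPZ (by extension).

    TIFF stores frame times in a ``<stem>_times.csv`` sidecar; NPZ keeps
    frames and times in one file.
    """
    path = Path(path)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, stack.frames.astype(np.uint16))
        pd.DataFrame({"time_s": stack.frame_times}).to_csv(
            path.with_name(path.stem + "_times.csv"), index=False)
    elif path.suffix.lower() == ".npz":
        np.savez_compressed(path, frames=stack.frames,
                            frame_times=stack.frame_times)
    else:
        raise ValueError(f"unsupported stack format: {path.suffix}")


def read_stack(path, frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S) -> ImageStack:
    """Read a TIFF/NPZ stack or a directory of grayscale PNGs.

    When no explicit times are stored (plain TIFF without sidecar, PNG
    directory in filename order), frames are assumed evenly spaced at
    ``frame_interval_s``.
    """
    path = Path(path)
    if path.is_dir():
        import imageio.v3 as iio
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if len(files) < 2:
            raise ValueError(f"stack directory {path} has fewer than 2 frames")
        frames = np.stack([iio.imread(f) for f in files])
        times = np.arange(len(files)) * frame_interval_s
        return ImageStack(frames=frames, frame_times=times)
    if path.suffix.lower() == ".npz":
        with np.load(path) as z:
            return ImageStack(frames=z["frames"], frame_times=z["frame_times"])
    if path.suffix.lower() in {".tif", ".tiff"}:
        frames = tifffile.imread(path)
        sidecar = path.with_name(path.stem + "_times.csv")
        if sidecar.exists():
            times = pd.read_csv(sidecar)["time_s"].to_numpy(dtype=float)
        else:
            times = np.arange(frames.shape[0]) * frame_interval_s
        return ImageStack(frames=frames, frame_times=times)
    raise ValueError(f"unsupported stack input: {path}")


def write_psi_trace(trace: PsiTrace, path) -> None:
    pd.DataFrame({"time_s": trace.times, "psi_MPa": trace.psi}).to_csv(
        path, index=False)


def read_psi_trace(path) -> PsiTrace:
    df = pd.read_csv(path)
    if not {"time_s", "psi_MPa"} <= set(df.columns):
        raise ValueError(f"{path}: psi trace needs columns time_s, psi_MPa")
    return PsiTrace(times=df["time_s"].to_numpy(dtype=float),
                    psi=df["psi_MPa"].to_numpy(dtype=float))


def write_mass_series(series: MassSeries, path) -> None:
    """CSV of (time_s, mass_g) plus a JSON sidecar with the metadata."""
    path = Path(path)
    pd.DataFrame({"time_s": series.times, "mass_g": series.masses}).to_csv(
        path, index=False)
    meta = {
        "temperature_C": series.temperature, "rh_percent": series.rh,
        "leaf_dry_mass_g": series.leaf_dry_mass,
        "sla_m2_per_kg": series.sla,
    }
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_mass_series(path) -> MassSeries:
    path = Path(path)
    df = pd.read_csv(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return MassSeries(
        times=df["time_s"].to_numpy(dtype=float),
        masses=df["mass_g"].to_numpy(dtype=float),
        temperature=float(meta["temperature_C"]), rh=float(meta["rh_percent"]),
        leaf_dry_mass=float(meta["leaf_dry_mass_g"]),
        sla=float(meta["sla_m2_per_kg"]))


def write_curve(curve: VulnerabilityCurve, frame_times, path) -> None:
    pd.DataFrame({
        "frame": curve.frame_index, "time_s": np.asarray(frame_times),
        "psi_MPa": curve.psi, "cum_px": curve.cum_px,
        "cum_percent": curve.cum_percent,
    }).to_csv(path, index=False)


def read_table(path, index_col: str = "species") -> pd.DataFrame:
    df = pd.read_csv(path)
    if index_col in df.columns:
        df = df.set_index(index_col)
    return df


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
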