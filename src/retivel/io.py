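"""File I/O: TIFF stacks, CSV maps, JSON reports, YAML config.

Input stacks are multi-page TIFFs or directories of single-frame TIFFs in
natural-numeric filename order. RGB frames are reduced to the green channel
at read time so every downstream stage sees single-channel stacks; 8- and
16-bit (and float) pixels are promoted to float64. CSV output uses '.'
decimals, no thousands separators and LF line endings, so reruns on
identical inputs produce identical bytes.
"""

from __future__ import annotations

import json
import re
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import tifffile
import yaml

from retivel.mapping import FrameStack, PulseMaps

__all__ = [
    "read_stack", "write_stack", "write_maps", "write_report",
    "load_config", "natural_sort_key",
]


class FormatError(ValueError):
    """Unreadable or inconsistent input data."""


_NUM_RE = re.compile(r"(\d+)")


def natural_sort_key(name: str):
    """Sort key placing f_10 after f_9 (numeric runs compared as integers)."""
    return tuple(int(p) if p.isdigit() else p for p in _NUM_RE.split(name))


def _to_green(frame: np.ndarray) -> np.ndarray:
    """Reduce an RGB(A) frame to its green channel; pass grayscale through."""
    if frame.ndim == 2:
        return frame.astype(float)
    if frame.ndim == 3 and frame.shape[-1] in (3, 4):
        return frame[..., 1].astype(float)
    raise FormatError(f"cannot interpret frame of shape {frame.shape}")


def read_stack(path: str | Path, fps: float = 120.0, origin: int = 0) -> FrameStack:
    """Read a frame stack from a multi-page TIFF or a directory of TIFFs."""
    path = Path(path)
    if path.is_dir():
        files = sorted(
            (p for p in path.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
            key=lambda p: natural_sort_key(p.name),
        )
        if not files:
            raise FormatError(f"no TIFF files in {path}")
        frames = [_to_green(tifffile.imread(f)) for f in files]
    else:
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        if data.ndim == 4:  # pages x H x W x channels
            frames = [_to_green(f) for f in data]
        else:
            frames = [f.astype(float) for f in data]
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise FormatError(f"frames have mixed dimensions: {sorted(shapes)}")
    return FrameStack(frames=np.stack(frames), fps=fps, origin=origin)


def write_stack(stack: FrameStack, outdir: str | Path, dtype: str = "uint16") -> list[Path]:
    """Write a stack as numbered single-frame TIFFs.

    Integer export clips to the dtype range and rounds; ``dtype="float32"``
    keeps fractional intensities. Returns the written paths in frame order.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    T = stack.shape[0]
    width = len(str(T))
    paths = []
    for k, frame in enumerate(stack.frames):
        if dtype == "float32":
            data = frame.astype(np.float32)
        elif dtype in ("uint8", "uint16"):
            info = np.iinfo(dtype)
            data = np.clip(np.rint(frame), info.min, info.max).astype(dtype)
        else:
            raise FormatError(f"unsupported export dtype {dtype!r}")
        p = outdir / f"frame_{k + 1:0{width}d}.tif"
        tifffile.imwrite(p, data)
        paths.append(p)
    return paths


def _write_csv_map(arr: np.ndarray, path: Path, fmt: str) -> None:
    with open(path, "w", newline="\n") as fh:
        np.savetxt(fh, arr, fmt=fmt, delimiter=",", newline="\n")


def write_maps(
    maps: PulseMaps,
    outdir: str | Path,
    sidecar: dict | None = None,
    heatmaps: bool = False,
) -> dict[str, Path]:
    """Write amplitude/trough/qc CSV maps (H rows x W columns) plus a JSON
    sidecar; optional PNG heatmaps are presentation-only."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    _write_csv_map(maps.amplitude, outdir / "amplitude.csv", "%.17g")
    _write_csv_map(maps.trough, outdir / "trough.csv", "%.17g")
    _write_csv_map(maps.qc, outdir / "qc.csv", "%d")
    out["amplitude"] = outdir / "amplitude.csv"
    out["trough"] = outdir / "trough.csv"
    out["qc"] = outdir / "qc.csv"
    if heatmaps:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        for name, arr, cmap in (("amplitude", maps.amplitude, "magma"),
                                ("trough", maps.trough, "twilight")):
            fig, ax = plt.subplots(figsize=(6, 4))
            im = ax.imshow(arr, cmap=cmap, origin="upper")
            fig.colorbar(im, ax=ax)
            ax.set_title(name)
            fig.savefig(outdir / f"{name}.png", dpi=120)
            plt.close(fig)
            out[f"{name}_png"] = outdir / f"{name}.png"
    write_report(sidecar or {}, outdir / "maps_meta.json")
    out["sidecar"] = outdir / "maps_meta.json"
    return out


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, (np.floating, np.integer, np.bool_)):
        return _jsonable(obj.item())
    if isinstance(obj, float) and not np.isfinite(obj):
        return None if np.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_report(report: dict, path: str | Path) -> Path:
    """Serialize a report dict to pretty JSON (NaN -> null, deterministic)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="\n") as fh:
        json.dump(_jsonable(report), fh, indent=2, sort_keys=True, allow_nan=False)
        fh.write("\n")
    return path


def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON) configuration file into a plain dict."""
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"config {path} must hold a mapping")
    return cfg
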