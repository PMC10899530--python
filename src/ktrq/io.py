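"""TIFF / CSV / JSON input-output helpers."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["write_stack", "read_stack", "write_channels", "read_channels",
           "write_label_stack", "write_json", "read_json"]


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (frames, H, W) stack as a multi-page TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack))


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    return arr


def write_channels(path: str | Path, channels: dict[str, np.ndarray]) -> None:
    """Write named channels as one multi-page TIFF (channel-major pages)."""
    names = list(channels)
    stack = np.stack([channels[n] for n in names])
    tifffile.imwrite(str(path), stack, photometric="minisblack",
                     metadata={"axes": "CYX", "channel_names": names})


def read_channels(path: str | Path,
                  names: list[str] | None = None) -> dict[str, np.ndarray]:
    """Read a channel-major multi-page TIFF into named channels."""
    arr = tifffile.imread(str(path))
    if arr.ndim == 2:
        arr = arr[None]
    if names is None:
        names = [f"ch{i}" for i in range(arr.shape[0])]
    if len(names) != arr.shape[0]:
        raise ValueError(
            f"{len(names)} names for {arr.shape[0]} channels")
    return {n: arr[i] for i, n in enumerate(names)}


def write_label_stack(path: str | Path, masks) -> None:
    """Write integer label masks (one page per frame) as 32-bit TIFF."""
    arr = np.asarray(masks, dtype=np.int32)
    tifffile.imwrite(str(path), arr)


def write_json(path: str | Path, payload: dict) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON-serializable: {type(o)}")
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_default) + "\n")


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
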