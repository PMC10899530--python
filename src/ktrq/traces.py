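"""Per-cell ERK-activity trace containers.

A :class:`TraceSet` holds one activity value per cell per frame on a shared
acquisition schedule, in a tidy long-format table, plus condition metadata
(ligand name, dose).  Activity is the ERKTR compartment intensity ratio
(cytoplasm/nucleus by default), possibly floor-normalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .schedule import AcquisitionSchedule

__all__ = ["TraceSet"]

_COLUMNS = ["cell_id", "frame", "time_min", "activity", "valid"]


@dataclass
class TraceSet:
    """Tidy per-cell activity time series on a shared frame grid.

    Attributes
    ----------
    data : pandas.DataFrame
        Columns ``cell_id, frame, time_min, activity, valid`` (one row per
        cell per frame).  ``valid`` marks frames where both compartments
        could be measured.
    schedule : AcquisitionSchedule
    condition : str
        Ligand / treatment label.
    dose_ng_ml : float
        Ligand dose in ng/mL (NaN when not applicable).
    """

    data: pd.DataFrame
    schedule: AcquisitionSchedule
    condition: str = ""
    dose_ng_ml: float = float("nan")

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"TraceSet data missing columns: {missing}")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_matrix(cls, activity: np.ndarray, schedule: AcquisitionSchedule,
                    valid: np.ndarray | None = None,
                    cell_ids: np.ndarray | None = None,
                    condition: str = "",
                    dose_ng_ml: float = float("nan")) -> "TraceSet":
        """Build from an (n_cells, n_frames) activity matrix."""
        activity = np.asarray(activity, dtype=float)
        n_cells, n_frames = activity.shape
        if n_frames != schedule.n_frames:
            raise ValueError(
                f"matrix has {n_frames} frames, schedule expects "
                f"{schedule.n_frames}")
        if valid is None:
            valid = np.isfinite(activity)
        if cell_ids is None:
            cell_ids = np.arange(1, n_cells + 1)
        frames = np.arange(n_frames)
        data = pd.DataFrame({
            "cell_id": np.repeat(cell_ids, n_frames),
            "frame": np.tile(frames, n_cells),
            "time_min": np.tile(schedule.times, n_cells),
            "activity": activity.ravel(),
            "valid": np.asarray(valid, dtype=bool).ravel(),
        })
        return cls(data, schedule, condition, dose_ng_ml)

    # -- access -----------------------------------------------------------

    @property
    def cell_ids(self) -> np.ndarray:
        return self.data["cell_id"].unique()

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def to_matrix(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return ``(cell_ids, activity, valid)`` matrices, frame-major."""
        wide = self.data.pivot_table(index="cell_id", columns="frame",
                                     values="activity", dropna=False)
        wide = wide.reindex(columns=range(self.schedule.n_frames))
        vwide = self.data.pivot_table(index="cell_id", columns="frame",
                                      values="valid", dropna=False)
        vwide = vwide.reindex(index=wide.index,
                              columns=range(self.schedule.n_frames))
        valid = vwide.to_numpy()
        valid = np.where(np.isnan(valid.astype(float)), False,
                         valid).astype(bool)
        return wide.index.to_numpy(), wide.to_numpy(dtype=float), valid

    def iter_cells(self) -> Iterator[tuple[int, pd.DataFrame]]:
        for cid, grp in self.data.groupby("cell_id", sort=True):
            yield cid, grp.sort_values("frame")

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["condition"] = self.condition
        out["dose_ng_ml"] = self.dose_ng_ml
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 schedule: AcquisitionSchedule | None = None) -> "TraceSet":
        data = pd.read_csv(path)
        condition = str(data["condition"].iloc[0]) if "condition" in data else ""
        dose = float(data["dose_ng_ml"].iloc[0]) if "dose_ng_ml" in data \
            else float("nan")
        if schedule is None:
            # infer the grid assuming the default baseline/MEKi layout
            tmax = float(data["time_min"].max())
            dt = np.diff(np.sort(data["time_min"].unique()))
            interval = float(dt.min()) if len(dt) else 6.0
            default = AcquisitionSchedule(frame_interval=interval)
            post = tmax + interval - default.baseline_duration \
                - default.meki_duration
            schedule = AcquisitionSchedule(
                frame_interval=interval, post_duration=max(post, interval))
        return cls(data[_COLUMNS].copy(), schedule, condition, dose)
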