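"""Acquisition schedule and analysis windows for KTR live-cell experiments.

The experimental template: cells are imaged at a fixed frame interval, first
for a baseline period, then a ligand (growth factor) is added and imaging
continues for a post-treatment period, and finally a MEK inhibitor is added
to drive ERK activity to its floor, which defines the per-cell normalization
reference.

All times are minutes from the start of the movie.  Event times are snapped
to the frame grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["AcquisitionSchedule", "AnalysisWindows"]


def _snap(t: float, interval: float) -> float:
    return round(t / interval) * interval


@dataclass(frozen=True)
class AcquisitionSchedule:
    """Frame timing of a KTR time-lapse experiment.

    Parameters
    ----------
    frame_interval : float
        Minutes between frames (default 6).
    baseline_duration : float
        Minutes of pre-treatment imaging (default 240 = 4 h).
    post_duration : float
        Minutes between ligand addition and MEK-inhibitor addition
        (default 900 = 15 h).
    meki_duration : float
        Minutes of imaging after MEK-inhibitor addition (default 90).
    meki_window : float
        Length in minutes of the *tail* of the MEKi recording used as the
        ERK-activity floor for normalization (default 30).
    """

    frame_interval: float = 6.0
    baseline_duration: float = 240.0
    post_duration: float = 900.0
    meki_duration: float = 90.0
    meki_window: float = 30.0

    def __post_init__(self) -> None:
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")
        if self.baseline_duration <= 0:
            raise ValueError("baseline_duration must be positive")
        if self.post_duration <= 0:
            raise ValueError("post_duration must be positive")
        if self.meki_duration < 0 or self.meki_window < 0:
            raise ValueError("MEKi durations must be non-negative")
        if self.meki_window > self.meki_duration:
            raise ValueError("meki_window cannot exceed meki_duration")
        # snap event boundaries to the frame grid
        for name in ("baseline_duration", "post_duration", "meki_duration",
                     "meki_window"):
            object.__setattr__(self, name,
                               _snap(getattr(self, name), self.frame_interval))
        if self.meki_time <= self.treatment_time:
            raise ValueError("MEKi must come after treatment")

    @property
    def treatment_time(self) -> float:
        """Minutes at which the ligand is added (end of baseline)."""
        return self.baseline_duration

    @property
    def meki_time(self) -> float:
        """Minutes at which the MEK inhibitor is added."""
        return self.baseline_duration + self.post_duration

    @property
    def total_duration(self) -> float:
        return self.meki_time + self.meki_duration

    @property
    def n_frames(self) -> int:
        return int(round(self.total_duration / self.frame_interval))

    @property
    def times(self) -> np.ndarray:
        """Frame acquisition times in minutes, ``times[0] == 0``."""
        return np.arange(self.n_frames) * self.frame_interval

    def frame_of(self, t: float) -> int:
        """Index of the frame acquired at (snapped) time ``t`` minutes."""
        return int(round(t / self.frame_interval))

    def meki_window_frames(self) -> np.ndarray:
        """Frame indices of the floor window (tail of the MEKi recording)."""
        t = self.times
        lo = self.total_duration - self.meki_window
        return np.nonzero(t >= lo)[0]


@dataclass(frozen=True)
class AnalysisWindows:
    """Windows (minutes) and significance level of the responder analysis.

    ``pre_window``/``post_window`` frame the paired pre- versus post-treatment
    test, ``amplitude_window`` bounds the maximum-response search, and
    ``auc_window`` is the integration span used as a surrogate for response
    duration.  ``alpha`` is the per-cell significance level.
    """

    pre_window: float = 60.0
    post_window: float = 60.0
    amplitude_window: float = 60.0
    auc_window: float = 720.0
    alpha: float = 0.005

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("pre_window", "post_window", "amplitude_window",
                     "auc_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def validate_against(self, schedule: AcquisitionSchedule) -> None:
        if self.pre_window > schedule.baseline_duration:
            raise ValueError("pre_window exceeds the baseline")
        if max(self.post_window, self.amplitude_window,
               self.auc_window) > schedule.post_duration:
            raise ValueError("post-treatment window exceeds the post period")
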