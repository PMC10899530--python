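"""Live-cell KTR image processing.

Segments nuclei from the H2B channel (background subtraction, Otsu
threshold, hole filling, distance-transform watershed to split touching
nuclei, minimum-area filter), derives per-nucleus cytoplasmic rings,
links cells across frames by greedy nearest-neighbor centroid matching,
and extracts per-cell ERK activity as the background-corrected ERKTR
cytoplasm/nucleus intensity ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.segmentation import relabel_sequential, watershed

from .schedule import AcquisitionSchedule
from .traces import TraceSet

__all__ = ["SegmentationOptions", "Track", "TrackSet", "segment_nuclei",
           "make_cyto_rings", "link_tracks", "extract_activity_traces"]


@dataclass
class SegmentationOptions:
    """Nuclear segmentation knobs, scaled to the default rendered nucleus."""

    min_area: int = 30              # px²; smaller objects discarded
    ring_width: int = 3             # px; cytoplasmic annulus width
    split_min_distance: int = 7     # px; min separation of watershed seeds
    smooth_sigma: float = 1.0       # px; pre-threshold Gaussian smoothing
    background_subtract: bool = True


def segment_nuclei(h2b_frame: np.ndarray,
                   opts: SegmentationOptions | None = None) -> np.ndarray:
    """Segment nuclei in one H2B frame into a label mask (0 = background).

    Constant frames (no signal) yield an empty mask rather than an error.
    """
    opts = opts or SegmentationOptions()
    img = np.asarray(h2b_frame, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a single-channel 2-D frame")
    if img.max() == img.min():
        return np.zeros(img.shape, dtype=np.int32)

    if opts.background_subtract:
        img = img - np.median(img)
    if opts.smooth_sigma > 0:
        img = ndi.gaussian_filter(img, opts.smooth_sigma)

    thr = threshold_otsu(img)
    binary = img > thr
    binary = ndi.binary_fill_holes(binary)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)

    # split touching nuclei with a distance-transform watershed
    distance = ndi.distance_transform_edt(binary)
    peaks = peak_local_max(distance, min_distance=opts.split_min_distance,
                           labels=binary, exclude_border=False)
    markers = np.zeros(img.shape, dtype=np.int32)
    markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
    if markers.max() == 0:
        labels, _ = ndi.label(binary)
    else:
        labels = watershed(-distance, markers, mask=binary)

    # minimum-area filter, then contiguous relabeling
    sizes = np.bincount(labels.ravel())
    small = np.nonzero(sizes < opts.min_area)[0]
    if len(small):
        labels[np.isin(labels, small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


def make_cyto_rings(nuclei: np.ndarray, ring_width: int = 3) -> np.ndarray:
    """Per-nucleus cytoplasmic annulus labels.

    Each ring is the dilation of its nucleus by ``ring_width`` minus all
    nuclear pixels; contested pixels go to the nearest nucleus (ties to the
    lower label).  Rings are clipped at the image border.
    """
    if ring_width < 1:
        raise ValueError("ring_width must be >= 1")
    nuclei = np.asarray(nuclei)
    if nuclei.max() == 0:
        return np.zeros_like(nuclei, dtype=np.int32)
    # nearest-nucleus assignment via the EDT of the background
    distance, (ir, ic) = ndi.distance_transform_edt(
        nuclei == 0, return_indices=True)
    nearest = nuclei[ir, ic]
    ring = (nuclei == 0) & (distance <= ring_width)
    out = np.zeros_like(nuclei, dtype=np.int32)
    out[ring] = nearest[ring]
    return out


@dataclass
class Track:
    """One cell's identity across frames."""

    cell_id: int
    frames: list[int] = field(default_factory=list)
    labels: list[int] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return self.frames[0]

    @property
    def end(self) -> int:
        return self.frames[-1]

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class TrackSet:
    """Cross-frame cell identities from greedy nearest-neighbor linking."""

    tracks: list[Track]
    n_frames: int

    def __len__(self) -> int:
        return len(self.tracks)

    def label_of(self, cell_id: int, frame: int) -> int | None:
        tr = self.tracks[cell_id - 1]
        try:
            return tr.labels[tr.frames.index(frame)]
        except ValueError:
            return None

    def to_frame(self) -> pd.DataFrame:
        rows = [(t.cell_id, f, lab, r, c)
                for t in self.tracks
                for f, lab, (r, c) in zip(t.frames, t.labels, t.centroids)]
        return pd.DataFrame(
            rows, columns=["cell_id", "frame", "label", "row", "col"])


def _centroids(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    props = regionprops(mask)
    labels = np.array([p.label for p in props], dtype=int)
    cents = np.array([p.centroid for p in props], dtype=float) \
        if props else np.zeros((0, 2))
    return labels, cents


def link_tracks(masks: Sequence[np.ndarray],
                max_disp: float = 15.0) -> TrackSet:
    """Link label masks across frames into tracks.

    Greedy nearest-neighbor matching, closest pairs first; links longer
    than ``max_disp`` pixels are refused; unmatched objects open new
    tracks.  No gap closing: a cell that disappears ends its track.
    """
    if len(masks) == 0:
        raise ValueError("empty mask sequence")

    tracks: list[Track] = []
    active: dict[int, Track] = {}        # track index of active tracks

    prev_labels, prev_cents = _centroids(masks[0])
    for lab, cent in zip(prev_labels, prev_cents):
        tr = Track(cell_id=len(tracks) + 1)
        tr.frames.append(0)
        tr.labels.append(int(lab))
        tr.centroids.append(tuple(cent))
        tracks.append(tr)
        active[len(tracks) - 1] = tr
    prev_track_idx = list(active.keys())

    for j in range(1, len(masks)):
        labels, cents = _centroids(masks[j])
        n_prev, n_cur = len(prev_cents), len(cents)
        new_active: dict[int, Track] = {}
        assigned_cur = np.zeros(n_cur, dtype=bool)
        if n_prev and n_cur:
            d = np.linalg.norm(
                prev_cents[:, None, :] - cents[None, :, :], axis=2)
            order = np.argsort(d, axis=None)
            used_prev = np.zeros(n_prev, dtype=bool)
            for flat in order:
                ip, ic = np.unravel_index(flat, d.shape)
                if d[ip, ic] > max_disp:
                    break
                if used_prev[ip] or assigned_cur[ic]:
                    continue
                used_prev[ip] = True
                assigned_cur[ic] = True
                ti = prev_track_idx[ip]
                tr = tracks[ti]
                tr.frames.append(j)
                tr.labels.append(int(labels[ic]))
                tr.centroids.append(tuple(cents[ic]))
                new_active[ti] = tr
        for ic in np.nonzero(~assigned_cur)[0]:
            tr = Track(cell_id=len(tracks) + 1)
            tr.frames.append(j)
            tr.labels.append(int(labels[ic]))
            tr.centroids.append(tuple(cents[ic]))
            tracks.append(tr)
            new_active[len(tracks) - 1] = tr
        # only objects present in this frame can be linked from next frame
        prev_track_idx = list(new_active.keys())
        prev_cents = np.array([tracks[i].centroids[-1]
                               for i in prev_track_idx]) \
            if new_active else np.zeros((0, 2))
        active = new_active

    return TrackSet(tracks=tracks, n_frames=len(masks))


def extract_activity_traces(
        erktr_stack: np.ndarray,
        tracks: TrackSet,
        nuclei_masks: Sequence[np.ndarray],
        ring_masks: Sequence[np.ndarray],
        schedule: AcquisitionSchedule,
        orientation: str = "cyt_over_nuc",
        min_pixels: int = 5,
        condition: str = "",
        dose_ng_ml: float = float("nan"),
) -> TraceSet:
    """Per-cell ERK activity from the ERKTR channel along the tracks.

    Activity is ``(cytoplasmic mean - background) / (nuclear mean -
    background)`` per frame (``cyt_over_nuc``), or its reciprocal under
    ``nuc_over_cyt``.  Background is the per-frame median of pixels
    belonging to neither compartment.  Frames where either compartment has
    fewer than ``min_pixels`` pixels, or a non-positive denominator after
    background subtraction, are flagged invalid (activity NaN, not
    propagated).
    """
    if orientation not in ("cyt_over_nuc", "nuc_over_cyt"):
        raise ValueError(f"unknown orientation {orientation!r}")
    stack = np.asarray(erktr_stack, dtype=float)
    n_frames = stack.shape[0]
    n_cells = len(tracks.tracks)

    activity = np.full((n_cells, n_frames), np.nan)
    valid = np.zeros((n_cells, n_frames), dtype=bool)

    for j in range(n_frames):
        frame = stack[j]
        nuc = np.asarray(nuclei_masks[j])
        ring = np.asarray(ring_masks[j])
        bg_pixels = frame[(nuc == 0) & (ring == 0)]
        background = float(np.median(bg_pixels)) if bg_pixels.size else 0.0
        for tr in tracks.tracks:
            if j < tr.start or j > tr.end:
                continue
            try:
                k = tr.frames.index(j)
            except ValueError:
                continue
            lab = tr.labels[k]
            i = tr.cell_id - 1
            nuc_px = frame[nuc == lab]
            ring_px = frame[ring == lab]
            if len(nuc_px) < min_pixels or len(ring_px) < min_pixels:
                continue
            nuc_mean = float(nuc_px.mean()) - background
            cyt_mean = float(ring_px.mean()) - background
            num, den = (cyt_mean, nuc_mean) if orientation == "cyt_over_nuc" \
                else (nuc_mean, cyt_mean)
            if den <= 0:
                continue
            activity[i, j] = num / den
            valid[i, j] = True

    if n_frames != schedule.n_frames:
        raise ValueError(
            f"stack has {n_frames} frames but schedule expects "
            f"{schedule.n_frames}")
    return TraceSet.from_matrix(activity, schedule, valid=valid,
                                condition=condition, dose_ng_ml=dose_ng_ml)
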