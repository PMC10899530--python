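"""Synthetic two-channel (H2B + ERKTR) time-lapse movies with ground truth.

Cells are rendered as concentric disks: a bright nucleus in the H2B channel,
and in the ERKTR channel a nucleus of fixed intensity surrounded by a
cytoplasm whose intensity is ``activity * nuclear_intensity``, so the
rendered cytoplasm/nucleus ratio equals the ground-truth ERK activity at
every frame before noise.  Nuclei perform reflected random walks confined
near their seeding positions so that tracks stay resolvable.

No point-spread function, illumination gradient or 3D structure is
modelled; the renderer exists to give the segmentation / tracking /
extraction pipeline an input with exactly known truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.draw import disk

from ..schedule import AcquisitionSchedule
from .traces import SimParams, TraceGroundTruth, simulate_trace_ensemble

__all__ = ["RenderOpts", "TimelapseGroundTruth", "simulate_timelapse"]


@dataclass
class RenderOpts:
    """Geometry and photometry of the rendered movie (pixels / counts)."""

    image_shape: tuple[int, int] = (320, 320)
    nucleus_radius: float = 8.0
    cell_radius: float = 14.0
    min_spacing: float = 48.0        # between cell centers at seeding
    confine_radius: float = 8.0      # random-walk tether around seed position
    drift_step: float = 2.0          # px per frame (per-axis uniform step)
    background: float = 100.0
    h2b_intensity: float = 3000.0
    erktr_nuclear_intensity: float = 1000.0
    photon_noise: float = 30.0       # Gaussian sd in counts; 0 = noiseless
    bit_depth: int = 16

    def __post_init__(self) -> None:
        if self.nucleus_radius >= self.cell_radius:
            raise ValueError("nucleus_radius must be < cell_radius")
        if self.min_spacing < 2 * self.cell_radius:
            raise ValueError("min_spacing must exceed the cell diameter")


@dataclass
class TimelapseGroundTruth:
    """Truth paired with a rendered movie."""

    positions: np.ndarray            # (n_cells, n_frames, 2) row/col centers
    activity: np.ndarray             # (n_cells, n_frames) noiseless activity
    responder: np.ndarray            # (n_cells,)
    nuclear_masks: np.ndarray        # (n_frames, H, W) int labels, 0 = bg
    cell_ids: np.ndarray             # (n_cells,) labels used in the masks


def _place_cells(n: int, shape: tuple[int, int], min_spacing: float,
                 margin: float, rng: np.random.Generator,
                 max_tries: int = 20_000) -> np.ndarray:
    """Rejection-sample cell centers with pairwise min spacing."""
    pts: list[np.ndarray] = []
    lo = np.array([margin, margin])
    hi = np.array([shape[0] - margin, shape[1] - margin])
    if np.any(hi <= lo):
        raise ValueError("image too small for the requested margin")
    for _ in range(max_tries):
        cand = rng.uniform(lo, hi)
        if all(np.hypot(*(cand - p)) >= min_spacing for p in pts):
            pts.append(cand)
            if len(pts) == n:
                return np.array(pts)
    raise ValueError(
        f"could only place {len(pts)} of {n} cells at spacing {min_spacing}")


def _walk(seed_pos: np.ndarray, n_frames: int, opts: RenderOpts,
          rng: np.random.Generator) -> np.ndarray:
    """Reflected random walk tethered within confine_radius of the seed."""
    n = len(seed_pos)
    pos = np.empty((n, n_frames, 2))
    pos[:, 0] = seed_pos
    for j in range(1, n_frames):
        step = rng.uniform(-opts.drift_step, opts.drift_step, size=(n, 2))
        new = pos[:, j - 1] + step
        # reflect off the tether boundary
        off = new - seed_pos
        r = np.hypot(off[:, 0], off[:, 1])
        out = r > opts.confine_radius
        if out.any():
            scale = (2 * opts.confine_radius - r[out]) / r[out]
            new[out] = seed_pos[out] + off[out] * np.clip(scale, 0, 1)[:, None]
        pos[:, j] = new
    return pos


def simulate_timelapse(
        params: SimParams,
        schedule: AcquisitionSchedule | None = None,
        render_opts: RenderOpts | None = None,
) -> tuple[np.ndarray, np.ndarray, TimelapseGroundTruth]:
    """Render a two-channel movie for a simulated trace ensemble.

    Returns
    -------
    h2b, erktr : ndarray, shape (n_frames, H, W), uint16
        Nuclear-marker and reporter channels.
    truth : TimelapseGroundTruth
    """
    if schedule is None:
        schedule = AcquisitionSchedule()
    opts = render_opts or RenderOpts()
    rng = np.random.default_rng(params.seed + 1)

    trace_set, trace_truth = simulate_trace_ensemble(
        # rendering noise is photometric; trace noise is added separately
        SimParams(**{**params.__dict__, "noise_sigma": 0.0}), schedule)
    activity = trace_truth.noiseless
    n_cells, n_frames = activity.shape
    shape = opts.image_shape

    if n_cells > 0:
        seeds = _place_cells(n_cells, shape, opts.min_spacing,
                             margin=opts.cell_radius + opts.confine_radius + 2,
                             rng=rng)
        positions = _walk(seeds, n_frames, opts, rng)
    else:
        positions = np.zeros((0, n_frames, 2))

    h2b = np.full((n_frames, *shape), opts.background, dtype=float)
    erktr = np.full((n_frames, *shape), opts.background, dtype=float)
    masks = np.zeros((n_frames, *shape), dtype=np.int32)
    cell_ids = np.arange(1, n_cells + 1)

    for j in range(n_frames):
        for i in range(n_cells):
            c = positions[i, j]
            rr_c, cc_c = disk(c, opts.cell_radius, shape=shape)
            rr_n, cc_n = disk(c, opts.nucleus_radius, shape=shape)
            cyt = activity[i, j] * opts.erktr_nuclear_intensity
            erktr[j, rr_c, cc_c] = opts.background + cyt
            erktr[j, rr_n, cc_n] = opts.background + \
                opts.erktr_nuclear_intensity
            h2b[j, rr_n, cc_n] = opts.background + opts.h2b_intensity
            masks[j, rr_n, cc_n] = cell_ids[i]

    if opts.photon_noise > 0:
        h2b += rng.normal(0, opts.photon_noise, h2b.shape)
        erktr += rng.normal(0, opts.photon_noise, erktr.shape)

    top = 2 ** opts.bit_depth - 1
    h2b = np.clip(np.rint(h2b), 0, top).astype(np.uint16)
    erktr = np.clip(np.rint(erktr), 0, top).astype(np.uint16)

    truth = TimelapseGroundTruth(
        positions=positions, activity=activity,
        responder=trace_truth.responder, nuclear_masks=masks,
        cell_ids=cell_ids)
    return h2b, erktr, truth
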