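"""Synthetic three-channel fluorescent tissue sections with ground truth.

A section is rendered as a DAPI-positive lung region (an ellipse occupying a
configurable fraction of the field) containing vimentin-positive tumor
blobs (disks) with a per-tumor marker intensity in the third channel.
Ground truth records the lung area, tumor count, per-tumor areas and the
90th-percentile marker intensity inside each tumor, all recomputed from the
rendered masks so the truth is self-consistent with the image by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import disk, ellipse

__all__ = ["TissueSimParams", "TissueGroundTruth", "simulate_tissue_section"]


@dataclass
class TissueSimParams:
    """Parameters of one rendered section."""

    image_shape: tuple[int, int] = (768, 768)
    pixel_size: float = 0.32                 # µm per pixel
    n_tumors: int = 5
    tumor_radius_range: tuple[float, float] = (10.0, 25.0)   # px
    min_tumor_separation: float = 10.0       # px edge-to-edge gap
    lung_fill_fraction: float = 0.6          # of the image area
    marker_intensity_mean: float = 6000.0    # per-tumor mean, counts
    marker_intensity_cv: float = 0.3
    dapi_intensity: float = 2000.0
    vimentin_intensity: float = 4000.0
    background: float = 150.0
    noise_sigma: float = 30.0                # counts, all channels
    channel_bit_depth: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tumors < 0:
            raise ValueError("n_tumors must be >= 0")
        if not 0 < self.lung_fill_fraction <= 1:
            raise ValueError("lung_fill_fraction must lie in (0, 1]")
        if self.tumor_radius_range[0] > self.tumor_radius_range[1]:
            raise ValueError("tumor_radius_range must be (lo, hi)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")


@dataclass
class TissueGroundTruth:
    """Truth paired with a rendered section.  Areas in px²."""

    lung_mask: np.ndarray
    tumor_labels: np.ndarray
    lung_area_px: int
    tumor_count: int
    tumor_areas_px: np.ndarray
    tumor_marker_p90: np.ndarray
    burden_percent: float


def _lung_mask(shape: tuple[int, int], fill: float) -> np.ndarray:
    """Axis-aligned ellipse whose area is ``fill`` of the image."""
    h, w = shape
    if fill >= 1.0:
        return np.ones(shape, dtype=bool)
    mask = np.zeros(shape, dtype=bool)
    if fill <= np.pi / 4:
        # ellipse proportional to the image, scaled to the fill area
        scale = np.sqrt(fill * h * w / (np.pi * (0.5 * h) * (0.5 * w)))
        rr, cc = ellipse(h / 2, w / 2, 0.5 * h * scale, 0.5 * w * scale,
                         shape=shape)
        mask[rr, cc] = True
    else:
        # the inscribed ellipse caps at pi/4; use a centered rectangle
        s = np.sqrt(fill)
        dr, dc = int(round(h * s / 2)), int(round(w * s / 2))
        mask[h // 2 - dr:h // 2 + dr, w // 2 - dc:w // 2 + dc] = True
    return mask


def _place_tumors(params: TissueSimParams, lung: np.ndarray,
                  rng: np.random.Generator,
                  max_tries: int = 50_000) -> list[tuple[np.ndarray, float]]:
    """Sample tumor (center, radius) pairs fully inside the lung region."""
    h, w = params.image_shape
    placed: list[tuple[np.ndarray, float]] = []
    interior = np.argwhere(lung)
    if params.n_tumors and len(interior) == 0:
        raise ValueError("lung region is empty; cannot place tumors")
    for _ in range(max_tries):
        if len(placed) == params.n_tumors:
            break
        r = rng.uniform(*params.tumor_radius_range)
        center = interior[rng.integers(len(interior))].astype(float)
        rr, cc = disk(center, r + 1, shape=(h, w))
        if not lung[rr, cc].all():           # blob must sit inside the lung
            continue
        ok = all(np.hypot(*(center - c)) >= r + rc +
                 params.min_tumor_separation for c, rc in placed)
        if ok:
            placed.append((center, r))
    if len(placed) < params.n_tumors:
        raise ValueError(
            f"could only place {len(placed)} of {params.n_tumors} tumors "
            "at the requested separation")
    return placed


def simulate_tissue_section(
        params: TissueSimParams,
) -> tuple[dict[str, np.ndarray], TissueGroundTruth]:
    """Render a DAPI / vimentin / marker section.

    Returns
    -------
    channels : dict with uint16 arrays ``dapi``, ``vimentin``, ``marker``
    truth : TissueGroundTruth
    """
    rng = np.random.default_rng(params.seed)
    shape = params.image_shape
    lung = _lung_mask(shape, params.lung_fill_fraction)

    tumors = _place_tumors(params, lung, rng) if params.n_tumors else []

    tumor_labels = np.zeros(shape, dtype=np.int32)
    marker_levels = []
    for lab, (center, r) in enumerate(tumors, start=1):
        rr, cc = disk(center, r, shape=shape)
        tumor_labels[rr, cc] = lab
        if params.marker_intensity_cv > 0:
            k = 1.0 / params.marker_intensity_cv ** 2
            level = rng.gamma(k, params.marker_intensity_mean / k)
        else:
            level = params.marker_intensity_mean
        marker_levels.append(level)

    dapi = np.full(shape, params.background, dtype=float)
    dapi[lung] += params.dapi_intensity
    vim = np.full(shape, params.background, dtype=float)
    vim[tumor_labels > 0] += params.vimentin_intensity
    marker = np.full(shape, params.background, dtype=float)
    for lab, level in enumerate(marker_levels, start=1):
        marker[tumor_labels == lab] += level

    if params.noise_sigma > 0:
        for img in (dapi, vim, marker):
            img += rng.normal(0, params.noise_sigma, shape)

    top = 2 ** params.channel_bit_depth - 1
    channels = {
        name: np.clip(np.rint(img), 0, top).astype(np.uint16)
        for name, img in (("dapi", dapi), ("vimentin", vim),
                          ("marker", marker))
    }

    # truth recomputed from the rendered masks and image
    areas = np.array([(tumor_labels == lab).sum()
                      for lab in range(1, len(tumors) + 1)], dtype=int)
    p90 = np.array([
        np.percentile(channels["marker"][tumor_labels == lab], 90)
        for lab in range(1, len(tumors) + 1)])
    lung_area = int(lung.sum())
    burden = 100.0 * areas.sum() / lung_area if lung_area else 0.0
    truth = TissueGroundTruth(
        lung_mask=lung, tumor_labels=tumor_labels, lung_area_px=lung_area,
        tumor_count=len(tumors), tumor_areas_px=areas, tumor_marker_p90=p90,
        burden_percent=burden)
    return channels, truth
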