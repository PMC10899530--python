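"""Fluorescent-histology quantification.

Tissue (lung) segmentation from the DAPI channel and tumor segmentation
from the vimentin channel by auto-threshold (Otsu), metastatic burden as
the percentage of lung area occupied by tumor, tumor counting, the
90th-percentile marker intensity within the tumor mask, per-cell
compartment signal for fixed-cell stains, and Bland-Altman agreement
between manual and automated quantifications.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import regionprops
from skimage.morphology import closing, disk as disk_footprint
from skimage.segmentation import relabel_sequential
from skimage.transform import rescale

__all__ = ["TissueOptions", "BurdenReport", "BlandAltmanResult",
           "segment_tissue", "segment_tumor", "metastatic_burden",
           "marker_p90", "icc_compartment_signal", "bland_altman",
           "downscale_channels"]


@dataclass
class TissueOptions:
    """Histology segmentation knobs."""

    min_tissue_area: int = 1000     # px²; smaller tissue fragments dropped
    min_tumor_area: int = 50        # px²; smaller vimentin blobs dropped
    closing_radius: int = 2         # px; morphological closing of tissue
    min_separation_sd: float = 4.0  # Otsu class-separation guard, in SDs
    pixel_size: float = 0.32        # µm per pixel


def _guarded_otsu(img: np.ndarray, min_separation_sd: float,
                  mask: np.ndarray | None = None) -> np.ndarray:
    """Otsu threshold with a class-separation guard.

    Otsu always splits a histogram, even when the channel carries no
    signal (pure noise splits at ~1.6 pooled SDs of separation); the guard
    requires the above/below-threshold class means to be at least
    ``min_separation_sd`` pooled within-class SDs apart, otherwise the
    mask is declared empty.
    """
    sel = img[mask] if mask is not None else img.ravel()
    if sel.size == 0 or sel.max() == sel.min():
        return np.zeros(img.shape, dtype=bool)
    thr = threshold_otsu(sel)
    fg = sel[sel > thr]
    bg = sel[sel <= thr]
    if fg.size == 0 or bg.size == 0:
        return np.zeros(img.shape, dtype=bool)
    pooled_sd = max(np.sqrt((fg.var() + bg.var()) / 2), 1e-9)
    if (fg.mean() - bg.mean()) / pooled_sd < min_separation_sd:
        return np.zeros(img.shape, dtype=bool)
    binary = img > thr
    if mask is not None:
        binary &= mask
    return binary


def segment_tissue(dapi: np.ndarray,
                   opts: TissueOptions | None = None,
                   manual_add: np.ndarray | None = None,
                   manual_remove: np.ndarray | None = None) -> np.ndarray:
    """Binary lung/tissue mask from the DAPI channel.

    Auto-threshold (Otsu with contrast guard), morphological closing,
    hole filling, minimum-area component filter.  Optional operator
    correction masks are applied last: ``manual_add`` by union,
    ``manual_remove`` by subtraction — never silently.
    """
    opts = opts or TissueOptions()
    img = np.asarray(dapi, dtype=float)
    binary = _guarded_otsu(img, opts.min_separation_sd)
    if binary.any():
        if opts.closing_radius > 0:
            binary = closing(binary, disk_footprint(opts.closing_radius))
        binary = ndi.binary_fill_holes(binary)
        labels, _ = ndi.label(binary)
        sizes = np.bincount(labels.ravel())
        keep = np.nonzero(sizes >= opts.min_tissue_area)[0]
        keep = keep[keep != 0]
        binary = np.isin(labels, keep)
    if manual_add is not None:
        binary = binary | np.asarray(manual_add, dtype=bool)
    if manual_remove is not None:
        binary = binary & ~np.asarray(manual_remove, dtype=bool)
    return binary


def segment_tumor(vimentin: np.ndarray, tissue_mask: np.ndarray,
                  opts: TissueOptions | None = None) -> np.ndarray:
    """Label mask of tumors from the vimentin channel within the tissue.

    Otsu restricted to tissue pixels, minimum-area filter, 8-connected
    component labels.  Signal outside the tissue mask is ignored.
    """
    opts = opts or TissueOptions()
    img = np.asarray(vimentin, dtype=float)
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    binary = _guarded_otsu(img, opts.min_separation_sd, mask=tissue_mask)
    if not binary.any():
        return np.zeros(img.shape, dtype=np.int32)
    labels, _ = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    sizes = np.bincount(labels.ravel())
    small = np.nonzero(sizes < opts.min_tumor_area)[0]
    if len(small):
        labels[np.isin(labels, small)] = 0
    labels, _, _ = relabel_sequential(labels)
    return labels.astype(np.int32)


@dataclass
class BurdenReport:
    """Lung area, tumor area/count and metastatic burden for one section."""

    lung_area_px: int
    tumor_area_px: int
    tumor_count: int
    burden_percent: float
    pixel_size: float = 0.32

    @property
    def lung_area_um2(self) -> float:
        return self.lung_area_px * self.pixel_size ** 2

    @property
    def tumor_area_um2(self) -> float:
        return self.tumor_area_px * self.pixel_size ** 2

    def to_dict(self) -> dict:
        return {
            "lung_area_px": self.lung_area_px,
            "lung_area_um2": self.lung_area_um2,
            "tumor_area_px": self.tumor_area_px,
            "tumor_area_um2": self.tumor_area_um2,
            "tumor_count": self.tumor_count,
            "burden_percent": self.burden_percent,
            "pixel_size_um": self.pixel_size,
        }


def metastatic_burden(tissue_mask: np.ndarray, tumor_labels: np.ndarray,
                      pixel_size: float = 0.32) -> BurdenReport:
    """Metastatic burden: total tumor area / lung area x 100.

    Tumor pixels outside the tissue mask are not counted.
    """
    tissue_mask = np.asarray(tissue_mask, dtype=bool)
    tumor_labels = np.asarray(tumor_labels)
    lung_area = int(tissue_mask.sum())
    if lung_area == 0:
        raise ValueError("lung area is zero")
    tumor_mask = (tumor_labels > 0) & tissue_mask
    tumor_area = int(tumor_mask.sum())
    count = len(np.unique(tumor_labels[tumor_mask]))
    burden = 100.0 * tumor_area / lung_area
    return BurdenReport(lung_area_px=lung_area, tumor_area_px=tumor_area,
                        tumor_count=count, burden_percent=burden,
                        pixel_size=pixel_size)


def marker_p90(marker: np.ndarray, tumor_labels: np.ndarray,
               scope: str = "whole_mask") -> float | np.ndarray | None:
    """90th-percentile marker intensity within the tumor (vimentin) mask.

    Linear-interpolation percentile convention.  ``whole_mask`` pools all
    tumor pixels; ``per_tumor`` returns one value per label.  Empty masks
    yield None (or NaN per empty label).
    """
    marker = np.asarray(marker)
    tumor_labels = np.asarray(tumor_labels)
    if scope == "whole_mask":
        px = marker[tumor_labels > 0]
        if px.size == 0:
            return None
        return float(np.percentile(px, 90))
    if scope == "per_tumor":
        labs = np.unique(tumor_labels)
        labs = labs[labs > 0]
        if len(labs) == 0:
            return None
        return np.array([float(np.percentile(marker[tumor_labels == lab], 90))
                         for lab in labs])
    raise ValueError(f"unknown scope {scope!r}")


def icc_compartment_signal(image: np.ndarray, nuclei: np.ndarray,
                           rings: np.ndarray, compartment: str,
                           control_mean: float | None = None,
                           ) -> np.ndarray:
    """Per-cell mean stain intensity in one compartment, control-normalized.

    ``compartment`` selects the nuclear mask or the cytoplasmic ring
    (markers are quantified in the compartment where they localize).
    When ``control_mean`` is given, values are divided by it (normalization
    to the control condition); it must be positive.
    """
    if compartment not in ("nuclear", "cytoplasmic"):
        raise ValueError(f"unknown compartment {compartment!r}")
    mask = np.asarray(nuclei if compartment == "nuclear" else rings)
    image = np.asarray(image, dtype=float)
    labs = np.unique(mask)
    labs = labs[labs > 0]
    means = np.array([image[mask == lab].mean() for lab in labs])
    if control_mean is not None:
        if control_mean <= 0:
            raise ValueError("control mean must be positive")
        means = means / control_mean
    return means


@dataclass
class BlandAltmanResult:
    """Agreement between two measurement methods on paired values."""

    bias: float
    loa_low: float
    loa_high: float
    sd: float
    n: int


def bland_altman(manual: np.ndarray, automated: np.ndarray,
                 ) -> BlandAltmanResult:
    """Bland-Altman bias and 95% limits of agreement.

    Differences are automated - manual; limits are
    bias +/- 1.96 * SD(differences) with the n-1 denominator.
    """
    manual = np.asarray(manual, dtype=float)
    automated = np.asarray(automated, dtype=float)
    if manual.shape != automated.shape:
        raise ValueError("paired vectors must have equal length")
    n = manual.size
    if n < 2:
        raise ValueError("need at least 2 paired measurements")
    d = automated - manual
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, sd=sd, n=n)


def downscale_channels(channels: dict[str, np.ndarray],
                       factor: float) -> dict[str, np.ndarray]:
    """Area-weighted downscale of all channels by ``factor`` in (0, 1]."""
    if not 0 < factor <= 1:
        raise ValueError("factor must lie in (0, 1]")
    if factor == 1:
        return dict(channels)
    out = {}
    for name, img in channels.items():
        scaled = rescale(np.asarray(img, dtype=float), factor,
                         anti_aliasing=False, order=1,
                         preserve_range=True)
        out[name] = scaled.astype(img.dtype) if np.issubdtype(
            np.asarray(img).dtype, np.integer) else scaled
    return out
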