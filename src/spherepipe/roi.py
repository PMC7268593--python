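"""Detection and extraction of regions of interest around phase objects.

Sparsely distributed spherical objects (beads, cells, isolated nuclei) are
segmented by thresholding the background-corrected phase, labeling
4-connected components (holes filled — nucleoli-induced holes must not
split a nucleus), and keeping components whose equivalent diameter matches
the expected specimen size.  ROI identifiers are hierarchical
``<dataset>_<image>.<roi>`` with 1-based image/roi numbers, stable across
reruns so that user exclusion lists remain valid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .bg import BackgroundSpec, correct_qpi

__all__ = ["ROI", "compute_threshold", "find_rois", "filter_ignored",
           "extract_roi"]

logger = logging.getLogger(__name__)


@dataclass
class ROI:
    """Rectangular region with half-open pixel bounds [r0, r1) x [c0, c1)."""

    image_index: int          # 1-based position of the image in the series
    roi_index: int            # 1-based per image
    r0: int
    r1: int
    c0: int
    c1: int
    dataset: str = ""

    def __post_init__(self):
        if not (0 <= self.r0 < self.r1 and 0 <= self.c0 < self.c1):
            raise ValueError("invalid ROI bounds")

    @property
    def identifier(self) -> str:
        return f"{self.dataset}_{self.image_index}.{self.roi_index}"

    @property
    def shape(self):
        return (self.r1 - self.r0, self.c1 - self.c0)

    def slices(self):
        return (slice(self.r0, self.r1), slice(self.c0, self.c1))


def compute_threshold(phase: np.ndarray, method="dm-nuclei") -> float:
    """Segmentation threshold for a phase image.

    A numeric ``method`` is returned unchanged.  ``"otsu"`` is the
    bimodal-histogram threshold (256 bins).  ``"dm-nuclei"`` is the
    nucleus-robust rule: discard the top 1% of pixel values (by count) and
    place the threshold at 20% of the remaining maximum, relative to the
    mean of the original phase::

        t = mean(phase) + 0.2 * (max_trimmed - mean(phase))

    This copes with bright nucleoli inside dim nuclei, where plain Otsu
    either misses the nucleus or segments only the nucleoli.
    """
    if not isinstance(method, str):
        return float(method)
    phase = np.asarray(phase, dtype=float).ravel()
    if method == "otsu":
        return float(threshold_otsu(phase, nbins=256))
    if method != "dm-nuclei":
        raise ValueError(f"unknown threshold method {method!r}")
    mean = float(phase.mean())
    n = phase.size
    k = int(np.ceil(0.01 * n))  # number of top values to discard
    if k >= n:
        return mean
    trimmed_max = float(np.partition(phase, n - k - 1)[n - k - 1])
    return mean + 0.2 * (trimmed_max - mean)


def find_rois(phase: np.ndarray, size_px: float, variation: float = 0.5,
              pad_px: int = 10, threshold_method="dm-nuclei",
              image_index: int = 1, dataset: str = "") -> list[ROI]:
    """Detect candidate objects of diameter ``size_px`` (+- ``variation``
    relative) in a background-corrected phase image.

    Pixels above the threshold are labeled as 4-connected components
    (holes filled); components whose equivalent diameter
    ``d = 2 sqrt(area / pi)`` satisfies ``|d - size_px| <= variation *
    size_px`` (boundary inclusive) are kept.  Bounding boxes are expanded
    by ``pad_px`` and clipped to the image; roi indices are assigned
    1..K in (r0, c0) order.
    """
    if size_px < 5:
        raise ValueError("size_px must be >= 5")
    if not 0 < variation < 1:
        raise ValueError("variation must be in (0, 1)")
    phase = np.asarray(phase, dtype=float)
    t = compute_threshold(phase, threshold_method)
    binary = ndimage.binary_fill_holes(phase > t)
    labels = measure.label(binary, connectivity=1)

    boxes = []
    for prop in measure.regionprops(labels):
        d = 2.0 * np.sqrt(prop.area / np.pi)
        if abs(d - size_px) <= variation * size_px:
            r0, c0, r1, c1 = prop.bbox
            # objects touching the frame border are only partially imaged
            # (and reconstruction artifacts concentrate there): discard
            m = 5
            if (r0 < m or c0 < m or r1 > phase.shape[0] - m
                    or c1 > phase.shape[1] - m):
                continue
            # a high threshold may segment only the top of a dim object:
            # grow the box to at least the stated specimen size so the
            # crop contains the full object and true background
            def grow(a, b, lim):
                short = int(np.ceil(size_px)) - (b - a)
                if short > 0:
                    a = max(0, a - short // 2)
                    b = min(lim, a + int(np.ceil(size_px)))
                return a, b
            r0, r1 = grow(r0, r1, phase.shape[0])
            c0, c1 = grow(c0, c1, phase.shape[1])
            boxes.append((max(0, r0 - pad_px), min(phase.shape[0], r1 + pad_px),
                          max(0, c0 - pad_px), min(phase.shape[1], c1 + pad_px)))
    boxes.sort(key=lambda b: (b[0], b[2]))
    return [ROI(image_index=image_index, roi_index=j + 1, r0=r0, r1=r1,
                c0=c0, c1=c1, dataset=dataset)
            for j, (r0, r1, c0, c1) in enumerate(boxes)]


def filter_ignored(rois: list[ROI], ignore) -> list[ROI]:
    """Drop ROIs whose (image_index, roi_index) appear in ``ignore``.

    Remaining roi indices are *not* renumbered, keeping identifiers stable
    across reruns.  Ignore entries matching nothing produce a warning.
    """
    ignore = {tuple(pair) for pair in ignore}
    present = {(r.image_index, r.roi_index) for r in rois}
    for pair in sorted(ignore - present):
        logger.warning("ignore entry %d.%d matches no ROI", *pair)
    return [r for r in rois if (r.image_index, r.roi_index) not in ignore]


def extract_roi(qpi, roi: ROI, bg_spec: BackgroundSpec | None = None):
    """Crop ``qpi`` to ``roi`` and apply the per-ROI background correction.

    When the spec's ``border_px`` is unset it defaults to 10% of the
    smaller ROI dimension.  Metadata is copied; the identifier is set to
    the ROI's hierarchical identifier.
    """
    H, W = qpi.phase.shape
    if roi.r1 > H or roi.c1 > W:
        raise ValueError(f"ROI {roi.identifier} exceeds image bounds")
    sl = roi.slices()
    cropped = qpi.copy(phase=qpi.phase[sl].copy(),
                       amplitude=qpi.amplitude[sl].copy(),
                       identifier=roi.identifier)
    if bg_spec is None:
        return cropped
    if bg_spec.profile != "image" and bg_spec.border_px is None:
        bg_spec = BackgroundSpec(
            profile=bg_spec.profile,
            border_px=max(1, int(round(0.1 * min(cropped.phase.shape)))),
            binary_threshold=bg_spec.binary_threshold,
            offset_mode=bg_spec.offset_mode)
    return correct_qpi(cropped, bg_spec)
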