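"""Nucleus and fiber segmentation from the structural channel.

Nuclei are segmented from a DNA-dye frame by Otsu thresholding of the
smoothed image; the fiber footprint comes from the Ca2+ indicator channel the
same way.  Both thresholds are data-driven, so segmentation is invariant to a
positive rescaling of the intensities.  Hand-drawn outlines can be supplied
instead of the automatic path via :func:`masks_from_labels`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import filters, measure, morphology

from .records import ImageRecord

__all__ = [
    "NucleusMask",
    "FiberMask",
    "segment_nuclei",
    "segment_fiber",
    "masks_from_labels",
    "distance_to_nucleus",
    "label_nucleus_locations",
]

DEFAULT_MIN_AREA_UM2 = 20.0  # suppress sub-nuclear debris


@dataclass
class NucleusMask:
    """One segmented nucleus on the full image grid."""

    nucleus_id: int
    mask: np.ndarray  # bool, full frame
    pixel_size_um: float
    location_class: str = "unknown"  # "peripheral" | "central" | "unknown"
    _edt: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2

    @property
    def centroid_xy_um(self) -> tuple[float, float]:
        rows, cols = np.nonzero(self.mask)
        return (float(cols.mean() + 0.5) * self.pixel_size_um,
                float(rows.mean() + 0.5) * self.pixel_size_um)

    @property
    def boundary(self) -> np.ndarray:
        """Boundary pixels (subset of the mask)."""
        return self.mask & ~ndimage.binary_erosion(self.mask)

    def distance_map_um(self) -> np.ndarray:
        """Euclidean distance (um) from each pixel to the nearest nucleus
        pixel; 0 inside the mask.  Cached."""
        if self._edt is None:
            self._edt = ndimage.distance_transform_edt(
                ~self.mask, sampling=self.pixel_size_um)
        return self._edt


@dataclass
class FiberMask:
    mask: np.ndarray
    pixel_size_um: float

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size_um**2


def _smooth(frame: np.ndarray, sigma_px: float) -> np.ndarray:
    return ndimage.gaussian_filter(frame, sigma=sigma_px)


def segment_nuclei(
    structural: ImageRecord,
    min_area_um2: float = DEFAULT_MIN_AREA_UM2,
    smoothing_sigma_px: float = 1.0,
    mode: str = "dna",
) -> list[NucleusMask]:
    """Segment nuclei from a structural frame.

    ``mode="dna"`` treats bright regions as nuclei; ``mode="membrane"``
    inverts the image first, so nuclei are detected as voids in a
    membrane/tubular-system stain (a lower-confidence proxy).  Components
    smaller than ``min_area_um2`` are dropped and holes are filled.  Returns
    an empty list when nothing exceeds the threshold.
    """
    if structural.modality != "frame":
        raise ValueError("segment_nuclei expects a single frame")
    img = _smooth(structural.pixels, smoothing_sigma_px)
    if mode == "membrane":
        img = img.max() - img
    elif mode != "dna":
        raise ValueError(f"unknown mode {mode!r}")
    if np.ptp(img) == 0:
        return []
    binary = img > filters.threshold_otsu(img)
    binary = ndimage.binary_fill_holes(binary)
    labels = measure.label(binary)
    masks: list[NucleusMask] = []
    min_px = int(np.ceil(min_area_um2 / structural.pixel_size_um**2))
    nid = 1
    for region in measure.regionprops(labels):
        if region.num_pixels < min_px:
            continue
        masks.append(NucleusMask(nucleus_id=nid, mask=labels == region.label,
                                 pixel_size_um=structural.pixel_size_um))
        nid += 1
    return masks


def segment_fiber(ca_frame: ImageRecord, smoothing_sigma_px: float = 1.0) -> FiberMask:
    """Segment the fiber footprint from the Ca2+ channel.

    Otsu threshold on the smoothed indicator frame, keep the largest
    connected component, fill holes (nuclei sit inside the fiber but can be
    dimmer than cytosol).  A blank frame is an error: there is no fiber.
    """
    if ca_frame.modality != "frame":
        raise ValueError("segment_fiber expects a single frame")
    img = _smooth(ca_frame.pixels, smoothing_sigma_px)
    if np.ptp(img) == 0:
        raise ValueError("blank frame: no fiber detectable")
    binary = img > filters.threshold_otsu(img)
    labels = measure.label(binary)
    if labels.max() == 0:
        raise ValueError("no fiber component above threshold")
    largest = np.argmax(np.bincount(labels.ravel())[1:]) + 1
    mask = ndimage.binary_fill_holes(labels == largest)
    mask = morphology.remove_small_holes(mask, max_size=64)
    return FiberMask(mask=mask, pixel_size_um=ca_frame.pixel_size_um)


def masks_from_labels(labels: np.ndarray, pixel_size_um: float) -> list[NucleusMask]:
    """Wrap a labeled image (0 = background, 1..n = nuclei) as NucleusMask
    objects — the import path for hand-drawn or ground-truth outlines."""
    return [NucleusMask(nucleus_id=int(v), mask=labels == v,
                        pixel_size_um=pixel_size_um)
            for v in np.unique(labels) if v != 0]


def distance_to_nucleus(
    point_um: tuple[float, float],
    nuclei: list[NucleusMask],
) -> tuple[float, int, bool]:
    """Distance from a point to the nearest nucleus boundary.

    Returns ``(distance_um, nucleus_id, inside)``.  A point inside a mask
    (boundary pixels included) has distance 0.  Otherwise the Euclidean
    distance to the nearest nucleus pixel is read from each nucleus's
    distance transform; the nearest nucleus wins and exact ties go to the
    lowest ``nucleus_id``.
    """
    if not nuclei:
        raise ValueError("empty nucleus list")
    ps = nuclei[0].pixel_size_um
    h, w = nuclei[0].mask.shape
    col = int(np.clip(point_um[0] / ps, 0, w - 1))
    row = int(np.clip(point_um[1] / ps, 0, h - 1))
    best = (np.inf, -1)
    for nuc in sorted(nuclei, key=lambda n: n.nucleus_id):
        if nuc.mask[row, col]:
            return 0.0, nuc.nucleus_id, True
        d = float(nuc.distance_map_um()[row, col])
        if d < best[0]:
            best = (d, nuc.nucleus_id)
    return best[0], best[1], False


def label_nucleus_locations(nuclei: list[NucleusMask], fiber: FiberMask) -> None:
    """Heuristically tag each nucleus as peripheral or central (in place).

    A nucleus whose centroid lies closer to the fiber boundary than its own
    minor semi-axis length is peripheral; otherwise central.
    """
    edge_dist = ndimage.distance_transform_edt(
        fiber.mask, sampling=fiber.pixel_size_um)
    for nuc in nuclei:
        rows, cols = np.nonzero(nuc.mask)
        # minor semi-axis from the mask's second moment
        minor_semi = measure.regionprops(nuc.mask.astype(int))[0].axis_minor_length
        minor_semi = minor_semi / 2.0 * nuc.pixel_size_um
        cx, cy = nuc.centroid_xy_um
        col = int(np.clip(cx / nuc.pixel_size_um, 0, fiber.mask.shape[1] - 1))
        row = int(np.clip(cy / nuc.pixel_size_um, 0, fiber.mask.shape[0] - 1))
        nuc.location_class = (
            "peripheral" if edge_dist[row, col] < minor_semi else "central")
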