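"""Isolation of individual objects from a full-field wrapped phase image.

Following the standard recipe for test-slide phase images: threshold the
absolute wrapped phase with Otsu's method, fill interior holes (phase
wrapping produces near-zero rings *inside* strongly retarding objects, so
hole filling is essential, not cosmetic), label 8-connected components,
discard specks, and crop each surviving object with a little padding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .phase import WQPI

__all__ = ["SegmentedObject", "otsu_threshold", "segment_slide", "match_to_truth"]

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class SegmentedObject:
    """One object cut out of a full-field WQPI.

    ``bbox`` is (row0, col0, row1, col1), half-open, in full-field pixel
    coordinates and includes the padding.  ``mask`` and ``wqpi_crop`` are
    crop-local; background pixels of the crop are set to phase 0.
    """

    mask: np.ndarray
    bbox: tuple[int, int, int, int]
    wqpi_crop: WQPI
    area_px: int
    class_id: int | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        r0, c0, r1, c1 = self.bbox
        if self.mask.shape != (r1 - r0, c1 - c0):
            raise ValueError("mask shape does not match bbox extents")
        if self.wqpi_crop.shape != self.mask.shape:
            raise ValueError("wqpi_crop shape does not match bbox extents")
        if self.area_px != int(self.mask.sum()) or self.area_px <= 0:
            raise ValueError("area_px must equal the positive mask pixel count")

    @property
    def centroid(self) -> tuple[float, float]:
        """(row, col) centroid of the mask in full-field coordinates."""
        rows, cols = np.nonzero(self.mask)
        return (float(rows.mean()) + self.bbox[0], float(cols.mean()) + self.bbox[1])


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu threshold over a 256-bin histogram of the image's value range.

    Returns the threshold maximizing the between-class variance.

    Raises
    ------
    ValueError
        If the image has fewer than two distinct values.
    """
    arr = np.asarray(image, dtype=float)
    if arr.size == 0 or arr.min() == arr.max():
        raise ValueError("Otsu threshold requires at least two distinct values")
    return float(threshold_otsu(arr, nbins=256))


def segment_slide(
    full_wqpi: WQPI, min_area_px: int = 100, pad_px: int = 8
) -> list[SegmentedObject]:
    """Segment a full-field WQPI into per-object crops.

    Thresholds ``|phase|`` with :func:`otsu_threshold`, fills interior holes,
    labels 8-connected components, discards components smaller than
    ``min_area_px``, and crops each survivor with ``pad_px`` background
    padding (clipped at the field border).  Objects are returned sorted by
    (row0, col0) of their bounding boxes, i.e. in slide-layout order for a
    well-separated test slide; ``class_id`` is left unassigned.

    A blank or constant field yields an empty list (not an error).
    """
    magnitude = np.abs(full_wqpi.phase)
    if magnitude.size == 0 or magnitude.min() == magnitude.max():
        return []
    thresh = otsu_threshold(magnitude)
    binary = ndimage.binary_fill_holes(magnitude > thresh)
    labels, n_found = ndimage.label(binary, structure=_EIGHT)
    ny, nx = magnitude.shape
    out: list[SegmentedObject] = []
    for comp_id, slices in enumerate(ndimage.find_objects(labels), start=1):
        if slices is None:
            continue
        sl_r, sl_c = slices
        comp = labels == comp_id
        area = int(comp.sum())
        if area < min_area_px:
            continue
        r0 = max(sl_r.start - pad_px, 0)
        r1 = min(sl_r.stop + pad_px, ny)
        c0 = max(sl_c.start - pad_px, 0)
        c1 = min(sl_c.stop + pad_px, nx)
        mask = comp[r0:r1, c0:c1]
        crop = np.where(mask, full_wqpi.phase[r0:r1, c0:c1], 0.0)
        out.append(
            SegmentedObject(
                mask=mask,
                bbox=(r0, c0, r1, c1),
                wqpi_crop=WQPI(crop, pixel_pitch=full_wqpi.pixel_pitch),
                area_px=area,
            )
        )
    out.sort(key=lambda o: (o.bbox[0], o.bbox[1]))
    return out


def match_to_truth(
    objects: list[SegmentedObject],
    true_centroids: dict[int, tuple[float, float]],
    max_dist_px: float | None = None,
) -> list[SegmentedObject]:
    """Assign class ids by one-to-one nearest-centroid matching.

    Solves the linear assignment between segmented-object centroids and
    ground-truth centroids (``{class_id: (row, col)}``); useful on synthetic
    slides where the truth is known.  Raises if counts differ or, when
    ``max_dist_px`` is given, if any matched pair is farther than that.
    """
    from scipy.optimize import linear_sum_assignment

    if len(objects) != len(true_centroids):
        raise ValueError(
            f"{len(objects)} segmented objects vs {len(true_centroids)} ground-truth objects"
        )
    ids = sorted(true_centroids)
    seg = np.array([o.centroid for o in objects])
    tru = np.array([true_centroids[i] for i in ids])
    dist = np.linalg.norm(seg[:, None, :] - tru[None, :, :], axis=-1)
    rows, cols = linear_sum_assignment(dist)
    for r, c in zip(rows, cols):
        if max_dist_px is not None and dist[r, c] > max_dist_px:
            raise ValueError(
                f"matched centroid pair {dist[r, c]:.1f}px apart exceeds {max_dist_px}px"
            )
        objects[r].class_id = ids[c]
        objects[r].wqpi_crop.class_id = ids[c]
    return objects
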