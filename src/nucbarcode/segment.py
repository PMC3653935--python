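"""Nucleus segmentation in two modes.

Stringent mode (:func:`segment_nuclei`) finds the larger, brighter nuclei
used for counting and ratio measurement: Otsu threshold on the corrected
em1 frame, hole filling, optional distance-transform watershed to split
touching nuclei, then area and intensity floors.

Permissive mode (:func:`permissive_mask`) finds *every* fluorescent object
down to faint debris and dilates the result by a few pixels; the mask marks
pixels to exclude when estimating the residual per-field background offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import threshold_otsu
from skimage.morphology import disk
from skimage.segmentation import watershed

from .model import ValidationError


@dataclass(frozen=True)
class SegmentedObject:
    label: int
    area_px: int
    centroid: tuple[float, float]
    mean_intensity: float


def _fill_and_label(mask: np.ndarray) -> np.ndarray:
    filled = ndi.binary_fill_holes(mask)
    labels, _ = ndi.label(filled)
    return labels


def segment_nuclei(
    image: np.ndarray,
    min_area_px: int = 30,
    min_mean_intensity: float = 0.0,
    split_touching: bool = True,
    min_separation_px: int = 6,
    threshold_floor: float | None = None,
) -> tuple[np.ndarray, list[SegmentedObject]]:
    """Segment nuclei in a background-corrected em1 frame.

    Parameters
    ----------
    image
        Corrected (real-valued) em1 frame; background is ~0 after the
        two-stage correction, so thresholds are relative to zero.
    min_area_px, min_mean_intensity
        Objects smaller or dimmer than these floors are discarded.
    split_touching
        Split merged blobs by watershed seeded from distance-transform
        maxima at least ``min_separation_px`` apart (one mean nucleus
        radius is a good choice).
    threshold_floor
        Optional absolute lower bound on the Otsu threshold; guards
        against Otsu latching onto noise in nearly-empty frames.

    Returns
    -------
    labels, objects
        Integer label image (0 = background) and per-object summaries.
    """
    if min_area_px <= 0:
        raise ValidationError("min_area_px must be positive")
    if min_separation_px <= 0:
        raise ValidationError("min_separation_px must be positive")
    img = np.asarray(image, dtype=float)
    finite = img[np.isfinite(img)]
    if finite.size == 0 or finite.max() <= finite.min():
        return np.zeros(img.shape, dtype=np.int32), []
    thr = float(threshold_otsu(img))
    if threshold_floor is not None:
        thr = max(thr, float(threshold_floor))
    mask = img > thr
    if not mask.any():
        return np.zeros(img.shape, dtype=np.int32), []
    labels = _fill_and_label(mask)

    if split_touching:
        filled = labels > 0
        distance = ndi.distance_transform_edt(filled)
        peaks = peak_local_max(
            distance,
            min_distance=min_separation_px,
            labels=filled,
            exclude_border=False,
        )
        if len(peaks):
            markers = np.zeros(img.shape, dtype=np.int32)
            markers[tuple(peaks.T)] = np.arange(1, len(peaks) + 1)
            labels = watershed(-distance, markers, mask=filled)

    return _filter_objects(labels, img, min_area_px, min_mean_intensity)


def _filter_objects(
    labels: np.ndarray,
    img: np.ndarray,
    min_area_px: int,
    min_mean_intensity: float,
) -> tuple[np.ndarray, list[SegmentedObject]]:
    """Drop small/dim labels and relabel sequentially from 1."""
    n = int(labels.max())
    if n == 0:
        return labels.astype(np.int32), []
    idx = np.arange(1, n + 1)
    areas = ndi.sum_labels(np.ones_like(img), labels, index=idx)
    means = ndi.mean(img, labels, index=idx)
    keep = (areas >= min_area_px) & (means >= min_mean_intensity)
    mapping = np.zeros(n + 1, dtype=np.int32)
    mapping[idx[keep]] = np.arange(1, keep.sum() + 1)
    relabeled = mapping[labels]

    objects: list[SegmentedObject] = []
    if keep.any():
        kept = np.arange(1, int(keep.sum()) + 1)
        centroids = ndi.center_of_mass(
            np.ones_like(img), relabeled, index=kept
        )
        kept_areas = areas[keep]
        kept_means = means[keep]
        for lab, area, cen, mean in zip(kept, kept_areas, centroids, kept_means):
            objects.append(
                SegmentedObject(
                    label=int(lab),
                    area_px=int(round(area)),
                    centroid=(float(cen[0]), float(cen[1])),
                    mean_intensity=float(mean),
                )
            )
    return relabeled, objects


def permissive_mask(
    image: np.ndarray,
    dilation_px: int = 3,
    highpass_sigma: float | None = 25.0,
    min_object_px: int = 3,
) -> np.ndarray:
    """Mask every detectable object, however small or faint, then dilate.

    Objects are detected *above local background*: a heavily smoothed
    (Gaussian, ``highpass_sigma``) copy of the frame is subtracted first,
    so slow illumination gradients (vignetting) are not mistaken for
    objects; pass ``highpass_sigma=None`` to skip this on frames that are
    already flat.  The threshold is then median + 2 robust standard
    deviations (MAD-based), so faint debris is masked.  Connected
    components below ``min_object_px`` pixels are treated as shot-noise
    speckle, not objects, and dropped (at the 2-sd threshold ~2% of pure
    noise pixels fire; isolated pixels would otherwise dilate into a mask
    covering half the frame).  The surviving mask is grown by
    ``dilation_px`` with a disk structuring element.  True pixels are
    excluded from background-offset estimation.
    """
    if dilation_px < 0:
        raise ValidationError("dilation_px must be non-negative")
    img = np.asarray(image, dtype=float)
    if highpass_sigma:
        img = img - ndi.gaussian_filter(img, sigma=highpass_sigma)
    med = float(np.median(img))
    mad = float(np.median(np.abs(img - med)))
    robust_sd = 1.4826 * mad
    thr = med + 2.0 * robust_sd
    mask = img > thr
    if min_object_px > 1 and mask.any():
        lab, n = ndi.label(mask)
        sizes = ndi.sum_labels(np.ones_like(img), lab, index=np.arange(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:][sizes >= min_object_px] = True
        mask = keep[lab]
    if dilation_px > 0 and mask.any():
        mask = ndi.binary_dilation(mask, structure=disk(dilation_px))
    return mask


def counterstain_fraction(
    labels: np.ndarray,
    counterstain: np.ndarray,
    positive_threshold: float,
) -> float | None:
    """Fraction of segmented objects that are counterstain-positive.

    An object is positive when its mean counterstain intensity exceeds
    ``positive_threshold``.  Returns ``None`` (not 0.0) when there are no
    objects, since the fraction is then undefined.
    """
    labels = np.asarray(labels)
    if labels.shape != np.asarray(counterstain).shape:
        raise ValidationError("label image and counterstain dimensions differ")
    n = int(labels.max())
    if n == 0:
        return None
    idx = np.arange(1, n + 1)
    present = np.isin(idx, labels)
    idx = idx[present]
    if idx.size == 0:
        return None
    means = ndi.mean(np.asarray(counterstain, dtype=float), labels, index=idx)
    return float(np.mean(means > positive_threshold))
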