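"""Method M1: quadrant-based cortical ROI densitometry.

Each standardized transverse slice is divided into four anatomical quadrants
(anterior, posterior, medial, lateral) by orthogonal axes through the
geometric center of the bone section.  Within each quadrant one circular ROI
is placed in cortical bone, prioritizing homogeneous areas with the highest
density; the slice BMD is the arithmetic mean of the four ROI means.

The ROI search is exhaustive over a candidate grid of centers whose disk
fits entirely inside the quadrant's bone mask.  "Homogeneous" is
operationalized as ROI SD <= homogeneity_limit * ROI mean (default 0.15); if
no candidate satisfies the constraint the unconstrained max-mean ROI is
taken.  Replicates re-run the search with the candidate grid origin jittered
by a sub-pixel offset, emulating the small placement variation of repeated
manual readings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import MeasurementError

__all__ = ["M1Config", "QuadrantSet", "CircularRoi", "bone_mask",
           "geometric_center", "quadrant_partition", "place_cortical_roi",
           "m1_slice_bmd"]

_EIGHT = np.ones((3, 3), dtype=bool)

QUADRANT_NAMES = ("anterior", "medial", "posterior", "lateral")


@dataclass(frozen=True)
class M1Config:
    """Tunables of the quadrant-ROI method.

    ``roi_radius_px`` defaults to 2 px (~0.5 mm at 0.25 mm pixels); the disk
    then holds 13 pixels, just above ``min_roi_pixels``.
    """

    low: float = 200.0
    high: float = 2000.0
    roi_radius_px: int = 2
    min_roi_radius_px: int = 2
    min_roi_pixels: int = 12
    homogeneity_limit: float = 0.15


@dataclass(frozen=True)
class QuadrantSet:
    """Four disjoint quadrant masks covering the bone mask of one slice."""

    center: tuple[float, float]
    masks: Mapping[str, np.ndarray]


@dataclass(frozen=True)
class CircularRoi:
    """One placed cortical ROI and its density statistics."""

    center_row: float
    center_col: float
    radius_px: float
    mean_bmd: float
    sd_bmd: float
    n_pixels: int
    quadrant: str = ""
    replicate: int = 0


def bone_mask(bmd_slice: np.ndarray, low: float = 200.0, high: float = 2000.0,
              exclude: np.ndarray | None = None) -> np.ndarray:
    """Largest connected component of in-window pixels (8-connectivity).

    ``exclude`` masks out non-bone structures in the window, e.g. the
    calibration phantom.
    """
    in_range = (bmd_slice >= low) & (bmd_slice <= high)
    if exclude is not None:
        in_range &= ~exclude
    labels, n = ndimage.label(in_range, structure=_EIGHT)
    if n == 0:
        raise MeasurementError("no pixels inside the density window")
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, index=range(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def geometric_center(mask: np.ndarray) -> tuple[float, float]:
    """Unweighted centroid (area center) of the mask pixels."""
    if not mask.any():
        raise MeasurementError("empty mask has no geometric center")
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def quadrant_partition(mask: np.ndarray, center: tuple[float, float]) -> QuadrantSet:
    """Assign each mask pixel to one of four 90-degree sectors.

    Sector boundaries lie on the image diagonals so each quadrant is centred
    on a cardinal direction: up (decreasing row) = anterior, down =
    posterior, left = medial, right = lateral.  A pixel exactly on a
    diagonal goes to the counter-clockwise sector.
    """
    cr, cc = center
    rows, cols = np.indices(mask.shape)
    # angle in degrees, up = 90, right = 0, measured counter-clockwise
    ang = np.degrees(np.arctan2(cr - rows, cols - cc)) % 360.0
    masks = {
        "anterior": mask & (ang >= 45.0) & (ang < 135.0),
        "medial": mask & (ang >= 135.0) & (ang < 225.0),
        "posterior": mask & (ang >= 225.0) & (ang < 315.0),
        "lateral": mask & ((ang >= 315.0) | (ang < 45.0)),
    }
    return QuadrantSet(center=(cr, cc), masks=masks)


def _disk_footprint(radius: float, jitter: tuple[float, float]) -> np.ndarray:
    """Boolean kernel of the pixelated ROI disk at a sub-pixel center offset.

    The kernel always holds exactly as many pixels as the zero-offset disk
    (the offsets nearest to the jittered center), so jittered replicates
    compare equal-area ROIs and the minimum-pixel-count contract is not
    broken by rasterization.
    """
    k = int(math.ceil(radius + 1.0))
    d = np.arange(-k, k + 1)
    drr, dcc = np.meshgrid(d, d, indexing="ij")
    n0 = int(np.count_nonzero(drr ** 2 + dcc ** 2 <= radius ** 2))
    dist = (drr - jitter[0]) ** 2 + (dcc - jitter[1]) ** 2
    order = np.lexsort((dcc.ravel(), drr.ravel(), dist.ravel()))
    fp = np.zeros(drr.shape, dtype=bool)
    fp.ravel()[order[:n0]] = True
    return fp


def place_cortical_roi(quadrant_mask: np.ndarray, bmd_slice: np.ndarray,
                       radius_px: int = 2, homogeneity_limit: float = 0.15,
                       jitter: tuple[float, float] = (0.0, 0.0),
                       min_roi_pixels: int = 12,
                       min_radius_px: int = 2) -> CircularRoi:
    """Exhaustive max-mean ROI search within one quadrant's bone mask.

    Candidate centers are every pixel (plus the sub-pixel ``jitter`` offset)
    whose disk lies entirely inside ``quadrant_mask``.  Among candidates with
    ROI SD <= homogeneity_limit * ROI mean the one with the highest mean is
    chosen (falling back to the unconstrained maximum if none qualifies);
    ties break to the smallest (row, col).  If the quadrant is too thin for
    the disk the radius shrinks in 1 px steps down to ``min_radius_px``
    before giving up.
    """
    bmd = np.asarray(bmd_slice, dtype=float)
    for radius in range(int(radius_px), int(min_radius_px) - 1, -1):
        fp = _disk_footprint(float(radius), jitter)
        n = int(fp.sum())
        if n < min_roi_pixels:
            break
        fpf = fp.astype(float)
        coverage = ndimage.correlate(quadrant_mask.astype(float), fpf,
                                     mode="constant", cval=0.0)
        admissible = coverage > n - 0.5
        if not admissible.any():
            continue
        s1 = ndimage.correlate(bmd, fpf, mode="constant", cval=0.0)
        s2 = ndimage.correlate(bmd * bmd, fpf, mode="constant", cval=0.0)
        mean = s1 / n
        var = np.maximum(s2 / n - mean * mean, 0.0)
        sd = np.sqrt(var)
        homogeneous = admissible & (sd <= homogeneity_limit * np.abs(mean))
        pool = homogeneous if homogeneous.any() else admissible
        score = np.where(pool, mean, -np.inf)
        flat = int(np.argmax(score))          # first max in row-major = lex tie-break
        r0, c0 = np.unravel_index(flat, score.shape)
        return CircularRoi(center_row=r0 + jitter[0], center_col=c0 + jitter[1],
                           radius_px=float(radius), mean_bmd=float(mean[r0, c0]),
                           sd_bmd=float(sd[r0, c0]), n_pixels=n)
    raise MeasurementError("quadrant admits no ROI center at the minimum radius")


def m1_slice_bmd(bmd_slice: np.ndarray, config: M1Config = M1Config(),
                 exclude: np.ndarray | None = None,
                 replicate_seed: int | None = None,
                 replicate: int = 0):
    """Measure one slice: four quadrant ROIs and their arithmetic mean.

    Returns ``(rois, slice_bmd, quadrants)`` where ``rois`` maps quadrant
    name -> :class:`CircularRoi`.
    """
    mask = bone_mask(bmd_slice, config.low, config.high, exclude=exclude)
    center = geometric_center(mask)
    quads = quadrant_partition(mask, center)
    if replicate_seed is None:
        jitter = (0.0, 0.0)
    else:
        rng = np.random.default_rng(replicate_seed)
        jitter = tuple(rng.uniform(-0.5, 0.5, size=2))
    rois = {}
    for name in QUADRANT_NAMES:
        roi = place_cortical_roi(quads.masks[name], bmd_slice,
                                 radius_px=config.roi_radius_px,
                                 homogeneity_limit=config.homogeneity_limit,
                                 jitter=jitter,
                                 min_roi_pixels=config.min_roi_pixels,
                                 min_radius_px=config.min_roi_radius_px)
        rois[name] = CircularRoi(roi.center_row, roi.center_col, roi.radius_px,
                                 roi.mean_bmd, roi.sd_bmd, roi.n_pixels,
                                 quadrant=name, replicate=replicate)
    slice_bmd = float(np.mean([r.mean_bmd for r in rois.values()]))
    return rois, slice_bmd, quads
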