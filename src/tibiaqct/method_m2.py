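"""Method M2: whole-bone densitometry by seeded 2-D region growing.

The entire mineralized bone area of each standardized slice is segmented by
growing from a seed pixel to all connected pixels inside a density window
(defaults 200-2000 mgHA/cm3: the lower bound separates bone from soft
tissue, the upper bound rejects hyperdense artifacts).  The mean, SD,
minimum, maximum, pixel count, area and contributed volume of the selected
region are reported, mirroring a DICOM workstation's "2D Grow Region" +
"ROI volume" tools.

Seed choice is deterministic: replicate r takes the r-th highest-density
in-window pixel at least 3 px from previously used seeds, so replicates of a
simply connected bone section grow identical masks and the replicate CV of
M2 is essentially zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import MeasurementError, SeedError

__all__ = ["SegmentationResult", "grow_region", "pick_seeds", "m2_slice_stats",
           "m2_slice_bmd"]

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class SegmentationResult:
    """Statistics of one grown region on one slice."""

    mean_bmd: float
    sd_bmd: float      # population SD (divisor n) over the mask
    min_bmd: float
    max_bmd: float
    n_pixels: int
    area_mm2: float
    volume_mm3: float  # area * slice thickness
    seed: tuple[int, int]
    replicate: int = 0
    mask: np.ndarray | None = None


def grow_region(bmd_slice: np.ndarray, seed: tuple[int, int],
                low: float = 200.0, high: float = 2000.0,
                connectivity: int = 2,
                exclude: np.ndarray | None = None) -> np.ndarray:
    """Connected component of the in-window set containing ``seed``.

    ``connectivity`` 2 means 8-connected in-plane (the default), 1 means
    4-connected.  Deterministic for fixed input.
    """
    in_range = (bmd_slice >= low) & (bmd_slice <= high)
    if exclude is not None:
        in_range &= ~exclude
    r, c = seed
    if not (0 <= r < in_range.shape[0] and 0 <= c < in_range.shape[1]):
        raise SeedError(f"seed {seed} outside the image")
    if not in_range[r, c]:
        raise SeedError(f"seed {seed} outside the density window [{low}, {high}]")
    labels, _ = ndimage.label(in_range, structure=_EIGHT if connectivity == 2 else _FOUR)
    return labels == labels[r, c]


def pick_seeds(bmd_slice: np.ndarray, n: int = 3,
               low: float = 200.0, high: float = 2000.0,
               exclude: np.ndarray | None = None,
               min_separation: float = 3.0) -> list[tuple[int, int]]:
    """The ``n`` highest-density in-window pixels, mutually >= 3 px apart.

    Ties in density break by lexicographic (row, col) order.
    """
    in_range = (bmd_slice >= low) & (bmd_slice <= high)
    if exclude is not None:
        in_range &= ~exclude
    rows, cols = np.nonzero(in_range)
    if rows.size == 0:
        raise MeasurementError("no in-window pixel to seed from")
    vals = np.asarray(bmd_slice, dtype=float)[rows, cols]
    order = np.lexsort((cols, rows, -vals))
    seeds: list[tuple[int, int]] = []
    for i in order:
        cand = (int(rows[i]), int(cols[i]))
        if all((cand[0] - s[0]) ** 2 + (cand[1] - s[1]) ** 2 >= min_separation ** 2
               for s in seeds):
            seeds.append(cand)
            if len(seeds) == n:
                return seeds
    raise MeasurementError(
        f"only {len(seeds)} admissible seeds found (requested {n})")


def m2_slice_stats(mask: np.ndarray, bmd_slice: np.ndarray,
                   spacing: tuple[float, float, float],
                   seed: tuple[int, int] = (0, 0),
                   replicate: int = 0,
                   keep_mask: bool = False) -> SegmentationResult:
    """Density and volumetric statistics over one grown mask."""
    if not mask.any():
        raise MeasurementError("empty segmentation mask")
    vals = np.asarray(bmd_slice, dtype=float)[mask]
    dz, dy, dx = spacing
    area = vals.size * dy * dx
    return SegmentationResult(
        mean_bmd=float(vals.mean()), sd_bmd=float(vals.std(ddof=0)),
        min_bmd=float(vals.min()), max_bmd=float(vals.max()),
        n_pixels=int(vals.size), area_mm2=float(area),
        volume_mm3=float(area * dz), seed=seed, replicate=replicate,
        mask=mask if keep_mask else None)


def m2_slice_bmd(bmd_slice: np.ndarray, spacing: tuple[float, float, float],
                 low: float = 200.0, high: float = 2000.0,
                 n_replicates: int = 3,
                 exclude: np.ndarray | None = None,
                 keep_masks: bool = False) -> list[SegmentationResult]:
    """Run all replicates of M2 on one slice: seed, grow, summarize."""
    seeds = pick_seeds(bmd_slice, n=n_replicates, low=low, high=high,
                       exclude=exclude)
    out = []
    for rep, seed in enumerate(seeds, start=1):
        mask = grow_region(bmd_slice, seed, low=low, high=high, exclude=exclude)
        out.append(m2_slice_stats(mask, bmd_slice, spacing, seed=seed,
                                  replicate=rep, keep_mask=keep_masks))
    return out
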