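"""Phantom-based HU -> BMD calibration.

The scanner reports Hounsfield units; absolute bone mineral density in
mgHA/cm3 is obtained from the in-field hydroxyapatite phantom.  The standard
two-point equation anchors the line on the water-equivalent (0 mgHA/cm3) and
bone-reference (200 mgHA/cm3) cylinders:

    BMD = 200 * HU_t / (HU_b - HU_w)

where HU_t is the tissue radiodensity, HU_b the mean HU of the 200 cylinder
and HU_w that of the 0 cylinder.  Note the equation as written does not
subtract HU_w from HU_t, so for HU_w != 0 the line does not pass through the
water point; this verbatim form is the default, and ``water_correct=True``
selects the interpolating variant 200 * (HU_t - HU_w) / (HU_b - HU_w).  A
least-squares mode fits density on HU over all cylinders instead.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .errors import CalibrationError, GeometryError
from .synthetic_ct import CtVolume, PhantomLayout

__all__ = ["PhantomReading", "CalibrationModel", "BmdMap",
           "read_phantom", "fit_calibration", "hu_to_bmd"]


@dataclass(frozen=True)
class PhantomReading:
    """Per-cylinder mean HU over a circular ROI, pooled across phantom slices."""

    mean_hu: Mapping[float, float]   # concentration -> mean HU
    n_pixels: Mapping[float, int]    # concentration -> pooled pixel count
    water_concentration: float = 0.0
    bone_concentration: float = 200.0

    @property
    def hu_water(self) -> float:
        return self.mean_hu[self.water_concentration]

    @property
    def hu_bone(self) -> float:
        return self.mean_hu[self.bone_concentration]


@dataclass(frozen=True)
class CalibrationModel:
    """Affine map density(HU) = slope * HU + intercept."""

    slope: float
    intercept: float
    mode: str = "two_point"
    water_correct: bool = False
    reading: PhantomReading | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"calibration slope must be > 0, got {self.slope}")

    def bmd(self, hu):
        return self.slope * np.asarray(hu, dtype=float) + self.intercept


@dataclass(frozen=True)
class BmdMap:
    """Calibrated per-voxel density volume in mgHA/cm3."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    model: CalibrationModel | None = None

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]


def read_phantom(volume: CtVolume, layout: PhantomLayout,
                 roi_radius_fraction: float = 0.7) -> PhantomReading:
    """Mean HU of each cylinder over a centred circular ROI.

    The ROI radius is ``roi_radius_fraction`` of the cylinder radius
    (default 0.7) so edge voxels affected by partial volume are excluded;
    means are pooled over every slice where the phantom is present.
    """
    if not 0 < roi_radius_fraction <= 1:
        raise ValueError("roi_radius_fraction must lie in (0, 1]")
    nz, nr, nc = volume.shape
    layout.check_inside((nr, nc))
    zs = list(layout.slices(nz))
    if not zs:
        raise GeometryError("phantom slice range does not intersect the volume")
    rr, cc = np.mgrid[0:nr, 0:nc]
    mean_hu: dict[float, float] = {}
    n_pixels: dict[float, int] = {}
    for cyl in layout.cylinders:
        r = roi_radius_fraction * cyl.radius_px
        roi = (rr - cyl.center_row) ** 2 + (cc - cyl.center_col) ** 2 <= r * r
        n = int(roi.sum())
        if n == 0:
            raise GeometryError("phantom ROI contains no pixels; radius too small")
        vals = volume.voxels[zs][:, roi].astype(np.float64)
        mean_hu[cyl.concentration] = float(vals.mean())
        n_pixels[cyl.concentration] = n * len(zs)
    return PhantomReading(mean_hu=mean_hu, n_pixels=n_pixels)


def fit_calibration(reading: PhantomReading, mode: str = "two_point",
                    water_correct: bool = False) -> CalibrationModel:
    """Fit the HU -> density line from a phantom reading.

    ``two_point`` reproduces the reference equation exactly:
    slope = 200 / (HU_b - HU_w), intercept 0 (or -slope * HU_w when
    ``water_correct`` is set).  ``least_squares`` fits density = slope * HU +
    intercept by OLS over all cylinders.
    """
    if mode == "two_point":
        hub, huw = reading.hu_bone, reading.hu_water
        if hub <= huw:
            raise CalibrationError(
                f"degenerate phantom: HU_bone ({hub:.2f}) <= HU_water ({huw:.2f})")
        slope = reading.bone_concentration / (hub - huw)
        intercept = -slope * huw if water_correct else 0.0
        return CalibrationModel(slope, intercept, mode="two_point",
                                water_correct=water_correct, reading=reading)
    if mode == "least_squares":
        concs = sorted(reading.mean_hu)
        if len(concs) < 2:
            raise CalibrationError("least_squares needs at least two cylinders")
        hu = np.array([reading.mean_hu[c] for c in concs], dtype=float)
        dens = np.array(concs, dtype=float)
        if np.ptp(hu) == 0:
            raise CalibrationError("identical cylinder HUs: singular fit")
        slope, intercept = np.polyfit(hu, dens, 1)
        return CalibrationModel(float(slope), float(intercept),
                                mode="least_squares", reading=reading)
    raise ValueError(f"unknown calibration mode {mode!r}")


def hu_to_bmd(volume: CtVolume, model: CalibrationModel) -> BmdMap:
    """Voxelwise affine conversion of a HU volume to a BMD map."""
    vox = model.slope * volume.voxels.astype(np.float64) + model.intercept
    return BmdMap(voxels=vox, spacing=volume.spacing, model=model)
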