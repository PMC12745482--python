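"""Synthetic QCT volumes of laying-hen tibiae with a known ground truth.

This module builds CT-like image stacks that emulate the acquisition used in
ex-vivo tibial densitometry of laying hens: transverse 1 mm slices of an
excised tibia, a three-cylinder hydroxyapatite calibration phantom (0 / 100 /
200 mgHA/cm3) placed ventrally to the bone, a dense cortical shell with
azimuthal and radial density structure, lower-density medullary bone filling
the marrow cavity, Gaussian HU noise and an optional partial-volume blur.

Every generated volume carries a :class:`GroundTruth` with the exact per-voxel
density and the bone/cortical/medullary masks, so the downstream measurement
methods can be validated against a known answer.  A linear trait model
produces a correlated bone / eggshell trait table (weight, volume, mineral
matter, Seedor index, shell weight / thickness / breaking strength) whose
association signs with true density mirror those seen in laying hens: denser
bones are heavier and larger, while hens with higher skeletal mineral
reserves lay lighter, thinner, weaker shells.

The scanner forward model is deliberately simple and exactly invertible:
``HU = hu_slope * density + hu_intercept`` on bone and phantom voxels, with a
soft-tissue background and air outside the body.  With the default slope of
1 HU per mgHA/cm3 and zero offset the two-point phantom calibration recovers
ground-truth density exactly, which anchors the round-trip tests; both
coefficients are configurable so miscalibration can be injected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import GeometryError

__all__ = [
    "CtVolume",
    "PhantomCylinder",
    "PhantomLayout",
    "GroundTruth",
    "CohortSpec",
    "TraitCoefficients",
    "TraitModel",
    "TRAIT_ORDER",
    "default_phantom_layout",
    "make_phantom_slice",
    "make_tibia_volume",
    "make_cohort",
    "iter_cohort",
    "simulate_traits",
    "noise_sd_for_target_r2",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CtVolume:
    """A 3-D grid of Hounsfield units.

    Axis order is fixed as (slice, row, column); slice 0 is the proximal end
    of the bone.  ``spacing`` is (dz, dy, dx) in mm; the default acquisition
    uses 1 mm slice thickness at 1 mm intervals.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 0.25, 0.25)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if v.ndim != 3 or v.size == 0:
            raise GeometryError("voxel grid must be a non-empty 3-D array")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise GeometryError(f"spacing must be strictly positive, got {self.spacing}")
        object.__setattr__(self, "voxels", v)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape


@dataclass(frozen=True)
class PhantomCylinder:
    """One reference cylinder: pixel-space center, pixel radius, and the
    known hydroxyapatite concentration in mgHA/cm3."""

    center_row: float
    center_col: float
    radius_px: float
    concentration: float


@dataclass(frozen=True)
class PhantomLayout:
    """Positions and concentrations of the in-field calibration cylinders.

    ``slice_range`` is a half-open (start, stop) range of slices where the
    phantom is present; ``None`` means every slice.
    """

    cylinders: tuple[PhantomCylinder, ...]
    slice_range: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        concs = [c.concentration for c in self.cylinders]
        if any(c < 0 for c in concs):
            raise GeometryError("phantom concentrations must be non-negative")
        if len(set(concs)) != len(concs):
            raise GeometryError("exactly one cylinder per concentration is required")
        for i, a in enumerate(self.cylinders):
            for b in self.cylinders[i + 1:]:
                d = math.hypot(a.center_row - b.center_row, a.center_col - b.center_col)
                if d <= a.radius_px + b.radius_px:
                    raise GeometryError("phantom cylinders overlap")

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(sorted(c.concentration for c in self.cylinders))

    def slices(self, n_slices: int) -> range:
        if self.slice_range is None:
            return range(n_slices)
        lo, hi = self.slice_range
        return range(max(lo, 0), min(hi, n_slices))

    def check_inside(self, shape_rc: tuple[int, int]) -> None:
        nr, nc = shape_rc
        for c in self.cylinders:
            if (c.center_row - c.radius_px < 0 or c.center_row + c.radius_px > nr - 1
                    or c.center_col - c.radius_px < 0 or c.center_col + c.radius_px > nc - 1):
                raise GeometryError(
                    f"cylinder at ({c.center_row}, {c.center_col}) r={c.radius_px} "
                    f"extends outside a {nr}x{nc} image")

    def mask(self, shape_rc: tuple[int, int], margin_px: float = 0.0) -> np.ndarray:
        """Boolean in-plane mask covering all cylinders (+ optional margin)."""
        rr, cc = np.mgrid[0:shape_rc[0], 0:shape_rc[1]]
        m = np.zeros(shape_rc, dtype=bool)
        for cyl in self.cylinders:
            r = cyl.radius_px + margin_px
            m |= (rr - cyl.center_row) ** 2 + (cc - cyl.center_col) ** 2 <= r * r
        return m


def default_phantom_layout(shape_rc: tuple[int, int] = (128, 128),
                           concentrations: Sequence[float] = (0.0, 100.0, 200.0),
                           ) -> PhantomLayout:
    """Three cylinders in a row, ventral to the bone (ventral = larger row)."""
    nr, nc = shape_rc
    row = 0.82 * (nr - 1)
    radius = 0.07 * nc
    cols = np.linspace(0.25, 0.75, len(concentrations)) * (nc - 1)
    cyls = tuple(PhantomCylinder(row, float(c), float(radius), float(k))
                 for c, k in zip(cols, concentrations))
    return PhantomLayout(cyls)


@dataclass(frozen=True)
class GroundTruth:
    """Exact density field and tissue masks for one synthetic bone."""

    density: np.ndarray        # mgHA/cm3, zero outside bone/phantom
    bone_mask: np.ndarray
    cortical_mask: np.ndarray
    medullary_mask: np.ndarray
    mean_bmd: float            # mean density over bone_mask
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.cortical_mask & self.medullary_mask).any():
            raise GeometryError("cortical and medullary masks overlap")
        if ((self.cortical_mask | self.medullary_mask) & ~self.bone_mask).any():
            raise GeometryError("compartment masks leak outside the bone mask")


@dataclass(frozen=True)
class CohortSpec:
    """Generator settings for one cohort of synthetic tibiae.

    Density parameters are in mgHA/cm3.  ``cortical_density_sd`` and
    ``medullary_density_sd`` are *between-bone* standard deviations; within a
    bone the cortex is modulated azimuthally (sinusoidal, random per-bone
    amplitude and phase) and radially (denser periosteal side), which gives
    the quadrant-ROI method a genuinely inhomogeneous target.
    """

    n_bones: int = 48
    shape_rc: tuple[int, int] = (128, 128)
    spacing: tuple[float, float, float] = (1.0, 0.25, 0.25)
    bone_length_mm: float = 110.0
    bone_center_rc: tuple[float, float] = (48.0, 64.0)
    outer_semiaxes_mm: tuple[float, float] = (4.2, 3.4)   # (row, col)
    cortical_thickness_mm: float = 1.3
    cortical_density_mean: float = 900.0
    cortical_density_sd: float = 80.0
    azimuthal_amp_mean: float = 0.12
    azimuthal_amp_sd: float = 0.05
    radial_gradient_amp: float = 0.08
    medullary_density_mean: float = 300.0
    medullary_density_sd: float = 30.0
    medullary_extent_sd: float = 0.08
    region_multipliers: tuple[float, float, float] = (0.972, 1.028, 1.000)
    soft_tissue_hu: float = 40.0
    air_hu: float = -1000.0
    hu_noise_sd: float = 15.0
    blur_sigma_px: float = 0.6
    hu_slope: float = 1.0
    hu_intercept: float = 0.0
    phantom_layout: PhantomLayout | None = None

    def __post_init__(self) -> None:
        if self.n_bones < 1:
            raise ValueError("n_bones must be >= 1")
        for name in ("cortical_density_sd", "medullary_density_sd", "hu_noise_sd",
                     "azimuthal_amp_sd", "medullary_extent_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cortical_density_mean <= self.medullary_density_mean:
            raise ValueError("cortical density mean must exceed medullary mean")

    @property
    def n_slices(self) -> int:
        return max(1, round(self.bone_length_mm / self.spacing[0]))

    @property
    def layout(self) -> PhantomLayout:
        if self.phantom_layout is not None:
            return self.phantom_layout
        return default_phantom_layout(self.shape_rc)


# ---------------------------------------------------------------------------
# trait model
# ---------------------------------------------------------------------------

TRAIT_ORDER = (
    "bone_weight_g",
    "bone_length_mm",
    "bone_volume_cm3",
    "mineral_g",
    "mineral_pct",
    "seedor_mg_per_mm",
    "eggshell_weight_g",
    "eggshell_thickness_mm",
    "eggshell_strength_n",
)


@dataclass(frozen=True)
class TraitCoefficients:
    """Linear model of one trait: trait = intercept + slope * true_BMD + N(0, resid_sd)."""

    intercept: float
    slope: float
    resid_sd: float

    def __post_init__(self) -> None:
        if self.resid_sd < 0:
            raise ValueError("residual SD must be >= 0")


def noise_sd_for_target_r2(slope: float, var_d: float, target_r2: float) -> float:
    """Residual SD giving a population R^2 of ``target_r2`` for trait ~ BMD.

    With trait = a + b*D + eps and Var(D) = var_d, the population R^2 is
    b^2 var_d / (b^2 var_d + s^2); solving for s gives
    s = |b| * sqrt(var_d * (1 - R^2) / R^2).
    """
    if not 0 < target_r2 < 1:
        raise ValueError(f"target R^2 must lie in (0, 1), got {target_r2}")
    if var_d <= 0:
        raise ValueError("var_d must be > 0")
    return abs(slope) * math.sqrt(var_d * (1.0 - target_r2) / target_r2)


@dataclass(frozen=True)
class TraitModel:
    """Per-trait linear coefficients on true whole-bone BMD."""

    coefficients: Mapping[str, TraitCoefficients]

    @classmethod
    def default(cls, bmd_mean: float = 650.0, bmd_sd: float = 46.0) -> "TraitModel":
        """Defaults centred on a 48-week Dekalb White cohort.

        Slopes carry the field-observed signs (heavier, larger bones are
        denser; better-mineralised skeletons go with lighter / thinner /
        weaker shells; length, mineral %, and the Seedor index are nearly
        uninformative).  Residual SDs are set from target population R^2
        values via :func:`noise_sd_for_target_r2` at the stated BMD spread.
        """
        var_d = bmd_sd ** 2

        def tc(mean: float, slope: float, r2: float | None, sd: float | None = None
               ) -> TraitCoefficients:
            resid = sd if sd is not None else noise_sd_for_target_r2(slope, var_d, r2)
            return TraitCoefficients(mean - slope * bmd_mean, slope, resid)

        return cls({
            "bone_weight_g": tc(9.0, 0.010, 0.79),
            "bone_length_mm": tc(117.0, 0.0, None, sd=3.0),
            "bone_volume_cm3": tc(7.5, 0.008, 0.54),
            "mineral_g": tc(4.1, -0.004, 0.72),
            "mineral_pct": tc(55.0, 0.0, None, sd=3.0),
            "seedor_mg_per_mm": tc(77.0, 0.0, None, sd=5.0),
            "eggshell_weight_g": tc(6.0, -0.005, 0.74),
            "eggshell_thickness_mm": tc(0.38, -0.0004, 0.62),
            "eggshell_strength_n": tc(38.0, -0.040, 0.65),
        })


def simulate_traits(model: TraitModel, true_bmd: Sequence[float],
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw one trait table for a cohort with true whole-bone BMD ``true_bmd``."""
    d = np.asarray(true_bmd, dtype=float)
    out = {"bone_id": np.arange(1, d.size + 1)}
    for name in TRAIT_ORDER:
        c = model.coefficients[name]
        eps = rng.normal(0.0, c.resid_sd, size=d.size) if c.resid_sd > 0 else 0.0
        out[name] = c.intercept + c.slope * d + eps
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# image synthesis
# ---------------------------------------------------------------------------

def make_phantom_slice(layout: PhantomLayout,
                       hu_per_concentration: Mapping[float, float],
                       shape_rc: tuple[int, int] = (128, 128),
                       noise_sd: float = 0.0,
                       background_hu: float = 40.0,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """One transverse image containing only phantom cylinders on soft tissue."""
    layout.check_inside(shape_rc)
    missing = [c.concentration for c in layout.cylinders
               if c.concentration not in hu_per_concentration]
    if missing:
        raise ValueError(f"no HU configured for concentrations {missing}")
    img = np.full(shape_rc, background_hu, dtype=float)
    rr, cc = np.mgrid[0:shape_rc[0], 0:shape_rc[1]]
    for cyl in layout.cylinders:
        inside = (rr - cyl.center_row) ** 2 + (cc - cyl.center_col) ** 2 <= cyl.radius_px ** 2
        img[inside] = hu_per_concentration[cyl.concentration]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        img = img + rng.normal(0.0, noise_sd, size=shape_rc)
    return img


def _region_multiplier_profile(n_slices: int,
                               multipliers: tuple[float, float, float]) -> np.ndarray:
    """Piecewise-constant density multiplier along the shaft: proximal,
    medial, distal thirds."""
    z = np.arange(n_slices)
    prof = np.full(n_slices, multipliers[2], dtype=float)
    prof[z < n_slices / 3] = multipliers[0]
    prof[(z >= n_slices / 3) & (z < 2 * n_slices / 3)] = multipliers[1]
    return prof


def make_tibia_volume(spec: CohortSpec, seed) -> tuple[CtVolume, GroundTruth]:
    """Generate one tibia-like volume plus its ground truth.

    The cross-section is an elliptic annulus (cortex) around a medullary
    core; cortical density is modulated azimuthally and radially; the whole
    slice density is scaled by a per-third regional multiplier so that the
    midshaft is densest (medial > distal > proximal).  The phantom cylinders
    are stamped into every slice of the configured range.
    """
    rng = np.random.default_rng(seed)
    nr, nc = spec.shape_rc
    dz, dy, dx = spec.spacing
    n_slices = spec.n_slices
    layout = spec.layout
    layout.check_inside(spec.shape_rc)

    # per-bone draws
    cort = rng.normal(spec.cortical_density_mean, spec.cortical_density_sd)
    med = rng.normal(spec.medullary_density_mean, spec.medullary_density_sd)
    med = float(np.clip(med, min(220.0, spec.medullary_density_mean),
                        cort - 1e-9))
    amp = float(np.clip(rng.normal(spec.azimuthal_amp_mean, spec.azimuthal_amp_sd),
                        0.0, 0.35))
    phase = rng.uniform(0.0, 2.0 * math.pi)
    extent = float(np.clip(rng.normal(1.0, spec.medullary_extent_sd), 0.6, 1.3))

    a_out, b_out = spec.outer_semiaxes_mm
    a_in = max(a_out - spec.cortical_thickness_mm * extent, 0.25 * a_out)
    b_in = max(b_out - spec.cortical_thickness_mm * extent, 0.25 * b_out)

    cr, ccol = spec.bone_center_rc
    if (cr - a_out / dy < 0 or cr + a_out / dy > nr - 1
            or ccol - b_out / dx < 0 or ccol + b_out / dx > nc - 1):
        raise GeometryError("bone cross-section exceeds the field of view")

    rr, cc = np.mgrid[0:nr, 0:nc]
    dr_mm = (rr - cr) * dy
    dc_mm = (cc - ccol) * dx
    rho_out = np.sqrt((dr_mm / a_out) ** 2 + (dc_mm / b_out) ** 2)
    rho_in = np.sqrt((dr_mm / a_in) ** 2 + (dc_mm / b_in) ** 2)
    medullary2d = rho_in <= 1.0
    cortical2d = (rho_out <= 1.0) & ~medullary2d
    bone2d = rho_out <= 1.0

    theta = np.arctan2(dr_mm, dc_mm)
    rho0 = 0.5 * (a_in / a_out + b_in / b_out)   # mean inner/outer ratio
    radial = np.clip(2.0 * (rho_out - (1.0 + rho0) / 2.0) / max(1.0 - rho0, 1e-6),
                     -1.0, 1.0)
    cort2d = cort * (1.0 + amp * np.cos(theta - phase)
                     + spec.radial_gradient_amp * radial)

    base2d = np.zeros((nr, nc), dtype=float)
    base2d[cortical2d] = cort2d[cortical2d]
    base2d[medullary2d] = med

    prof = _region_multiplier_profile(n_slices, spec.region_multipliers)
    density = (prof[:, None, None] * base2d[None, :, :]).astype(np.float32)

    # masks are constant along the shaft
    bone_mask = np.broadcast_to(bone2d, (n_slices, nr, nc)).copy()
    cortical_mask = np.broadcast_to(cortical2d, (n_slices, nr, nc)).copy()
    medullary_mask = np.broadcast_to(medullary2d, (n_slices, nr, nc)).copy()

    # body outline: soft tissue inside, air outside
    body = ((rr - (nr - 1) / 2.0) / (0.52 * nr)) ** 2 \
        + ((cc - (nc - 1) / 2.0) / (0.52 * nc)) ** 2 <= 1.0

    hu2d_bg = np.where(body, spec.soft_tissue_hu, spec.air_hu)
    hu = np.broadcast_to(hu2d_bg, (n_slices, nr, nc)).astype(np.float32).copy()
    hu[bone_mask] = (spec.hu_slope * density[bone_mask]
                     + spec.hu_intercept).astype(np.float32)

    # phantom cylinders
    phantom2d = np.zeros((nr, nc), dtype=np.float32)
    pmask2d = np.zeros((nr, nc), dtype=bool)
    for cyl in layout.cylinders:
        inside = (rr - cyl.center_row) ** 2 + (cc - cyl.center_col) ** 2 <= cyl.radius_px ** 2
        phantom2d[inside] = cyl.concentration
        pmask2d |= inside
    for z in layout.slices(n_slices):
        hu[z][pmask2d] = (spec.hu_slope * phantom2d[pmask2d] + spec.hu_intercept)
        density[z][pmask2d] = phantom2d[pmask2d]

    if spec.blur_sigma_px > 0:
        hu = ndimage.gaussian_filter(
            hu, sigma=(0.0, spec.blur_sigma_px, spec.blur_sigma_px))
    if spec.hu_noise_sd > 0:
        hu = hu + rng.normal(0.0, spec.hu_noise_sd, size=hu.shape).astype(np.float32)

    mean_bmd = float(density[bone_mask].astype(np.float64).mean())
    gt = GroundTruth(density=density, bone_mask=bone_mask,
                     cortical_mask=cortical_mask, medullary_mask=medullary_mask,
                     mean_bmd=mean_bmd,
                     params={"cortical_density": cort, "medullary_density": med,
                             "azimuthal_amp": amp, "azimuthal_phase": phase,
                             "medullary_extent": extent})
    return CtVolume(hu, spec.spacing), gt


def iter_cohort(spec: CohortSpec, seed: int = 0):
    """Yield (bone_id, CtVolume, GroundTruth) one bone at a time.

    Bones are generated from independent child seeds of ``seed`` so the
    cohort is reproducible while keeping only one volume in memory.
    """
    children = np.random.SeedSequence(seed).spawn(spec.n_bones)
    for i, child in enumerate(children, start=1):
        vol, gt = make_tibia_volume(spec, child)
        yield i, vol, gt


def make_cohort(spec: CohortSpec, trait_model: TraitModel | None = None,
                seed: int = 0):
    """Generate a full cohort: list of (CtVolume, GroundTruth) plus traits.

    The trait table is drawn from ``trait_model`` (default
    :meth:`TraitModel.default`) conditioned on each bone's true mean BMD.
    """
    if trait_model is None:
        trait_model = TraitModel.default()
    bones = []
    true_bmd = []
    for _, vol, gt in iter_cohort(spec, seed):
        bones.append((vol, gt))
        true_bmd.append(gt.mean_bmd)
    trait_rng = np.random.default_rng(np.random.SeedSequence([seed, 7_919]))
    traits = simulate_traits(trait_model, true_bmd, trait_rng)
    return bones, traits


def scaled_spec(n_bones: int = 4, **overrides) -> CohortSpec:
    """A reduced-size CohortSpec (64x64 in-plane, short shaft) for fast
    experiments and tests; density parameters match the defaults."""
    base = dict(
        n_bones=n_bones,
        shape_rc=(64, 64),
        bone_length_mm=36.0,
        bone_center_rc=(24.0, 32.0),
        outer_semiaxes_mm=(4.2, 3.4),
        phantom_layout=default_phantom_layout((64, 64)),
    )
    base.update(overrides)
    return CohortSpec(**base)
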