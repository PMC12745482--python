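"""End-to-end pipeline: simulate -> calibrate -> measure -> aggregate ->
agreement -> trait regressions.

Measurement protocol: three standardized diaphyseal levels per bone at 25%
(proximal), 50% (medial) and 75% (distal) of the slice count from the
proximal end; three replicates per level and method; a cohort of 48 bones
therefore yields 48 x 3 x 3 = 432 measurement records per method.
Aggregation follows the replicates -> region -> whole bone order: the
region value of a bone is the mean of its three replicates, the whole-bone
value the unweighted mean of its three region values.  Within-method
precision is the CV% across the three replicates of each (bone, region)
cell, averaged per method.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import AgreementReport, agreement_report, cv_percent, descriptive_table
from .calibration import fit_calibration, hu_to_bmd, read_phantom
from .errors import MeasurementError
from .method_m1 import M1Config, m1_slice_bmd
from .method_m2 import m2_slice_bmd
from .synthetic_ct import (CohortSpec, TraitModel, iter_cohort, simulate_traits)
from .traits import trait_screen

__all__ = ["PipelineConfig", "PipelineResult", "region_slice_indices",
           "measure_bone", "run_pipeline", "replicate_cv", "bone_summaries",
           "load_config"]

log = logging.getLogger(__name__)

REGIONS = ("proximal", "medial", "distal")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one reproducible synthetic run."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    trait_model: TraitModel = field(default_factory=TraitModel.default)
    seed: int = 1
    region_fractions: tuple[float, float, float] = (0.25, 0.50, 0.75)
    n_replicates: int = 3
    threshold_low: float = 200.0
    threshold_high: float = 2000.0
    threshold_space: str = "bmd"          # or "hu"
    calibration_mode: str = "two_point"   # or "least_squares"
    water_correct: bool = False
    roi_radius_px: int = 2
    homogeneity_limit: float = 0.15
    phantom_margin_px: float = 2.0
    volume_normalize: bool = True
    deming_lambda: float = 1.0

    @property
    def m1(self) -> M1Config:
        return M1Config(low=self.threshold_low, high=self.threshold_high,
                        roi_radius_px=self.roi_radius_px,
                        homogeneity_limit=self.homogeneity_limit)


def region_slice_indices(n_slices: int,
                         fractions=(0.25, 0.50, 0.75)) -> dict[str, int]:
    """Slice index per region: round(fraction * L), half-integers to the
    lower index, measured from the proximal end (slice 0)."""
    out = {}
    for name, f in zip(REGIONS, fractions):
        idx = int(np.ceil(f * n_slices - 0.5))       # round, ties down
        out[name] = min(max(idx, 0), n_slices - 1)
    return out


def measure_bone(bone_id: int, bmd_map, hu_map, config: PipelineConfig,
                 exclude: np.ndarray,
                 replicate_seed_base: int) -> tuple[list[dict], list[str]]:
    """All M1 and M2 records for one calibrated bone volume.

    Thresholding normally happens on the calibrated map; with
    ``threshold_space='hu'`` the window is applied to the raw HU volume
    instead while statistics stay on the BMD map.
    """
    records: list[dict] = []
    failures: list[str] = []
    idx = region_slice_indices(bmd_map.n_slices, config.region_fractions)
    for region, z in idx.items():
        bmd_sl = np.asarray(bmd_map.voxels[z], dtype=float)
        if config.threshold_space == "hu":
            # carve the window out of HU space, then measure calibrated values
            hu_sl = np.asarray(hu_map.voxels[z], dtype=float)
            window = (hu_sl >= config.threshold_low) & (hu_sl <= config.threshold_high)
            meas_sl = np.where(window, bmd_sl, config.threshold_low - 1e6)
        else:
            meas_sl = bmd_sl
        base = dict(bone_id=bone_id, region=region, slice_index=z)
        # M1: three jittered-replicate searches
        for rep in range(1, config.n_replicates + 1):
            try:
                rois, slice_bmd, _ = m1_slice_bmd(
                    meas_sl, config.m1, exclude=exclude,
                    replicate_seed=replicate_seed_base + 97 * rep,
                    replicate=rep)
            except MeasurementError as exc:
                failures.append(f"M1 bone {bone_id} {region} rep {rep}: {exc}")
                continue
            for q, roi in rois.items():
                records.append({**base, "method": "M1", "replicate": rep,
                                "quadrant": q, "roi_row": roi.center_row,
                                "roi_col": roi.center_col,
                                "roi_radius": roi.radius_px,
                                "mean_bmd": roi.mean_bmd, "sd_bmd": roi.sd_bmd,
                                "n_pixels": roi.n_pixels,
                                "slice_bmd": slice_bmd})
        # M2: three seeded region growings
        try:
            segs = m2_slice_bmd(meas_sl, bmd_map.spacing,
                                low=config.threshold_low,
                                high=config.threshold_high,
                                n_replicates=config.n_replicates,
                                exclude=exclude)
        except MeasurementError as exc:
            failures.append(f"M2 bone {bone_id} {region}: {exc}")
            segs = []
        for seg in segs:
            records.append({**base, "method": "M2", "replicate": seg.replicate,
                            "seed_row": seg.seed[0], "seed_col": seg.seed[1],
                            "mean_bmd": seg.mean_bmd, "sd_bmd": seg.sd_bmd,
                            "min_bmd": seg.min_bmd, "max_bmd": seg.max_bmd,
                            "n_pixels": seg.n_pixels, "area_mm2": seg.area_mm2,
                            "volume_mm3": seg.volume_mm3,
                            "slice_bmd": seg.mean_bmd})
    return records, failures


def _slice_level(measurements: pd.DataFrame) -> pd.DataFrame:
    """One row per (bone, method, region, replicate) with the slice BMD.

    M1 rows carry four quadrant ROIs per replicate whose ``slice_bmd`` is
    their common mean; M2 rows are already one per replicate.
    """
    return (measurements
            .groupby(["bone_id", "method", "region", "replicate"], sort=True,
                     as_index=False)["slice_bmd"].first()
            .rename(columns={"slice_bmd": "bmd"}))


def bone_summaries(measurements: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(region-level, whole-bone) summaries in the prescribed pooling order."""
    sl = _slice_level(measurements)
    region = (sl.groupby(["bone_id", "method", "region"], sort=True,
                         as_index=False)
              .agg(bmd=("bmd", "mean"),
                   replicate_cv_pct=("bmd", lambda v: cv_percent(v.to_numpy())
                                     if len(v) > 1 else 0.0),
                   n_replicates=("bmd", "size")))
    whole = (region.groupby(["bone_id", "method"], sort=True, as_index=False)
             .agg(bmd=("bmd", "mean"), n_regions=("region", "size")))
    return region, whole


def replicate_cv(measurements: pd.DataFrame) -> dict[str, float]:
    """Mean within-method replicate CV% per method (precision of the
    protocol), averaged over all (bone, region) cells."""
    region, _ = bone_summaries(measurements)
    good = region[region.n_replicates > 1]
    return {m: float(g["replicate_cv_pct"].mean())
            for m, g in good.groupby("method")}


@dataclass
class PipelineResult:
    measurements: pd.DataFrame
    region_summary: pd.DataFrame
    bone_summary: pd.DataFrame       # wide: bone_id, bmd_m1, bmd_m2
    descriptive: pd.DataFrame
    agreement: AgreementReport | None
    traits: pd.DataFrame
    trait_screen: pd.DataFrame
    replicate_cv: dict[str, float]
    manifest: dict


def run_pipeline(config: PipelineConfig = PipelineConfig(),
                 out_dir: str | Path | None = None) -> PipelineResult:
    """Run the full synthetic study and (optionally) write all result files."""
    spec = config.cohort
    layout = spec.layout
    exclude = layout.mask(spec.shape_rc, margin_px=config.phantom_margin_px)
    all_records: list[dict] = []
    failures: list[str] = []
    true_bmd: list[float] = []
    rep_seed_root = np.random.SeedSequence([config.seed, 104_729])
    rep_seeds = rep_seed_root.generate_state(spec.n_bones) % (2 ** 31)
    for bone_id, vol, gt in iter_cohort(spec, config.seed):
        reading = read_phantom(vol, layout)
        model = fit_calibration(reading, mode=config.calibration_mode,
                                water_correct=config.water_correct)
        bmd_map = hu_to_bmd(vol, model)
        recs, fails = measure_bone(bone_id, bmd_map, vol, config, exclude,
                                   int(rep_seeds[bone_id - 1]))
        all_records.extend(recs)
        failures.extend(fails)
        true_bmd.append(gt.mean_bmd)
        log.info("bone %d: %d records (%d failures)", bone_id, len(recs), len(fails))
    if not all_records:
        raise MeasurementError("no method produced any record")
    measurements = pd.DataFrame(all_records)
    region_summary, whole = bone_summaries(measurements)
    bone_summary = (whole.pivot(index="bone_id", columns="method", values="bmd")
                    .rename(columns=lambda m: f"bmd_{m.lower()}")
                    .reset_index())
    descriptive = descriptive_table(region_summary)
    report = None
    if {"bmd_m1", "bmd_m2"} <= set(bone_summary.columns):
        paired = bone_summary.dropna(subset=["bmd_m1", "bmd_m2"])
        if len(paired) >= 3:
            report = agreement_report(paired["bmd_m1"].to_numpy(),
                                      paired["bmd_m2"].to_numpy(),
                                      lam=config.deming_lambda)
    trait_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7_919]))
    traits = simulate_traits(config.trait_model, true_bmd, trait_rng)
    # both BMD scales are emitted, labeled; config.volume_normalize picks
    # which one leads the output
    if len(bone_summary) >= 3:
        screens = [trait_screen(traits, bone_summary, normalize_by_volume=flag)
                   for flag in (config.volume_normalize, not config.volume_normalize)]
        screen = pd.concat(screens, ignore_index=True)
    else:
        log.warning("fewer than 3 bones: trait screen skipped")
        screen = pd.DataFrame(columns=["trait", "method", "slope", "intercept",
                                       "r", "r2", "signed_r2", "p", "n",
                                       "p_bh", "bmd_scale"])
    cvs = replicate_cv(measurements)
    manifest = {
        "tool": "tibiaqct", "version": __version__, "seed": config.seed,
        "n_bones": spec.n_bones, "n_records": {
            m: int((measurements.method == m).sum())
            for m in sorted(measurements.method.unique())},
        "n_measurements": {
            m: int(len(g.drop_duplicates(["bone_id", "region", "replicate"])))
            for m, g in measurements.groupby("method")},
        "failures": failures, "replicate_cv_pct": cvs,
        "config": _config_dict(config),
    }
    result = PipelineResult(measurements=measurements,
                            region_summary=region_summary,
                            bone_summary=bone_summary, descriptive=descriptive,
                            agreement=report, traits=traits,
                            trait_screen=screen, replicate_cv=cvs,
                            manifest=manifest)
    if out_dir is not None:
        _write_results(result, Path(out_dir))
    return result


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"].pop("phantom_layout", None)
    d["trait_model"] = {k: dataclasses.asdict(v)
                        for k, v in config.trait_model.coefficients.items()}
    return d


def _write_results(result: PipelineResult, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    result.measurements.to_csv(out_dir / "measurements.csv", index=False)
    result.region_summary.to_csv(out_dir / "region_summary.csv", index=False)
    result.bone_summary.to_csv(out_dir / "bone_summary.csv", index=False)
    result.descriptive.to_csv(out_dir / "descriptive.csv", index=False)
    result.traits.to_csv(out_dir / "traits.csv", index=False)
    result.trait_screen.to_csv(out_dir / "trait_screen.csv", index=False)
    if result.agreement is not None:
        with open(out_dir / "agreement.json", "w") as fh:
            json.dump(result.agreement.to_dict(), fh, indent=2)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)


# ---------------------------------------------------------------------------
# TOML configuration
# ---------------------------------------------------------------------------

def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a TOML file.

    Recognized sections: ``[cohort]`` (CohortSpec fields), ``[pipeline]``
    (PipelineConfig scalar fields), ``[traits.<name>]`` with intercept /
    slope / resid_sd.
    """
    import tomllib

    from .synthetic_ct import TraitCoefficients

    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    cohort_kw = raw.get("cohort", {})
    for key in ("shape_rc", "spacing", "bone_center_rc", "outer_semiaxes_mm",
                "region_multipliers"):
        if key in cohort_kw:
            cohort_kw[key] = tuple(cohort_kw[key])
    spec = CohortSpec(**cohort_kw)
    if "traits" in raw:
        model = TraitModel({name: TraitCoefficients(**coef)
                            for name, coef in raw["traits"].items()})
    else:
        model = TraitModel.default()
    pipe_kw = raw.get("pipeline", {})
    if "region_fractions" in pipe_kw:
        pipe_kw["region_fractions"] = tuple(pipe_kw["region_fractions"])
    return PipelineConfig(cohort=spec, trait_model=model, **pipe_kw)
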