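"""Volume and mask I/O: NIfTI (nibabel) and DICOM series (pydicom).

Arrays use the toolkit's (slice, row, column) axis order; NIfTI files are
written with that order and an affine of diag(dz, dy, dx, 1), i.e. the
first NIfTI axis is the slice axis.  Files written and read by this module
round-trip exactly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .calibration import BmdMap, CalibrationModel
from .errors import GeometryError
from .synthetic_ct import CtVolume

__all__ = ["save_volume_nifti", "load_volume_nifti", "save_mask_nifti",
           "load_mask_nifti", "read_dicom_series", "save_bmd_nifti",
           "calibration_to_json", "calibration_from_json"]


def _affine(spacing) -> np.ndarray:
    dz, dy, dx = spacing
    return np.diag([dz, dy, dx, 1.0])


def save_volume_nifti(volume: CtVolume, path: str | Path) -> None:
    import nibabel as nib
    img = nib.Nifti1Image(np.asarray(volume.voxels, dtype=np.float32),
                          _affine(volume.spacing))
    nib.save(img, str(path))


def load_volume_nifti(path: str | Path) -> CtVolume:
    import nibabel as nib
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return CtVolume(data, spacing)


def save_bmd_nifti(bmd: BmdMap, path: str | Path) -> None:
    import nibabel as nib
    img = nib.Nifti1Image(np.asarray(bmd.voxels, dtype=np.float32),
                          _affine(bmd.spacing))
    nib.save(img, str(path))


def save_mask_nifti(mask: np.ndarray, spacing, path: str | Path) -> None:
    import nibabel as nib
    img = nib.Nifti1Image(mask.astype(np.uint8), _affine(spacing))
    nib.save(img, str(path))


def load_mask_nifti(path: str | Path) -> np.ndarray:
    import nibabel as nib
    return np.asarray(nib.load(str(path)).dataobj) > 0


def read_dicom_series(directory: str | Path) -> CtVolume:
    """Load a single-series DICOM directory as a CtVolume.

    Slices are ordered by ImagePositionPatient along the scan axis (falling
    back to InstanceNumber) and rescaled to HU with RescaleSlope/Intercept.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm")) or sorted(Path(directory).iterdir())
    datasets = [pydicom.dcmread(str(f)) for f in files if f.is_file()]
    datasets = [d for d in datasets if hasattr(d, "pixel_array")]
    if not datasets:
        raise GeometryError(f"no DICOM images found in {directory}")

    def sort_key(d):
        pos = getattr(d, "ImagePositionPatient", None)
        return float(pos[2]) if pos is not None else float(getattr(d, "InstanceNumber", 0))

    datasets.sort(key=sort_key)
    slope = float(getattr(datasets[0], "RescaleSlope", 1.0))
    intercept = float(getattr(datasets[0], "RescaleIntercept", 0.0))
    vox = np.stack([d.pixel_array.astype(np.float32) * slope + intercept
                    for d in datasets])
    dy, dx = (float(v) for v in getattr(datasets[0], "PixelSpacing", [1.0, 1.0]))
    dz = float(getattr(datasets[0], "SliceThickness", 1.0))
    return CtVolume(vox, (dz, dy, dx))


def calibration_to_json(model: CalibrationModel, path: str | Path) -> None:
    import json
    payload = {"slope": model.slope, "intercept": model.intercept,
               "mode": model.mode, "water_correct": model.water_correct}
    if model.reading is not None:
        payload["reading"] = {str(k): v for k, v in model.reading.mean_hu.items()}
    Path(path).write_text(json.dumps(payload, indent=2))


def calibration_from_json(path: str | Path) -> CalibrationModel:
    import json
    d = json.loads(Path(path).read_text())
    return CalibrationModel(slope=d["slope"], intercept=d["intercept"],
                            mode=d.get("mode", "two_point"),
                            water_correct=d.get("water_correct", False))
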