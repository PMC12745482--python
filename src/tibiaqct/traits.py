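"""Bone / eggshell trait computations and the trait-vs-BMD regression screen.

Traits measured on the same tibiae (weight, length, volume, mineral matter,
Seedor index) and on eggs from the same hens (shell weight, thickness,
breaking strength) are screened against each method's whole-bone BMD with
simple linear regressions.  Results carry both the true coefficient of
determination R^2 and the reporting convention signed_R^2 =
sign(slope) * R^2, which encodes the direction of the association (a true
R^2 is never negative).

BMD is normalized by bone volume before the screen by default, which
removes gross size effects; the raw-BMD screen is available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .synthetic_ct import TRAIT_ORDER

__all__ = ["RegressionResult", "seedor_index", "normalize_bmd",
           "regress_trait", "trait_screen", "screen_matrix", "TRAIT_ORDER"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression of one trait on one method's BMD."""

    trait: str
    method: str
    slope: float
    intercept: float
    r: float
    r2: float
    signed_r2: float
    p: float
    n: int


def seedor_index(bone_weight, bone_length_mm, weight_unit: str = "mg"):
    """Seedor robustness index: bone weight (mg) / bone length (mm).

    ``weight_unit='g'`` converts gram inputs to mg first.
    """
    w = np.asarray(bone_weight, dtype=float)
    length = np.asarray(bone_length_mm, dtype=float)
    if np.any(length <= 0):
        raise ValueError("bone length must be > 0")
    if weight_unit == "g":
        w = w * 1000.0
    elif weight_unit != "mg":
        raise ValueError(f"unknown weight unit {weight_unit!r}")
    out = w / length
    return float(out) if out.ndim == 0 else out


def normalize_bmd(bmd, bone_volume_cm3):
    """BMD divided by bone volume, removing gross size effects."""
    vol = np.asarray(bone_volume_cm3, dtype=float)
    if np.any(vol <= 0):
        raise ValueError("bone volume must be > 0")
    out = np.asarray(bmd, dtype=float) / vol
    return float(out) if out.ndim == 0 else out


def regress_trait(trait_values, bmd_values, trait: str = "",
                  method: str = "") -> RegressionResult:
    """OLS of trait on BMD with signed-R^2 reporting."""
    t = np.asarray(trait_values, dtype=float)
    b = np.asarray(bmd_values, dtype=float)
    if t.size != b.size or t.size < 3:
        raise ValueError("need >= 3 paired values")
    if b.std() == 0:
        raise ValueError("zero variance in BMD")
    fit = stats.linregress(b, t)
    r2 = fit.rvalue ** 2
    return RegressionResult(trait=trait, method=method,
                            slope=float(fit.slope), intercept=float(fit.intercept),
                            r=float(fit.rvalue), r2=float(r2),
                            signed_r2=float(np.sign(fit.slope) * r2),
                            p=float(fit.pvalue), n=t.size)


def trait_screen(trait_table: pd.DataFrame, bmd_table: pd.DataFrame,
                 methods: tuple[str, ...] = ("M1", "M2"),
                 normalize_by_volume: bool = True,
                 volume_col: str = "bone_volume_cm3",
                 traits: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Regress every trait on every method's whole-bone BMD.

    ``bmd_table`` must hold one row per bone with columns ``bone_id`` and
    ``bmd_<method>`` (lower-case).  Bones missing from either table are
    logged and excluded pairwise.  The output is a long-format frame ordered
    trait-major, with a Benjamini-Hochberg column ``p_bh`` supplied as
    supplementary information only (the primary screen is unadjusted,
    alpha = 0.05).
    """
    traits = tuple(traits or [t for t in TRAIT_ORDER if t in trait_table.columns])
    merged = trait_table.merge(bmd_table, on="bone_id", how="inner")
    dropped = (set(trait_table.bone_id) | set(bmd_table.bone_id)) - set(merged.bone_id)
    if dropped:
        log.warning("excluding %d bone_ids missing from one table: %s",
                    len(dropped), sorted(dropped))
    rows = []
    for trait in traits:
        for method in methods:
            col = f"bmd_{method.lower()}"
            cols = [trait, col] + ([volume_col] if normalize_by_volume else [])
            sub = merged[list(dict.fromkeys(cols))].dropna()
            bmd = sub[col].to_numpy()
            if normalize_by_volume:
                bmd = normalize_bmd(bmd, sub[volume_col].to_numpy())
            res = regress_trait(sub[trait].to_numpy(), bmd, trait=trait,
                                method=method)
            rows.append(res.__dict__)
    out = pd.DataFrame(rows)
    out["p_bh"] = multipletests(out["p"], method="fdr_bh")[1]
    out["bmd_scale"] = "volume_normalized" if normalize_by_volume else "raw"
    out.attrs["normalized_by_volume"] = normalize_by_volume
    return out


def screen_matrix(screen: pd.DataFrame, value: str = "signed_r2") -> pd.DataFrame:
    """Heatmap-ready trait x method matrix of one screen column."""
    return screen.pivot(index="trait", columns="method", values=value
                        ).reindex([t for t in TRAIT_ORDER
                                   if t in screen["trait"].unique()])
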