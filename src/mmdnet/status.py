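"""Micronutrient-deficiency classification from a 24-month blood panel.

Four indicators are derived from plasma biomarkers: anemia (hemoglobin,
altitude-adjusted upstream where applicable), iron deficiency (depleted
ferritin together with elevated transferrin receptor), zinc deficiency
(plasma zinc), and vitamin-A deficiency (plasma retinol).  Multiple
micronutrient deficiency (MMD) is the co-existence of more than one of the
four, i.e. at least two indicators positive.

All rules use strict inequalities; a panel exactly at every cut-off is
classified non-deficient.  AGP is carried on the panel as an inflammation
covariate but plays no role in classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .profiles import RETINOL_UGDL_PER_UMOLL

__all__ = [
    "DeficiencyThresholds", "BloodPanel", "DeficiencyFlags",
    "IncompletePanelError", "classify_deficiencies", "classify_blood_table",
    "mmd_prevalence", "retinol_ugdl_to_umoll",
]


class IncompletePanelError(ValueError):
    """Raised when a blood panel with missing biomarkers reaches the
    classifier; callers must complete-case filter first."""


@dataclass(frozen=True)
class DeficiencyThresholds:
    """Classification cut-offs, in the units the assays report.

    Defaults: ferritin < 12.0 ug/L together with TfR > 8.3 mg/L defines
    iron deficiency; zinc < 9.9 umol/L; retinol < 0.70 umol/L;
    hemoglobin < 11.0 g/dL defines anemia.
    """

    ferritin_max: float = 12.0
    tfr_min: float = 8.3
    zinc_max: float = 9.9
    retinol_max: float = 0.70
    hemoglobin_max: float = 11.0

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ValueError(f"threshold {name} must be strictly positive")


@dataclass(frozen=True)
class BloodPanel:
    """One child's 24-month plasma panel (hemoglobin g/dL, ferritin ug/L,
    TfR mg/L, zinc umol/L, retinol umol/L, AGP g/L)."""

    hemoglobin: float
    ferritin: float
    tfr: float
    zinc: float
    retinol: float
    agp: float | None = None

    def is_complete(self) -> bool:
        required = (self.hemoglobin, self.ferritin, self.tfr, self.zinc, self.retinol)
        return all(v is not None and np.isfinite(v) for v in required)


@dataclass(frozen=True)
class DeficiencyFlags:
    anemia: bool
    iron_deficiency: bool
    zinc_deficiency: bool
    retinol_deficiency: bool

    @property
    def deficiency_count(self) -> int:
        return int(self.anemia) + int(self.iron_deficiency) \
            + int(self.zinc_deficiency) + int(self.retinol_deficiency)

    @property
    def mmd(self) -> bool:
        """Co-existence of more than one deficiency."""
        return self.deficiency_count >= 2


def classify_deficiencies(panel: BloodPanel,
                          thresholds: DeficiencyThresholds | None = None) -> DeficiencyFlags:
    """Apply the deficiency cut-offs to one complete blood panel."""
    thr = thresholds or DeficiencyThresholds()
    if not panel.is_complete():
        raise IncompletePanelError(
            "panel has missing biomarkers; apply a complete-case filter first")
    return DeficiencyFlags(
        anemia=panel.hemoglobin < thr.hemoglobin_max,
        iron_deficiency=(panel.ferritin < thr.ferritin_max) and (panel.tfr > thr.tfr_min),
        zinc_deficiency=panel.zinc < thr.zinc_max,
        retinol_deficiency=panel.retinol < thr.retinol_max,
    )


def classify_blood_table(blood: pd.DataFrame,
                         thresholds: DeficiencyThresholds | None = None,
                         columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Vectorized classification of a complete-case blood table.

    Expects columns hemoglobin, ferritin, tfr, zinc, retinol (one row per
    child); ``columns`` maps these logical names to differently named
    columns (e.g. ``{"zinc": "plasma_zinc"}``).  Returns a frame with the
    four flags, deficiency_count and mmd, preserving child_id / site
    columns when present.
    """
    thr = thresholds or DeficiencyThresholds()
    colmap = {name: name for name in ("hemoglobin", "ferritin", "tfr", "zinc", "retinol")}
    if columns:
        colmap.update(columns)
    required = list(colmap.values())
    if blood[required].isna().any().any():
        raise IncompletePanelError(
            "blood table has missing biomarkers; apply a complete-case filter first")
    out = pd.DataFrame(index=blood.index)
    for col in ("child_id", "site"):
        if col in blood.columns:
            out[col] = blood[col]
    out["anemia"] = blood[colmap["hemoglobin"]].to_numpy() < thr.hemoglobin_max
    out["iron_deficiency"] = (blood[colmap["ferritin"]].to_numpy() < thr.ferritin_max) \
        & (blood[colmap["tfr"]].to_numpy() > thr.tfr_min)
    out["zinc_deficiency"] = blood[colmap["zinc"]].to_numpy() < thr.zinc_max
    out["retinol_deficiency"] = blood[colmap["retinol"]].to_numpy() < thr.retinol_max
    out["deficiency_count"] = (
        out[["anemia", "iron_deficiency", "zinc_deficiency", "retinol_deficiency"]]
        .sum(axis=1).astype(int)
    )
    out["mmd"] = out["deficiency_count"] >= 2
    return out


def mmd_prevalence(flags: Iterable[DeficiencyFlags] | pd.DataFrame,
                   grouping: Iterable | None = None) -> tuple[dict, float]:
    """Per-group and pooled MMD fractions.

    ``flags`` is either a sequence of :class:`DeficiencyFlags` with a
    parallel ``grouping`` of site labels, or a classified table carrying an
    ``mmd`` column (and optionally ``site``).  Empty input is rejected;
    groups are returned as label -> fraction, with NaN for an empty group.
    """
    if isinstance(flags, pd.DataFrame):
        mmd = flags["mmd"].to_numpy(dtype=bool)
        labels = flags["site"].to_numpy() if grouping is None and "site" in flags \
            else (np.asarray(list(grouping)) if grouping is not None else None)
    else:
        mmd = np.array([f.mmd for f in flags], dtype=bool)
        labels = np.asarray(list(grouping)) if grouping is not None else None
    if mmd.size == 0:
        raise ValueError("no deficiency flags supplied")
    pooled = float(mmd.mean())
    per_group: dict = {}
    if labels is not None:
        if len(labels) != mmd.size:
            raise ValueError("grouping length does not match flags")
        for g in pd.unique(labels):
            sel = labels == g
            per_group[g] = float(mmd[sel].mean()) if sel.any() else float("nan")
    return per_group, pooled


def retinol_ugdl_to_umoll(value: float) -> float:
    """Convert plasma retinol from ug/dL to umol/L (molar mass 286.45 g/mol)."""
    arr = np.asarray(value, dtype=float)
    if np.any(arr <= 0):
        raise ValueError("retinol concentration must be strictly positive")
    result = arr / RETINOL_UGDL_PER_UMOLL
    return float(result) if np.isscalar(value) else result


def flags_to_frame(flags: Mapping | Iterable[DeficiencyFlags]) -> pd.DataFrame:
    """Utility: a list of DeficiencyFlags as a tidy boolean frame."""
    rows = [
        dict(anemia=f.anemia, iron_deficiency=f.iron_deficiency,
             zinc_deficiency=f.zinc_deficiency, retinol_deficiency=f.retinol_deficiency,
             deficiency_count=f.deficiency_count, mmd=f.mmd)
        for f in flags
    ]
    return pd.DataFrame(rows)
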