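"""Derivation of the one-row-per-child analysis table.

Longitudinal inputs (monthly 24-h-recall intakes, monthly stool biomarkers
and pathogen detections, morbidity surveillance) are collapsed to
child-level exposures over a 9-24-month window: natural-log window means
for biomarkers, arithmetic means for intakes, per-sample pathogen scores,
the percentage of days breastfed, and diarrheal incidence per 100
child-months.  A complete-case filter on the five outcome-defining blood
biomarkers produces the analytic sample, and within-site z-scores of the
continuous covariates are attached for modelling.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .profiles import INTAKE_NUTRIENTS, PATHOGEN_CLASSES, STOOL_BIOMARKERS
from .cohort import DAYS_PER_MONTH, RawCohort
from .status import classify_blood_table

__all__ = [
    "DEFAULT_WINDOW", "log_window_mean", "pathogen_score",
    "breastfeeding_pct", "complete_case_filter", "assemble_analysis_table",
    "STANDARDIZED_COLUMNS",
]

DEFAULT_WINDOW = (9, 24)

#: blood columns whose absence drops a child from the analytic sample
OUTCOME_BIOMARKERS = ("hemoglobin", "zinc", "retinol", "ferritin", "tfr")

#: in the joined analysis table plasma zinc is renamed to avoid colliding
#: with the dietary zinc intake column
ANALYSIS_BIOMARKERS = ("hemoglobin", "plasma_zinc", "retinol", "ferritin", "tfr")


def log_window_mean(months, values, window: tuple[int, int] = DEFAULT_WINDOW) -> float:
    """Mean of natural-log values inside the month window.

    Equals the log of the geometric mean of the in-window observations.
    Duplicated months are averaged (on the log scale) before the window
    mean so repeated collections cannot over-weight a month.  Returns NaN
    when the window holds no observation; raises on non-positive values.
    """
    months = np.asarray(months)
    values = np.asarray(values, dtype=float)
    lo, hi = window
    sel = (months >= lo) & (months <= hi)
    if not sel.any():
        return float("nan")
    v = values[sel]
    if np.any(v <= 0):
        raise ValueError("log_window_mean requires strictly positive values")
    logs = pd.Series(np.log(v)).groupby(pd.Series(months[sel])).mean()
    return float(logs.mean())


def pathogen_score(detections) -> float:
    """Total enteropathogen detections divided by stool samples tested.

    NaN (not zero) when no sample was tested.
    """
    d = np.asarray(detections, dtype=float)
    if d.size == 0:
        return float("nan")
    if np.any(d < 0):
        raise ValueError("detection counts must be non-negative")
    return float(d.sum() / d.size)


def breastfeeding_pct(days_breastfed, days_observed) -> float:
    """Percentage of observed days on which the child was breastfed."""
    if days_observed <= 0:
        return float("nan")
    if days_breastfed < 0 or days_breastfed > days_observed:
        raise ValueError("days_breastfed must lie in [0, days_observed]")
    return 100.0 * days_breastfed / days_observed


def complete_case_filter(table: pd.DataFrame,
                         required=OUTCOME_BIOMARKERS) -> tuple[pd.DataFrame, int]:
    """Drop rows missing any outcome-defining biomarker.

    Returns (retained table, dropped count); a child missing several
    markers is dropped (and counted) once.
    """
    present = [c for c in required if c in table.columns]
    keep = ~table[present].isna().any(axis=1)
    return table[keep].reset_index(drop=True), int((~keep).sum())


#: continuous covariates that receive within-site z-scored copies; intakes
#: and concentrations are standardized on the natural-log scale
_LOG_SCALE = set(INTAKE_NUTRIENTS) | {"income"}
_LINEAR_SCALE = (
    "log_mpo", "log_neo", "log_aat", "log_agp",
    "bacteria_score", "virus_score", "parasite_score",
    "diarrheal_incidence", "breastfed_pct",
    "maternal_schooling_years", "birth_weight",
)
STANDARDIZED_COLUMNS = tuple(sorted(_LOG_SCALE)) + _LINEAR_SCALE


def _attach_z_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Within-site z-scores (z_<name>) of the continuous covariates.

    Standardizing inside each site removes between-country level shifts,
    so model coefficients on these copies are within-country per-SD
    effects.  Log-normal quantities are standardized on the log scale.
    """
    out = table.copy()
    for col in STANDARDIZED_COLUMNS:
        if col not in out.columns:
            continue
        x = out[col].astype(float)
        if col in _LOG_SCALE:
            if (x <= 0).any():
                raise ValueError(f"non-positive values in log-scale column {col}")
            x = np.log(x)
        g = x.groupby(out["site"])
        mean, sd = g.transform("mean"), g.transform("std").replace(0.0, np.nan)
        z = ((x - mean) / sd).fillna(0.0)
        out[f"z_{col}"] = z
    return out


def assemble_analysis_table(raw: RawCohort,
                            window: tuple[int, int] = DEFAULT_WINDOW,
                            thresholds=None) -> tuple[pd.DataFrame, int]:
    """Join and derive the complete-case analysis table.

    Returns (table, dropped count).  One row per complete-case child with
    the derived exposures, within-site z-scored copies, the four
    deficiency flags and the MMD outcome.
    """
    child = raw.child_table
    if child["child_id"].duplicated().any():
        raise ValueError("duplicate child_id in child table")
    lo, hi = window

    diet = raw.diet_table
    diet_w = diet[(diet["month"] >= lo) & (diet["month"] <= hi)]
    intake_means = diet_w.groupby("child_id")[list(INTAKE_NUTRIENTS)].mean()

    stool = raw.stool_table
    stool_w = stool[(stool["month"] >= lo) & (stool["month"] <= hi)].copy()
    if (stool_w[list(STOOL_BIOMARKERS)] <= 0).any().any():
        raise ValueError("non-positive stool biomarker concentrations")
    logged = np.log(stool_w[list(STOOL_BIOMARKERS)])
    logged.columns = [f"log_{m}" for m in STOOL_BIOMARKERS]
    biomarker_logs = logged.groupby(stool_w["child_id"]).mean()
    det_cols = [f"{p}_detections" for p in PATHOGEN_CLASSES]
    g = stool_w.groupby("child_id")
    scores = g[det_cols].mean()
    scores.columns = [f"{p}_score" for p in PATHOGEN_CLASSES]
    # pooled score: all detections over the same sample denominator
    scores["pathogen_score"] = g[det_cols].sum().sum(axis=1) / g.size()

    morb = raw.morbidity_table.set_index("child_id")
    months_obs = morb["days_observed"] / DAYS_PER_MONTH
    derived_morb = pd.DataFrame({
        "breastfed_pct": 100.0 * morb["days_breastfed"] / morb["days_observed"],
        "diarrheal_incidence": 100.0 * morb["diarrheal_episodes"] / months_obs,
    })

    blood = raw.blood_table.set_index("child_id")
    blood = blood.rename(columns={"agp": "agp_24m", "zinc": "plasma_zinc"})
    blood["log_agp"] = np.log(blood["agp_24m"])

    table = (
        child.set_index("child_id")
        .join(intake_means, how="left")
        .join(biomarker_logs, how="left")
        .join(scores, how="left")
        .join(derived_morb, how="left")
        .join(blood, how="left")
        .reset_index()
    )
    table, dropped = complete_case_filter(table, required=ANALYSIS_BIOMARKERS)
    flags = classify_blood_table(table, thresholds, columns={"zinc": "plasma_zinc"})
    for col in ("anemia", "iron_deficiency", "zinc_deficiency",
                "retinol_deficiency", "deficiency_count", "mmd"):
        table[col] = flags[col].to_numpy()
    table["mmd"] = table["mmd"].astype(int)
    table = _attach_z_scores(table)
    return table, dropped
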