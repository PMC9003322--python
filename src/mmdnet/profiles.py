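"""Per-site calibration profiles for the seven-country cohort generator.

Each study site (Dhaka/BGD, Fortaleza/BRF, Vellore/INV, Bhaktapur/NPB,
Loreto/PEL, Naushero Feroze/PKN, Haydom/TZH) carries the marginal
distributions of dietary intakes, stool and plasma biomarkers, and the
cohort-accounting counts (enrolment, blood draws, missing biomarker values,
analytic sample) that the simulator reproduces.

Positive, right-skewed quantities (intakes, blood concentrations) are
modelled log-normally with parameters solved from the published median and
inter-quartile range; stool biomarkers are specified directly as mean +/- SD
on the natural-log scale; pathogen scores as mean +/- SD of per-sample
detection averages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import brentq

SITE_IDS = ("BGD", "BRF", "INV", "NPB", "PEL", "PKN", "TZH")

#: standard normal 75th percentile; IQR of a log-normal = exp(2 * z75 * sigma)
_Z75 = stats.norm.ppf(0.75)

#: retinol molar mass is 286.45 g/mol, so 28.645 ug/dL per umol/L
RETINOL_UGDL_PER_UMOLL = 28.645

INTAKE_NUTRIENTS = (
    "energy", "protein", "carbohydrate", "iron", "folate", "zinc",
    "thiamin", "niacin", "riboflavin", "vitamin_a", "vitamin_c",
    "vitamin_b6", "vitamin_b12",
)

STOOL_BIOMARKERS = ("mpo", "neo", "aat")

BLOOD_BIOMARKERS = ("hemoglobin", "zinc_plasma", "retinol", "ferritin", "tfr")

PATHOGEN_CLASSES = ("bacteria", "virus", "parasite")


def lognormal_from_median_iqr(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching a given median and quartiles."""
    if min(median, q1, q3) <= 0 or q3 <= q1:
        raise ValueError("median/quartiles must be positive with q3 > q1")
    mu = np.log(median)
    sigma = np.log(q3 / q1) / (2.0 * _Z75)
    return float(mu), float(sigma)


# ---------------------------------------------------------------------------
# Published per-site summaries used for calibration.
# Intakes: daily median [q1, q3] from complementary foods, months 9-24.
# Blood: 24-month concentrations, median [q1, q3].
# Retinol is printed in ug/dL and converted to umol/L downstream.
# ---------------------------------------------------------------------------

_SITE_TABLE: dict[str, dict] = {
    "BGD": dict(
        enrolled=265, blood_draw=177, analytic=174,
        missing=dict(hemoglobin=1, zinc_plasma=2, retinol=0, ferritin=0),
        female=86 / 174,
        birth_weight=(2.81, 0.41),
        intakes=dict(
            energy=(338, 272, 412), protein=(9.37, 7.83, 12.0),
            carbohydrate=(56.1, 45.0, 67.9), iron=(1.40, 1.09, 1.78),
            folate=(34.3, 28.8, 44.8), zinc=(1.13, 0.90, 1.42),
            thiamin=(0.18, 0.15, 0.23), niacin=(2.64, 2.08, 3.19),
            riboflavin=(0.20, 0.15, 0.30), vitamin_a=(52.8, 35.9, 77.4),
            vitamin_c=(10.1, 6.88, 16.2), vitamin_b6=(0.26, 0.20, 0.32),
            vitamin_b12=(0.37, 0.24, 0.60),
        ),
        stool_log=dict(mpo=(8.31, 0.41), neo=(6.87, 0.45), aat=(-0.95, 0.37)),
        blood=dict(
            hemoglobin=(11.9, 10.9, 12.7), zinc_plasma=(11.8, 10.9, 13.2),
            retinol_ugdl=(24.0, 19.9, 28.0), ferritin=(7.75, 4.70, 14.2),
        ),
        pathogens=dict(bacteria=(0.91, 0.25), parasite=(0.12, 0.10), virus=(0.08, 0.08)),
    ),
    "BRF": dict(
        enrolled=233, blood_draw=143, analytic=128,
        missing=dict(hemoglobin=0, zinc_plasma=15, retinol=0, ferritin=0),
        female=58 / 128,
        birth_weight=(3.36, 0.52),
        intakes=dict(
            energy=(987, 824, 1140), protein=(40.3, 34.3, 48.7),
            carbohydrate=(138, 113, 157), iron=(14.2, 11.3, 17.4),
            folate=(166, 133, 201), zinc=(9.05, 7.27, 11.0),
            thiamin=(0.77, 0.65, 0.95), niacin=(9.47, 7.51, 11.3),
            riboflavin=(1.52, 1.27, 1.87), vitamin_a=(955, 754, 1150),
            vitamin_c=(101, 77.2, 121), vitamin_b6=(1.03, 0.79, 1.51),
            vitamin_b12=(4.61, 3.96, 5.59),
        ),
        stool_log=dict(mpo=(7.83, 0.73), neo=(7.28, 0.38), aat=(-1.30, 0.49)),
        blood=dict(
            hemoglobin=(12.0, 10.6, 13.3), zinc_plasma=(13.6, 12.9, 15.4),
            retinol_ugdl=(30.7, 25.3, 35.8), ferritin=(25.3, 15.0, 36.4),
        ),
        pathogens=dict(bacteria=(1.05, 0.33), parasite=(0.14, 0.20), virus=(0.03, 0.06)),
    ),
    "INV": dict(
        enrolled=251, blood_draw=225, analytic=223,
        missing=dict(hemoglobin=0, zinc_plasma=1, retinol=0, ferritin=1),
        female=120 / 223,
        birth_weight=(2.89, 0.44),
        intakes=dict(
            energy=(739, 600, 894), protein=(20.7, 16.4, 26.8),
            carbohydrate=(112, 93.6, 133), iron=(2.38, 2.05, 2.95),
            folate=(82.0, 68.5, 101), zinc=(2.85, 2.24, 3.69),
            thiamin=(0.25, 0.20, 0.32), niacin=(2.66, 2.12, 3.22),
            riboflavin=(0.44, 0.29, 0.79), vitamin_a=(181, 116, 284),
            vitamin_c=(9.67, 7.92, 11.9), vitamin_b6=(0.27, 0.21, 0.34),
            vitamin_b12=(0.62, 0.39, 0.96),
        ),
        stool_log=dict(mpo=(8.86, 0.46), neo=(7.41, 0.37), aat=(-1.11, 0.37)),
        blood=dict(
            hemoglobin=(11.2, 10.2, 11.9), zinc_plasma=(8.50, 8.00, 9.20),
            retinol_ugdl=(29.2, 23.2, 36.1), ferritin=(8.60, 4.35, 19.7),
        ),
        pathogens=dict(bacteria=(0.79, 0.28), parasite=(0.21, 0.19), virus=(0.06, 0.06)),
    ),
    "NPB": dict(
        enrolled=240, blood_draw=116, analytic=115,
        missing=dict(hemoglobin=0, zinc_plasma=1, retinol=0, ferritin=0),
        female=51 / 115,
        birth_weight=(2.95, 0.40),
        intakes=dict(
            energy=(392, 328, 481), protein=(10.6, 8.09, 13.7),
            carbohydrate=(58.8, 49.4, 69.5), iron=(1.31, 1.06, 1.70),
            folate=(40.3, 32.8, 53.9), zinc=(1.28, 1.00, 1.71),
            thiamin=(0.16, 0.12, 0.22), niacin=(1.60, 1.25, 2.07),
            riboflavin=(0.25, 0.17, 0.37), vitamin_a=(83.9, 61.0, 114),
            vitamin_c=(7.28, 5.08, 10.0), vitamin_b6=(0.23, 0.19, 0.29),
            vitamin_b12=(0.51, 0.31, 0.84),
        ),
        stool_log=dict(mpo=(8.55, 0.47), neo=(7.47, 0.28), aat=(-0.76, 0.37)),
        blood=dict(
            hemoglobin=(11.3, 10.6, 11.7), zinc_plasma=(11.6, 10.1, 13.0),
            retinol_ugdl=(24.5, 19.9, 30.4), ferritin=(14.8, 7.10, 24.2),
        ),
        pathogens=dict(bacteria=(0.70, 0.22), parasite=(0.14, 0.16), virus=(0.06, 0.07)),
    ),
    "PEL": dict(
        enrolled=303, blood_draw=195, analytic=150,
        missing=dict(hemoglobin=0, zinc_plasma=44, retinol=0, ferritin=1),
        female=62 / 150,
        birth_weight=(3.13, 0.42),
        intakes=dict(
            energy=(728, 610, 876), protein=(19.5, 16.3, 22.6),
            carbohydrate=(126, 109, 154), iron=(3.77, 2.99, 4.80),
            folate=(57.8, 43.0, 71.7), zinc=(2.20, 1.87, 2.74),
            thiamin=(0.28, 0.23, 0.37), niacin=(3.96, 3.13, 4.60),
            riboflavin=(0.47, 0.35, 0.65), vitamin_a=(219, 148, 335),
            vitamin_c=(55.4, 28.5, 114), vitamin_b6=(0.37, 0.30, 0.45),
            vitamin_b12=(0.94, 0.68, 1.29),
        ),
        stool_log=dict(mpo=(8.83, 0.48), neo=(7.72, 0.37), aat=(-0.98, 0.42)),
        blood=dict(
            hemoglobin=(11.7, 11.0, 12.5), zinc_plasma=(14.2, 11.8, 16.7),
            retinol_ugdl=(22.8, 18.9, 28.9), ferritin=(25.9, 12.8, 37.3),
        ),
        pathogens=dict(bacteria=(0.56, 0.24), parasite=(0.32, 0.21), virus=(0.08, 0.07)),
    ),
    "PKN": dict(
        enrolled=277, blood_draw=222, analytic=151,
        missing=dict(hemoglobin=0, zinc_plasma=49, retinol=19, ferritin=3),
        female=73 / 151,
        birth_weight=(1.52, 1.46),
        intakes=dict(
            energy=(619, 470, 782), protein=(15.8, 11.9, 20.4),
            carbohydrate=(86.8, 69.6, 107), iron=(2.09, 1.69, 2.78),
            folate=(58.7, 47.0, 78.3), zinc=(1.94, 1.46, 2.54),
            thiamin=(0.41, 0.33, 0.52), niacin=(4.37, 3.43, 5.61),
            riboflavin=(0.49, 0.36, 0.74), vitamin_a=(150, 93.0, 220),
            vitamin_c=(11.6, 7.38, 17.9), vitamin_b6=(0.42, 0.32, 0.56),
            vitamin_b12=(0.68, 0.42, 1.21),
        ),
        stool_log=dict(mpo=(8.31, 0.55), neo=(6.14, 0.39), aat=(-1.78, 0.58)),
        blood=dict(
            hemoglobin=(9.80, 8.60, 10.7), zinc_plasma=(8.00, 6.00, 10.6),
            retinol_ugdl=(20.6, 16.5, 25.0), ferritin=(4.00, 2.00, 8.10),
        ),
        pathogens=dict(bacteria=(1.14, 0.31), parasite=(0.45, 0.23), virus=(0.07, 0.08)),
    ),
    "TZH": dict(
        enrolled=262, blood_draw=216, analytic=152,
        missing=dict(hemoglobin=8, zinc_plasma=54, retinol=1, ferritin=1),
        female=73 / 152,
        birth_weight=(3.27, 0.49),
        intakes=dict(
            energy=(994, 888, 1130), protein=(28.2, 24.6, 34.0),
            carbohydrate=(185, 163, 207), iron=(8.31, 7.23, 9.14),
            folate=(65.0, 56.2, 77.3), zinc=(5.25, 4.55, 6.03),
            thiamin=(0.56, 0.47, 0.63), niacin=(5.44, 4.63, 6.12),
            riboflavin=(0.97, 0.64, 1.34), vitamin_a=(136, 91.5, 184),
            vitamin_c=(5.84, 3.96, 7.89), vitamin_b6=(0.15, 0.11, 0.20),
            vitamin_b12=(1.18, 0.72, 1.75),
        ),
        stool_log=dict(mpo=(8.53, 0.41), neo=(6.62, 0.51), aat=(-1.46, 0.48)),
        blood=dict(
            hemoglobin=(11.4, 10.5, 12.2), zinc_plasma=(11.2, 10.0, 12.7),
            retinol_ugdl=(17.2, 13.8, 20.7), ferritin=(15.0, 7.70, 24.5),
        ),
        pathogens=dict(bacteria=(1.04, 0.31), parasite=(0.23, 0.18), virus=(0.09, 0.09)),
    ),
}

#: published MMD prevalences; the remaining sites are anchored to the
#: prevalence implied by their own biomarker marginals (see default_truth).
PUBLISHED_MMD_PREVALENCE = {"PKN": 0.901, "BRF": 0.063}
POOLED_MMD_PREVALENCE = 0.476

#: transferrin receptor is not tabulated; log-spread from a plausible
#: 5-10 mg/L inter-quartile range, per-site level tied to iron depletion
#: (ferritin) so that elevated TfR tracks low iron stores.
TFR_SIGMA = float(np.log(10.0 / 5.0) / (2.0 * _Z75))
TFR_THRESHOLD = 8.3  # mg/L, deficiency when above

#: AGP (systemic inflammation) is not tabulated; median 1.0 g/L, IQR 0.7-1.4
AGP_PARAMS = lognormal_from_median_iqr(1.0, 0.7, 1.4)

#: income (USD/month) and maternal schooling (years) are not tabulated;
#: plausible site levels spanning the seven economies.
_SES_DEFAULTS = {
    #        income med [q1,q3]        schooling mean, sd
    "BGD": ((150, 100, 220), (5.0, 3.5)),
    "BRF": ((350, 240, 520), (9.0, 3.0)),
    "INV": ((120, 80, 180), (6.0, 4.0)),
    "NPB": ((180, 120, 260), (6.5, 4.0)),
    "PEL": ((200, 140, 300), (8.0, 3.5)),
    "PKN": ((140, 95, 210), (2.5, 3.5)),
    "TZH": ((90, 60, 140), (4.5, 3.0)),
}

#: diarrheal episodes per 100 child-months, months 9-24 (site means)
_DIARRHEA_RATE = {
    "BGD": 28.0, "BRF": 12.0, "INV": 22.0, "NPB": 15.0,
    "PEL": 30.0, "PKN": 35.0, "TZH": 10.0,
}

#: percentage of days breastfed between 9 and 24 months (beta mean)
_BREASTFED_PCT = {
    "BGD": 92.0, "BRF": 45.0, "INV": 80.0, "NPB": 85.0,
    "PEL": 75.0, "PKN": 70.0, "TZH": 78.0,
}


@dataclass
class SiteProfile:
    """Marginal calibration and accounting for one study site."""

    site_id: str
    enrolled_n: int
    blood_draw_n: int
    analytic_n: int
    female_fraction: float
    birth_weight_mean: float
    birth_weight_sd: float
    intake_lognormal_params: dict[str, tuple[float, float]]
    stool_log_params: dict[str, tuple[float, float]]
    biomarker_lognormal_params: dict[str, tuple[float, float]]
    pathogen_params: dict[str, tuple[float, float]]
    missing_counts: dict[str, int]
    income_lognormal_params: tuple[float, float]
    schooling_params: tuple[float, float]
    diarrhea_rate: float
    breastfed_pct_mean: float
    target_mmd_prevalence: float = field(default=float("nan"))

    def __post_init__(self):
        if self.analytic_n <= 0:
            raise ValueError("analytic_n must be positive")
        if not 0.0 < self.female_fraction < 1.0:
            raise ValueError("female_fraction must be in (0, 1)")
        for name, (_, sigma) in {**self.intake_lognormal_params,
                                 **self.biomarker_lognormal_params}.items():
            if sigma <= 0:
                raise ValueError(f"non-positive log-spread for {name}")


def _tfr_params(ferritin_params: tuple[float, float]) -> tuple[float, float]:
    """TfR log-normal whose elevation probability equals the site's
    ferritin-depletion probability (iron-deficient populations run high TfR)."""
    mu_f, s_f = ferritin_params
    p_deplete = stats.norm.cdf((np.log(12.0) - mu_f) / s_f)
    p_deplete = float(np.clip(p_deplete, 0.02, 0.98))
    # P(TfR > 8.3) = p_deplete  =>  mu = ln(8.3) - sigma * Phi^-1(1 - p)
    mu = np.log(TFR_THRESHOLD) - TFR_SIGMA * stats.norm.ppf(1.0 - p_deplete)
    return float(mu), TFR_SIGMA


def build_site_profile(site_id: str) -> SiteProfile:
    """Assemble the calibrated profile for one site (prevalence target unset)."""
    try:
        row = _SITE_TABLE[site_id]
    except KeyError:
        raise KeyError(f"unknown site {site_id!r}; expected one of {SITE_IDS}") from None
    intake_params = {
        n: lognormal_from_median_iqr(*row["intakes"][n]) for n in INTAKE_NUTRIENTS
    }
    blood = row["blood"]
    ret_med, ret_q1, ret_q3 = blood["retinol_ugdl"]
    biomarker_params = {
        "hemoglobin": lognormal_from_median_iqr(*blood["hemoglobin"]),
        "zinc_plasma": lognormal_from_median_iqr(*blood["zinc_plasma"]),
        "retinol": lognormal_from_median_iqr(
            ret_med / RETINOL_UGDL_PER_UMOLL,
            ret_q1 / RETINOL_UGDL_PER_UMOLL,
            ret_q3 / RETINOL_UGDL_PER_UMOLL,
        ),
        "ferritin": lognormal_from_median_iqr(*blood["ferritin"]),
        "agp": AGP_PARAMS,
    }
    biomarker_params["tfr"] = _tfr_params(biomarker_params["ferritin"])
    income_spec, schooling_spec = _SES_DEFAULTS[site_id]
    return SiteProfile(
        site_id=site_id,
        enrolled_n=row["enrolled"],
        blood_draw_n=row["blood_draw"],
        analytic_n=row["analytic"],
        female_fraction=row["female"],
        birth_weight_mean=row["birth_weight"][0],
        birth_weight_sd=row["birth_weight"][1],
        intake_lognormal_params=intake_params,
        stool_log_params=dict(row["stool_log"]),
        biomarker_lognormal_params=biomarker_params,
        pathogen_params=dict(row["pathogens"]),
        missing_counts=dict(row["missing"]),
        income_lognormal_params=lognormal_from_median_iqr(*income_spec),
        schooling_params=schooling_spec,
        diarrhea_rate=_DIARRHEA_RATE[site_id],
        breastfed_pct_mean=_BREASTFED_PCT[site_id],
    )


# ---------------------------------------------------------------------------
# Latent-copula prevalence machinery.
#
# The four deficiency indicators (anemia, iron = low ferritin AND high TfR,
# low plasma zinc, low retinol) are driven by five latent normals sharing a
# single common factor with loading sqrt(rho).  Given the factor, indicators
# are independent, so P(>= 2 deficiencies) reduces to a one-dimensional
# Gauss-Hermite integral over the factor.
# ---------------------------------------------------------------------------

DEFAULT_COPULA_RHO = 0.3

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(61)
_GH_X = _GH_NODES * np.sqrt(2.0)          # factor values
_GH_W = _GH_WEIGHTS / np.sqrt(np.pi)      # N(0,1) weights


def shifted_biomarker_params(profile: SiteProfile,
                             log_shift: float) -> dict[str, tuple[float, float]]:
    """Biomarker log-normal parameters after a multiplicative calibration
    shift.

    A positive ``log_shift`` moves every deficiency-defining concentration
    toward deficiency by the same relative amount: the four "low is
    deficient" markers are multiplied by exp(-log_shift) and TfR (elevated
    when deficient) by exp(+log_shift).  AGP is untouched.
    """
    out = {}
    for marker, (mu, sigma) in profile.biomarker_lognormal_params.items():
        if marker == "agp":
            out[marker] = (mu, sigma)
        elif marker == "tfr":
            out[marker] = (mu + log_shift, sigma)
        else:
            out[marker] = (mu - log_shift, sigma)
    return out


def marker_crossing_probs(profile: SiteProfile, log_shift: float = 0.0,
                          thresholds=None) -> dict[str, float]:
    """Marginal probability that each blood marker crosses its deficiency
    threshold under the site's (optionally shifted) log-normal calibration."""
    from .status import DeficiencyThresholds

    thr = thresholds or DeficiencyThresholds()
    params = shifted_biomarker_params(profile, log_shift)
    out = {}
    specs = {
        "hemoglobin": (thr.hemoglobin_max, "below"),
        "zinc_plasma": (thr.zinc_max, "below"),
        "retinol": (thr.retinol_max, "below"),
        "ferritin": (thr.ferritin_max, "below"),
        "tfr": (thr.tfr_min, "above"),
    }
    for marker, (cut, side) in specs.items():
        mu, sigma = params[marker]
        z = (np.log(cut) - mu) / sigma
        p = stats.norm.cdf(z) if side == "below" else stats.norm.sf(z)
        out[marker] = float(p)
    return out


def mmd_probability(crossing_probs: dict[str, float],
                    rho: float = DEFAULT_COPULA_RHO) -> float:
    """P(at least two deficiencies) under the one-factor latent copula."""
    d = {m: stats.norm.ppf(1.0 - p) for m, p in crossing_probs.items()}
    lam = np.sqrt(rho)
    res = np.sqrt(1.0 - rho)
    q = {m: stats.norm.cdf((lam * _GH_X - dm) / res) for m, dm in d.items()}
    q_iron = q["ferritin"] * q["tfr"]
    comps = [q["hemoglobin"], q_iron, q["zinc_plasma"], q["retinol"]]
    p0 = np.ones_like(_GH_X)
    for c in comps:
        p0 = p0 * (1.0 - c)
    p1 = np.zeros_like(_GH_X)
    for i, c in enumerate(comps):
        term = c.copy()
        for j, other in enumerate(comps):
            if j != i:
                term = term * (1.0 - other)
        p1 += term
    return float(np.sum(_GH_W * (1.0 - p0 - p1)))


def site_mmd_probability(profile: SiteProfile, log_shift: float = 0.0,
                         rho: float = DEFAULT_COPULA_RHO, thresholds=None) -> float:
    """Copula MMD probability for a site under a calibration shift."""
    return mmd_probability(
        marker_crossing_probs(profile, log_shift, thresholds), rho=rho)


def solve_prevalence_shift(profile: SiteProfile, target: float,
                           rho: float = DEFAULT_COPULA_RHO, thresholds=None) -> float:
    """Multiplicative concentration shift (natural-log units) making the
    copula MMD probability hit the target prevalence."""
    if not 0.0 < target < 1.0:
        raise ValueError("target prevalence must be in (0, 1)")
    f = lambda s: site_mmd_probability(profile, s, rho, thresholds) - target
    return float(brentq(f, -1.5, 1.5, xtol=1e-10))
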