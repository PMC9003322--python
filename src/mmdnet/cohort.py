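"""Seeded synthetic multi-site cohort generator.

The generator emulates the data structure of a seven-country birth cohort
followed to 24 months: a child table (site, sex, birth weight, household
SES and WASH), a monthly diet table of 24-h-recall nutrient intakes over
months 9-24, a monthly stool table (per-class enteropathogen detections and
fecal biomarkers), a 24-month blood table, and a morbidity table.

Structure is planted through a small set of directed arcs acting on
within-site z-scores of the *derived* analysis variables, so a downstream
model that re-derives those variables can recover the planted coefficients.
The binary outcome (multiple micronutrient deficiency, MMD) is generated as
a Bernoulli-logit in its parents and then *realized* as blood-biomarker
values through a one-factor latent Gaussian copula conditioned on the MMD
state, so that threshold classification of the generated panel reproduces
the planted outcome exactly while the biomarker marginals stay at their
site calibration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .profiles import (
    DEFAULT_COPULA_RHO,
    INTAKE_NUTRIENTS,
    PATHOGEN_CLASSES,
    POOLED_MMD_PREVALENCE,
    PUBLISHED_MMD_PREVALENCE,
    SITE_IDS,
    STOOL_BIOMARKERS,
    SiteProfile,
    build_site_profile,
    shifted_biomarker_params,
    site_mmd_probability,
    solve_prevalence_shift,
)

__all__ = [
    "SimulationTruth", "RawCohort", "CohortConfigError",
    "DEFAULT_ARC_COEFFICIENTS", "default_truth", "generate_cohort",
    "apply_missingness",
]

#: follow-up window (months) for diet and stool collection
MONTHS = np.arange(9, 25)
N_MONTHS = len(MONTHS)

#: average month length in days, used for incidence denominators
DAYS_PER_MONTH = 30.44


class CohortConfigError(ValueError):
    """Invalid simulation configuration (unknown site, impossible counts)."""


# ---------------------------------------------------------------------------
# Planted structural coefficients.
#
# Arcs into the MMD node are on the log-odds scale (per SD of the
# standardized continuous parent, or female vs male for sex); all other
# arcs are linear effects per SD of the parent on the SD scale of the
# child node.  The three MMD arcs and the three arcs into fecal MPO carry
# the published point estimates; SES arcs to intakes and pathogen scores
# are plausible defaults of the stated sign.
# ---------------------------------------------------------------------------

DEFAULT_ARC_COEFFICIENTS: dict[tuple[str, str], float] = {
    ("female", "mmd"): float(np.log(0.72)),
    ("vitamin_c", "mmd"): float(np.log(0.70)),
    ("log_mpo", "mmd"): float(np.log(1.31)),
    ("protein", "log_mpo"): -0.47,
    ("bacteria_score", "log_mpo"): 0.08,
    ("diarrheal_incidence", "log_mpo"): -0.17,
    ("income", "zinc"): 0.15,
    ("income", "thiamin"): 0.15,
    ("income", "niacin"): 0.15,
    ("schooling", "protein"): 0.15,
    ("schooling", "iron"): 0.15,
    ("schooling", "zinc"): 0.15,
    ("schooling", "niacin"): 0.15,
    ("schooling", "riboflavin"): 0.15,
    ("schooling", "vitamin_a"): 0.15,
    ("crowding_high", "vitamin_c"): -0.15,
    ("crowding_high", "bacteria_score"): -0.10,
    ("income", "virus_score"): -0.10,
    ("schooling", "parasite_score"): -0.10,
}


@dataclass
class SimulationTruth:
    """Ground truth for one simulated study: site calibration profiles,
    planted arc coefficients, copula dependence, and observation noise."""

    site_profiles: dict[str, SiteProfile]
    arc_coefficients: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ARC_COEFFICIENTS))
    copula_rho: float = DEFAULT_COPULA_RHO
    monthly_intake_noise: float = 0.30   # natural-log SD of monthly recalls
    monthly_stool_noise: float = 0.25    # natural-log SD of monthly biomarkers
    seed: int = 0

    def __post_init__(self):
        for sid in self.site_profiles:
            if sid not in SITE_IDS:
                raise CohortConfigError(f"unknown site {sid!r}")
        if not 0.0 <= self.copula_rho < 1.0:
            raise CohortConfigError("copula_rho must be in [0, 1)")
        for sid, prof in self.site_profiles.items():
            missing_total = sum(prof.missing_counts.values())
            if prof.blood_draw_n - missing_total != prof.analytic_n:
                raise CohortConfigError(
                    f"{sid}: missing counts do not reconcile blood-draw and "
                    f"analytic totals")

    @property
    def missingness_counts(self) -> dict[str, dict[str, int]]:
        """biomarker -> site -> count of missing 24-month blood values."""
        out: dict[str, dict[str, int]] = {}
        for sid, prof in self.site_profiles.items():
            for marker, k in prof.missing_counts.items():
                out.setdefault(marker, {})[sid] = k
        return out

    def with_null_arcs(self) -> "SimulationTruth":
        """Copy with every structural coefficient set to zero."""
        return replace(self, arc_coefficients={k: 0.0 for k in self.arc_coefficients})

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        profs = {}
        for sid, p in self.site_profiles.items():
            profs[sid] = {
                "site_id": p.site_id,
                "enrolled_n": p.enrolled_n,
                "blood_draw_n": p.blood_draw_n,
                "analytic_n": p.analytic_n,
                "female_fraction": p.female_fraction,
                "birth_weight_mean": p.birth_weight_mean,
                "birth_weight_sd": p.birth_weight_sd,
                "intake_lognormal_params": {k: list(v) for k, v in p.intake_lognormal_params.items()},
                "stool_log_params": {k: list(v) for k, v in p.stool_log_params.items()},
                "biomarker_lognormal_params": {k: list(v) for k, v in p.biomarker_lognormal_params.items()},
                "pathogen_params": {k: list(v) for k, v in p.pathogen_params.items()},
                "missing_counts": dict(p.missing_counts),
                "income_lognormal_params": list(p.income_lognormal_params),
                "schooling_params": list(p.schooling_params),
                "diarrhea_rate": p.diarrhea_rate,
                "breastfed_pct_mean": p.breastfed_pct_mean,
                "target_mmd_prevalence": p.target_mmd_prevalence,
            }
        return {
            "site_profiles": profs,
            "arc_coefficients": {f"{s}->{t}": v for (s, t), v in self.arc_coefficients.items()},
            "copula_rho": self.copula_rho,
            "monthly_intake_noise": self.monthly_intake_noise,
            "monthly_stool_noise": self.monthly_stool_noise,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationTruth":
        profs = {}
        for sid, pd_ in d["site_profiles"].items():
            kwargs = dict(pd_)
            for key in ("intake_lognormal_params", "stool_log_params",
                        "biomarker_lognormal_params", "pathogen_params"):
                kwargs[key] = {k: tuple(v) for k, v in kwargs[key].items()}
            kwargs["income_lognormal_params"] = tuple(kwargs["income_lognormal_params"])
            kwargs["schooling_params"] = tuple(kwargs["schooling_params"])
            profs[sid] = SiteProfile(**kwargs)
        arcs = {tuple(k.split("->")): float(v) for k, v in d["arc_coefficients"].items()}
        return cls(
            site_profiles=profs,
            arc_coefficients=arcs,
            copula_rho=d.get("copula_rho", DEFAULT_COPULA_RHO),
            monthly_intake_noise=d.get("monthly_intake_noise", 0.30),
            monthly_stool_noise=d.get("monthly_stool_noise", 0.25),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "SimulationTruth":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "SimulationTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class RawCohort:
    """The five simulated tables, keyed by child_id."""

    child_table: pd.DataFrame
    diet_table: pd.DataFrame
    stool_table: pd.DataFrame
    blood_table: pd.DataFrame
    morbidity_table: pd.DataFrame

    TABLE_NAMES = ("child_table", "diet_table", "stool_table",
                   "blood_table", "morbidity_table")

    def to_csv_dir(self, directory) -> list[Path]:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for name in self.TABLE_NAMES:
            path = directory / f"{name}.csv"
            getattr(self, name).to_csv(path, index=False)
            written.append(path)
        return written

    @classmethod
    def from_csv_dir(cls, directory) -> "RawCohort":
        directory = Path(directory)
        return cls(**{
            name: pd.read_csv(directory / f"{name}.csv")
            for name in cls.TABLE_NAMES
        })


def default_truth(pooled_prevalence: float = POOLED_MMD_PREVALENCE,
                  seed: int = 0) -> SimulationTruth:
    """The default study conditions.

    Site profiles carry the published analytic sample sizes and marginal
    calibration; the two published site prevalences (PKN, BRF) are fixed,
    and the remaining five sites are anchored at the prevalence implied by
    their own biomarker marginals under a shared multiplicative shift
    solved so the size-weighted pooled prevalence equals the published
    overall figure.  Arc coefficients carry the published point estimates
    (see :data:`DEFAULT_ARC_COEFFICIENTS`).
    """
    profiles = {sid: build_site_profile(sid) for sid in SITE_IDS}
    fixed = dict(PUBLISHED_MMD_PREVALENCE)
    free_sites = [s for s in SITE_IDS if s not in fixed]
    n_total = sum(p.analytic_n for p in profiles.values())
    need = pooled_prevalence * n_total - sum(
        profiles[s].analytic_n * t for s, t in fixed.items())

    def gap(shift):
        return sum(profiles[s].analytic_n * site_mmd_probability(profiles[s], shift)
                   for s in free_sites) - need

    shared_shift = brentq(gap, -1.0, 1.0, xtol=1e-10)
    for sid, prof in profiles.items():
        prof.target_mmd_prevalence = (
            fixed[sid] if sid in fixed
            else float(site_mmd_probability(prof, shared_shift)))
    return SimulationTruth(site_profiles=profiles, seed=seed)


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------

def _z(x: np.ndarray) -> np.ndarray:
    """Within-array z-score with a degenerate-variance guard."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd < 1e-12:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _structural_core(predictors: list[tuple[np.ndarray, float]],
                     rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance structural score: planted linear predictor plus
    Gaussian residual scaled to keep total variance near one."""
    lp = np.zeros(n)
    for x, beta in predictors:
        lp = lp + beta * np.asarray(x, dtype=float)
    lp = lp - lp.mean()
    resid_var = max(1.0 - lp.var(), 0.2)
    return lp + np.sqrt(resid_var) * rng.standard_normal(n)


def _arcs_into(truth: SimulationTruth, target: str) -> dict[str, float]:
    return {s: b for (s, t), b in truth.arc_coefficients.items() if t == target}


def generate_cohort(truth: SimulationTruth, scale: float = 1.0,
                    seed: int = 0, attrition: bool = False) -> RawCohort:
    """Draw one cohort from the planted structural model.

    ``scale`` multiplies the per-site sample size (analytic totals by
    default; blood-draw totals when ``attrition=True``, for exercising the
    missingness bookkeeping).  Identical (truth, scale, seed, attrition)
    quadruples yield identical tables.
    """
    if not scale > 0:
        raise CohortConfigError("scale must be positive")
    rng = np.random.default_rng(int(seed))
    sites = sorted(truth.site_profiles)

    # ---- phase 1: child-level exogenous variables, all sites --------------
    child_frames = []
    for sid in sites:
        prof = truth.site_profiles[sid]
        base_n = prof.blood_draw_n if attrition else prof.analytic_n
        n = int(round(base_n * scale))
        mu_i, s_i = prof.income_lognormal_params
        m_s, sd_s = prof.schooling_params
        child_frames.append(pd.DataFrame({
            "child_id": [f"{sid}-{i:06d}" for i in range(n)],
            "site": sid,
            "female": (rng.random(n) < prof.female_fraction).astype(int),
            "birth_weight": np.clip(
                rng.normal(prof.birth_weight_mean, prof.birth_weight_sd, n), 0.3, None),
            "income": np.exp(rng.normal(mu_i, s_i, n)),
            "maternal_schooling_years": np.clip(rng.normal(m_s, sd_s, n), 0.0, 18.0),
            "persons_per_room": np.exp(rng.normal(np.log(2.5), 0.45, n)),
            "improved_water": (rng.random(n) < 0.65).astype(int),
            "improved_sanitation": (rng.random(n) < 0.55).astype(int),
        }))
    child_table = pd.concat(child_frames, ignore_index=True)
    # crowding index dichotomized at the pooled cohort median
    median_ppr = child_table["persons_per_room"].median()
    child_table["crowding_high"] = (child_table["persons_per_room"] > median_ppr).astype(int)

    diet_frames, stool_frames, blood_frames, morb_frames = [], [], [], []

    # ---- phase 2: endogenous variables, site by site ----------------------
    for sid in sites:
        prof = truth.site_profiles[sid]
        kids = child_table[child_table["site"] == sid]
        n = len(kids)
        ids = kids["child_id"].to_numpy()
        z_income = _z(np.log(kids["income"].to_numpy()))
        z_school = _z(kids["maternal_schooling_years"].to_numpy())
        crowd = kids["crowding_high"].to_numpy().astype(float)
        crowd_c = crowd - crowd.mean()
        female = kids["female"].to_numpy().astype(float)

        predictor_pool = {
            "income": z_income, "schooling": z_school, "crowding_high": crowd_c,
            "female": female - female.mean(),
        }

        # -- diet: monthly nutrient intakes --------------------------------
        tau = truth.monthly_intake_noise
        monthly = {}
        child_level_log = {}
        for nutrient in INTAKE_NUTRIENTS:
            mu_n, s_n = prof.intake_lognormal_params[nutrient]
            arcs = _arcs_into(truth, nutrient)
            preds = [(predictor_pool[src], b) for src, b in arcs.items()]
            core = _structural_core(preds, rng, n)
            level = mu_n + s_n * core
            child_level_log[nutrient] = level
            eps = rng.standard_normal((n, N_MONTHS))
            # -tau^2/2 keeps the mean of monthly intakes at exp(level)
            monthly[nutrient] = np.exp(level[:, None] + tau * eps - 0.5 * tau ** 2)
        diet = pd.DataFrame({
            "child_id": np.repeat(ids, N_MONTHS),
            "month": np.tile(MONTHS, n),
        })
        for nutrient in INTAKE_NUTRIENTS:
            diet[nutrient] = monthly[nutrient].ravel()
        diet_frames.append(diet)

        # -- stool: per-class pathogen detections ---------------------------
        detections = {}
        scores = {}
        for pclass in PATHOGEN_CLASSES:
            m, s = prof.pathogen_params[pclass]
            arcs = _arcs_into(truth, f"{pclass}_score")
            preds = [(predictor_pool[src], b) for src, b in arcs.items()]
            core = _structural_core(preds, rng, n)
            # child-level rate: log-normal around the site mean with a
            # coefficient of variation leaving room for Poisson noise in
            # the per-sample score (var(score) = var(rate) + mean/16)
            rate_var = max(s ** 2 - m / N_MONTHS, 1e-4)
            cv = np.sqrt(rate_var) / m
            lam = m * np.exp(cv * core - 0.5 * cv ** 2)
            counts = rng.poisson(lam[:, None], size=(n, N_MONTHS))
            detections[pclass] = counts
            scores[pclass] = counts.sum(axis=1) / N_MONTHS

        # -- morbidity -------------------------------------------------------
        days_obs = np.clip(rng.normal(456, 18, n).round(), 380, 487).astype(int)
        months_obs = days_obs / DAYS_PER_MONTH
        frailty = np.exp(0.4 * rng.standard_normal(n) - 0.08)
        episodes = rng.poisson(prof.diarrhea_rate / 100.0 * months_obs * frailty)
        diarrheal_incidence = episodes / months_obs * 100.0
        mean_pct = prof.breastfed_pct_mean / 100.0
        conc = 12.0
        bf_frac = rng.beta(mean_pct * conc, (1 - mean_pct) * conc, n)
        days_bf = np.minimum((bf_frac * days_obs).round().astype(int), days_obs)
        morb_frames.append(pd.DataFrame({
            "child_id": ids,
            "diarrheal_episodes": episodes,
            "days_breastfed": days_bf,
            "days_observed": days_obs,
        }))

        # -- stool biomarkers (monthly, natural-log scale levels) -----------
        tau_s = truth.monthly_stool_noise
        z_protein = _z(np.log(monthly["protein"].mean(axis=1)))
        z_bact = _z(scores["bacteria"])
        z_diarr = _z(diarrheal_incidence)
        biomarker_monthly = {}
        derived_log = {}
        stool_preds = {
            "protein": z_protein, "bacteria_score": z_bact,
            "diarrheal_incidence": z_diarr, **predictor_pool,
        }
        for marker in STOOL_BIOMARKERS:
            m_b, s_b = prof.stool_log_params[marker]
            arcs = _arcs_into(truth, f"log_{marker}")
            preds = [(stool_preds[src], b) for src, b in arcs.items()]
            core = _structural_core(preds, rng, n)
            level = m_b + s_b * core
            vals = level[:, None] + tau_s * rng.standard_normal((n, N_MONTHS))
            biomarker_monthly[marker] = np.exp(vals)
            derived_log[marker] = vals.mean(axis=1)
        stool = pd.DataFrame({
            "child_id": np.repeat(ids, N_MONTHS),
            "month": np.tile(MONTHS, n),
            "bacteria_detections": detections["bacteria"].ravel(),
            "virus_detections": detections["virus"].ravel(),
            "parasite_detections": detections["parasite"].ravel(),
            "mpo": biomarker_monthly["mpo"].ravel(),
            "neo": biomarker_monthly["neo"].ravel(),
            "aat": biomarker_monthly["aat"].ravel(),
        })
        stool_frames.append(stool)

        # -- outcome and blood panel ----------------------------------------
        mmd_arcs = _arcs_into(truth, "mmd")
        mmd_preds = {
            "female": female,
            "vitamin_c": _z(np.log(monthly["vitamin_c"].mean(axis=1))),
            "log_mpo": _z(derived_log["mpo"]),
        }
        eta = np.zeros(n)
        for src, b in mmd_arcs.items():
            if src not in mmd_preds:
                raise CohortConfigError(
                    f"unsupported MMD parent {src!r} in truth arcs")
            eta = eta + b * mmd_preds[src]
        target = prof.target_mmd_prevalence
        if not 0.0 < target < 1.0:
            raise CohortConfigError(f"{sid}: target_mmd_prevalence not set")

        def _prev_gap(alpha, eta=eta, target=target):
            return np.mean(1.0 / (1.0 + np.exp(-(alpha + eta)))) - target

        alpha = brentq(_prev_gap, -12.0, 12.0, xtol=1e-10)
        p_mmd = 1.0 / (1.0 + np.exp(-(alpha + eta)))
        mmd = rng.random(n) < p_mmd

        blood_frames.append(_draw_blood_panel(prof, truth, mmd, rng))
        blood_frames[-1].insert(0, "child_id", ids)

    blood_table = pd.concat(blood_frames, ignore_index=True)
    cohort = RawCohort(
        child_table=child_table,
        diet_table=pd.concat(diet_frames, ignore_index=True),
        stool_table=pd.concat(stool_frames, ignore_index=True),
        blood_table=blood_table,
        morbidity_table=pd.concat(morb_frames, ignore_index=True),
    )
    return cohort


def _draw_blood_panel(prof: SiteProfile, truth: SimulationTruth,
                      mmd: np.ndarray, rng: np.random.Generator) -> pd.DataFrame:
    """Blood biomarkers consistent with the planted MMD state.

    Latent deficiency propensities follow a one-factor Gaussian copula;
    panels are rejection-sampled so that threshold classification yields
    at least two deficiencies exactly for MMD children and at most one
    otherwise.  Because the per-site copula probability of >= 2 crossings
    is calibrated to the site's MMD target, the marginal distribution of
    each biomarker stays at its (shifted) site calibration.
    """
    from .status import DeficiencyThresholds

    thr = DeficiencyThresholds()
    n = mmd.size
    rho = truth.copula_rho
    target = prof.target_mmd_prevalence
    log_shift = solve_prevalence_shift(prof, target, rho=rho)
    params = shifted_biomarker_params(prof, log_shift)

    # deficiency-direction thresholds d_m: crossing iff latent V_m > d_m
    d = {}
    cuts = {
        "hemoglobin": thr.hemoglobin_max, "zinc_plasma": thr.zinc_max,
        "retinol": thr.retinol_max, "ferritin": thr.ferritin_max,
        "tfr": thr.tfr_min,
    }
    for marker, cut in cuts.items():
        mu, sigma = params[marker]
        if marker == "tfr":
            d[marker] = (np.log(cut) - mu) / sigma
        else:
            d[marker] = (mu - np.log(cut)) / sigma

    markers = list(cuts)
    lam, res = np.sqrt(rho), np.sqrt(1.0 - rho)
    V = np.empty((n, len(markers)))
    pending = np.ones(n, dtype=bool)
    for _ in range(10_000):
        k = int(pending.sum())
        if k == 0:
            break
        u = rng.standard_normal(k)
        eps = rng.standard_normal((k, len(markers)))
        v = lam * u[:, None] + res * eps
        crossed = {m: v[:, j] > d[m] for j, m in enumerate(markers)}
        count = (crossed["hemoglobin"].astype(int)
                 + (crossed["ferritin"] & crossed["tfr"]).astype(int)
                 + crossed["zinc_plasma"].astype(int)
                 + crossed["retinol"].astype(int))
        ok = (count >= 2) == mmd[pending]
        idx = np.flatnonzero(pending)
        V[idx[ok]] = v[ok]
        pending[idx[ok]] = False
    else:  # pragma: no cover - astronomically unlikely under valid calibration
        raise RuntimeError("copula rejection sampling failed to converge")

    panel = {}
    for j, marker in enumerate(markers):
        mu, sigma = params[marker]
        sign = 1.0 if marker == "tfr" else -1.0
        panel[marker] = np.exp(mu + sign * sigma * V[:, j])
    mu_a, s_a = prof.biomarker_lognormal_params["agp"]
    return pd.DataFrame({
        "hemoglobin": panel["hemoglobin"],
        "ferritin": panel["ferritin"],
        "tfr": panel["tfr"],
        "zinc": panel["zinc_plasma"],
        "retinol": panel["retinol"],
        "agp": np.exp(rng.normal(mu_a, s_a, n)),
    })


def apply_missingness(blood_table: pd.DataFrame, truth: SimulationTruth,
                      seed: int = 0, scale: float | None = None) -> pd.DataFrame:
    """Set the configured number of blood values per biomarker per site to
    missing, drawing disjoint child sets (a child loses at most one marker).

    Counts come from the truth's site profiles, multiplied by ``scale``;
    when ``scale`` is None it is inferred per site as the ratio of the
    table's row count to the profile's blood-draw total, so a scale-k
    cohort receives k times the configured missingness.  Missingness is
    completely at random within site.
    """
    if "child_id" not in blood_table.columns:
        raise CohortConfigError("blood table must carry child_id")
    rng = np.random.default_rng(int(seed))
    out = blood_table.copy()
    site_of = out["child_id"].str.slice(0, 3)
    column_of = {"hemoglobin": "hemoglobin", "zinc_plasma": "zinc",
                 "retinol": "retinol", "ferritin": "ferritin"}
    for sid in sorted(truth.site_profiles):
        prof = truth.site_profiles[sid]
        rows = np.flatnonzero((site_of == sid).to_numpy())
        if rows.size == 0:
            continue
        ratio = scale if scale is not None else rows.size / prof.blood_draw_n
        counts = {m: int(round(k * ratio)) for m, k in prof.missing_counts.items()}
        total = sum(counts.values())
        if total > rows.size:
            raise CohortConfigError(
                f"{sid}: missing counts ({total}) exceed available rows ({rows.size})")
        chosen = rng.permutation(rows)[:total]
        offset = 0
        for marker in ("hemoglobin", "zinc_plasma", "retinol", "ferritin"):
            k = counts.get(marker, 0)
            idx = chosen[offset:offset + k]
            out.iloc[idx, out.columns.get_loc(column_of[marker])] = np.nan
            offset += k
    return out
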