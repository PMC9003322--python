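"""Pipeline orchestration and paper-shaped reporting.

Chains simulate -> derive -> screen -> fit-network as a configured, logged
run with row-count reconciliation, a file manifest with checksums, and
deterministic seeding: a single global seed is fanned out to each
stochastic stage through a counter-based seed sequence, so partial
re-runs of a stage reproduce its output exactly.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import RawCohort, SimulationTruth, apply_missingness, default_truth, generate_cohort
from .exposures import DEFAULT_WINDOW, assemble_analysis_table
from .glmm import ScreenConfig, bivariate_screen, collinearity_filter, fit_logistic_random_intercept
from .network import (EdgeSummary, SamplerSettings, default_network,
                      fit_network, select_arcs)
from .profiles import INTAKE_NUTRIENTS

__all__ = ["PipelineConfig", "RunReport", "run_pipeline",
           "make_descriptives", "make_edge_report", "stage_seed"]

_STAGES = ("simulate", "derive", "screen", "fit_bn", "report")

#: covariates entering the bivariate screen by default
DEFAULT_SCREEN_CANDIDATES = (
    "female", "z_birth_weight", "z_income", "z_maternal_schooling_years",
    "crowding_high", "improved_water", "improved_sanitation",
    "z_energy", "z_protein", "z_iron", "z_zinc", "z_vitamin_a", "z_vitamin_c",
    "z_bacteria_score", "z_virus_score", "z_parasite_score",
    "z_diarrheal_incidence", "z_breastfed_pct",
    "z_log_mpo", "z_log_neo", "z_log_aat", "z_log_agp",
)


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31 from the global seed."""
    idx = _STAGES.index(stage)
    ss = np.random.SeedSequence(int(global_seed), spawn_key=(idx,))
    return int(ss.generate_state(1, np.uint32)[0] % (2 ** 31))


@dataclass
class PipelineConfig:
    stages: tuple[str, ...] = _STAGES
    truth_path: str | None = None           # YAML/JSON truth; default_truth() if None
    scale: float = 1.0
    attrition: bool = True                  # simulate blood-draw totals + missingness
    window: tuple[int, int] = DEFAULT_WINDOW
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    sampler: SamplerSettings = field(default_factory=SamplerSettings)
    seed: int = 0
    out_dir: str = "mmdnet_run"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("truth_path", "scale", "attrition", "seed", "out_dir"):
            if key in raw:
                kwargs[key] = raw[key]
        if "stages" in raw:
            kwargs["stages"] = tuple(raw["stages"])
        if "window" in raw:
            kwargs["window"] = tuple(raw["window"])
        if "screen" in raw:
            kwargs["screen"] = ScreenConfig(**raw["screen"])
        if "sampler" in raw:
            kwargs["sampler"] = SamplerSettings(**raw["sampler"])
        return cls(**kwargs)


@dataclass
class RunReport:
    row_counts: dict[str, int] = field(default_factory=dict)
    dropped_counts: dict[str, int] = field(default_factory=dict)
    convergence: dict[str, bool] = field(default_factory=dict)
    manifest: dict[str, str] = field(default_factory=dict)   # path -> sha256
    wall_clock: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, sort_keys=True))


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the enabled stages in order, writing all artifacts and the
    run report under ``config.out_dir``.  Re-running an identical config
    reproduces identical files (checksums included)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)

    truth = (SimulationTruth.from_yaml(config.truth_path)
             if config.truth_path else default_truth())
    cohort: RawCohort | None = None
    table: pd.DataFrame | None = None

    def record(path: Path):
        report.manifest[str(path)] = _checksum(path)

    try:
        if "simulate" in config.stages:
            t0 = time.perf_counter()
            cohort = generate_cohort(truth, config.scale,
                                     stage_seed(config.seed, "simulate"),
                                     attrition=config.attrition)
            if config.attrition:
                cohort.blood_table = apply_missingness(
                    cohort.blood_table, truth, stage_seed(config.seed, "simulate") + 1)
            for path in cohort.to_csv_dir(out / "cohort"):
                record(path)
            truth_path = out / "truth.yaml"
            truth.to_yaml(truth_path)
            record(truth_path)
            report.row_counts["simulate.children"] = len(cohort.child_table)
            report.wall_clock["simulate"] = time.perf_counter() - t0

        if "derive" in config.stages:
            t0 = time.perf_counter()
            if cohort is None:
                cohort = RawCohort.from_csv_dir(out / "cohort")
            table, dropped = assemble_analysis_table(cohort, config.window)
            path = out / "analysis_table.csv"
            table.to_csv(path, index=False)
            record(path)
            report.row_counts["derive.analysis_rows"] = len(table)
            report.dropped_counts["derive.incomplete_blood"] = dropped
            if "simulate.children" in report.row_counts:
                assert len(table) + dropped == report.row_counts["simulate.children"]
            report.wall_clock["derive"] = time.perf_counter() - t0

        if "screen" in config.stages:
            t0 = time.perf_counter()
            if table is None:
                table = pd.read_csv(out / "analysis_table.csv")
            candidates = [c for c in DEFAULT_SCREEN_CANDIDATES if c in table.columns]
            retained, ledger = bivariate_screen(table, candidates, config.screen)
            kept, flagged, vifs = collinearity_filter(table, retained, config.screen)
            adjusted = fit_logistic_random_intercept(
                table["mmd"], table[kept], table["site"], config.screen) \
                if kept else None
            screen_report = {
                "candidates": candidates,
                "retained_bivariate": retained,
                "kept_after_collinearity": kept,
                "p_value_ledger": ledger.to_dict(orient="records"),
                "flagged_pairs": flagged.to_dict(orient="records"),
                "vif": {k: (None if not np.isfinite(v) else v)
                        for k, v in vifs.items()},
                "adjusted_fit": None if adjusted is None else {
                    "odds_ratios": {k: list(v) for k, v in adjusted.odds_ratios.items()},
                    "random_intercept_variance": adjusted.random_intercept_variance,
                    "converged": adjusted.converged,
                },
            }
            path = out / "screen_report.json"
            path.write_text(json.dumps(screen_report, indent=1))
            record(path)
            report.convergence["screen.adjusted"] = (
                bool(adjusted.converged) if adjusted else False)
            report.wall_clock["screen"] = time.perf_counter() - t0

        if "fit_bn" in config.stages:
            t0 = time.perf_counter()
            if table is None:
                table = pd.read_csv(out / "analysis_table.csv")
            spec = default_network()
            settings = SamplerSettings(
                chains=config.sampler.chains,
                iterations=config.sampler.iterations,
                warmup=config.sampler.warmup,
                seed=stage_seed(config.seed, "fit_bn"))
            posterior = fit_network(spec, table, settings)
            edges = select_arcs(posterior, spec)
            edge_frame = pd.DataFrame([e.to_row() for e in edges])
            path = out / "edge_summaries.csv"
            edge_frame.to_csv(path, index=False)
            record(path)
            spec_path = out / "network.json"
            spec_path.write_text(json.dumps(spec.to_dict(), indent=1))
            record(spec_path)
            report.convergence["fit_bn"] = posterior.converged
            report.row_counts["fit_bn.arcs"] = len(edges)
            report.row_counts["fit_bn.retained"] = sum(e.retained for e in edges)
            report.wall_clock["fit_bn"] = time.perf_counter() - t0
        else:
            edges = None

        if "report" in config.stages:
            t0 = time.perf_counter()
            if table is None:
                table = pd.read_csv(out / "analysis_table.csv")
            if edges is None:
                frame = pd.read_csv(out / "edge_summaries.csv")
                edges = [EdgeSummary(
                    arc=(r.source, r.target), scale=r.scale, median=r.median,
                    ci_low=r.ci_low, ci_high=r.ci_high, retained=bool(r.retained),
                    ess=r.ess, unstable=bool(r.unstable),
                    odds_ratio=None if pd.isna(r.odds_ratio) else r.odds_ratio,
                    or_ci_low=None if pd.isna(r.or_ci_low) else r.or_ci_low,
                    or_ci_high=None if pd.isna(r.or_ci_high) else r.or_ci_high,
                ) for r in frame.itertuples()]
            desc = make_descriptives(table)
            dpath = out / "descriptives.csv"
            desc.to_csv(dpath)
            record(dpath)
            retained_frame, dot = make_edge_report(edges)
            epath = out / "retained_edges.csv"
            retained_frame.to_csv(epath, index=False)
            record(epath)
            gpath = out / "network.dot"
            gpath.write_text(dot)
            record(gpath)
            prev = table.groupby("site")["mmd"].mean().to_dict()
            prev["overall"] = float(table["mmd"].mean())
            ppath = out / "mmd_prevalence.json"
            ppath.write_text(json.dumps(prev, indent=1, sort_keys=True))
            record(ppath)
            report.wall_clock["report"] = time.perf_counter() - t0
    finally:
        report.to_json(out / "run_report.json")
    return report


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

_MEDIAN_VARS = tuple(INTAKE_NUTRIENTS) + (
    "hemoglobin", "plasma_zinc", "retinol", "ferritin", "tfr")
_MEAN_VARS = ("birth_weight", "log_mpo", "log_neo", "log_aat",
              "bacteria_score", "parasite_score", "virus_score")


def make_descriptives(table: pd.DataFrame) -> pd.DataFrame:
    """Per-site and overall descriptive table.

    Right-skewed variables (intakes, blood concentrations) are summarized
    as median [IQR]; approximately symmetric ones (log biomarkers,
    pathogen scores, birth weight) as mean +/- SD; sex as n (%).
    """
    if table.empty:
        raise ValueError("empty analysis table")
    groups = {site: sub for site, sub in table.groupby("site")}
    groups["overall"] = table
    rows = {}
    for label, sub in groups.items():
        col = {}
        n_f = int(sub["female"].sum())
        col["female_n_pct"] = f"{n_f} ({100.0 * n_f / len(sub):.1f}%)"
        col["n"] = len(sub)
        for var in _MEDIAN_VARS:
            if var not in sub.columns:
                continue
            q1, med, q3 = sub[var].quantile([0.25, 0.5, 0.75])
            col[f"{var}_median_iqr"] = f"{med:.3g} [{q1:.3g}, {q3:.3g}]"
        for var in _MEAN_VARS:
            if var not in sub.columns:
                continue
            col[f"{var}_mean_sd"] = f"{sub[var].mean():.3g} ± {sub[var].std():.3g}"
        rows[label] = col
    order = sorted(g for g in groups if g != "overall") + ["overall"]
    return pd.DataFrame(rows)[order]


def make_edge_report(edges: list[EdgeSummary]) -> tuple[pd.DataFrame, str]:
    """Retained-arc table plus a DOT graph.

    Positive associations are colored red and negative blue; linear arcs
    are solid, log-odds arcs dashed.  Linear arcs carry no odds-ratio
    columns.
    """
    nodes: set[str] = set()
    rows = []
    lines = ["digraph mmd_network {", "  rankdir=LR;"]
    for e in edges:
        nodes.update(e.arc)
    for name in sorted(nodes):
        lines.append(f'  "{name}";')
    for e in edges:
        if not e.retained:
            continue
        rows.append(e.to_row())
        color = "red" if e.median > 0 else "blue"
        style = "dashed" if e.scale == "log_odds" else "solid"
        lines.append(
            f'  "{e.arc[0]}" -> "{e.arc[1]}" '
            f'[color={color}, style={style}, label="{e.median:.2f}"];')
    lines.append("}")
    columns = ["source", "target", "scale", "median", "ci_low", "ci_high",
               "retained", "ess", "unstable", "odds_ratio", "or_ci_low",
               "or_ci_high"]
    frame = pd.DataFrame(rows, columns=columns)
    return frame, "\n".join(lines)
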