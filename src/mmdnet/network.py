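"""Hybrid Bayesian network over diet, WASH, enteric pathogen burden, gut
biomarkers, and multiple micronutrient deficiency.

The DAG is fixed a priori in layers (SES/demographics -> household
crowding -> dietary intakes, pathogen burden & morbidity -> gut/systemic
biomarkers -> MMD).  Continuous nodes are linear-Gaussian in their
parents; the single binary sink (MMD) is Bernoulli-logit.  Because the
joint density factorizes over the DAG and the data are complete-case,
the posterior factorizes too; the sampler runs one joint Gibbs sweep per
iteration: conjugate normal / inverse-gamma updates for the linear nodes
and Polya-Gamma augmentation for the logistic node.  Arcs are retained
when the central 95% posterior interval of their coefficient excludes
zero.

Continuous variables enter as within-site z-scores, and the logistic
node additionally carries per-site intercepts, so arc coefficients are
within-country per-SD effects (odds ratios per SD for arcs into MMD).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx

from .pg import sample_pg, seed_pg

__all__ = [
    "NetworkSpec", "SamplerSettings", "PriorSpec", "Posterior",
    "EdgeSummary", "default_network", "fit_network", "select_arcs",
    "sensitivity_refit", "NetworkSpecError",
]


class NetworkSpecError(ValueError):
    """Structural problem in a network specification."""


GAUSSIAN = "gaussian_linear"
LOGIT = "bernoulli_logit"

#: node name -> (family, analysis-table column, layer index)
_DEFAULT_NODES: dict[str, tuple[str, str, int]] = {
    "female": (GAUSSIAN, "female", 0),
    "birth_weight": (GAUSSIAN, "z_birth_weight", 0),
    "income": (GAUSSIAN, "z_income", 0),
    "schooling": (GAUSSIAN, "z_maternal_schooling_years", 0),
    "crowding_high": (GAUSSIAN, "crowding_high", 1),
    **{name: (GAUSSIAN, f"z_{name}", 2) for name in (
        "energy", "protein", "carbohydrate", "iron", "folate", "zinc",
        "thiamin", "niacin", "riboflavin", "vitamin_a", "vitamin_c",
        "vitamin_b6", "vitamin_b12")},
    "bacteria_score": (GAUSSIAN, "z_bacteria_score", 2),
    "virus_score": (GAUSSIAN, "z_virus_score", 2),
    "parasite_score": (GAUSSIAN, "z_parasite_score", 2),
    "diarrheal_incidence": (GAUSSIAN, "z_diarrheal_incidence", 2),
    "breastfed_pct": (GAUSSIAN, "z_breastfed_pct", 2),
    "log_mpo": (GAUSSIAN, "z_log_mpo", 3),
    "log_neo": (GAUSSIAN, "z_log_neo", 3),
    "log_aat": (GAUSSIAN, "z_log_aat", 3),
    "log_agp": (GAUSSIAN, "z_log_agp", 3),
    "mmd": (LOGIT, "mmd", 4),
}

_DEFAULT_ARCS: tuple[tuple[str, str], ...] = (
    # household SES -> dietary intakes
    ("income", "zinc"), ("income", "thiamin"), ("income", "niacin"),
    ("schooling", "protein"), ("schooling", "iron"), ("schooling", "zinc"),
    ("schooling", "niacin"), ("schooling", "riboflavin"),
    ("schooling", "vitamin_a"),
    ("crowding_high", "vitamin_c"),
    # household SES -> enteric pathogen burden
    ("income", "virus_score"), ("schooling", "parasite_score"),
    ("crowding_high", "bacteria_score"),
    # diet, infection and morbidity -> gut / systemic biomarkers
    ("protein", "log_mpo"), ("bacteria_score", "log_mpo"),
    ("diarrheal_incidence", "log_mpo"),
    ("bacteria_score", "log_neo"), ("virus_score", "log_neo"),
    ("bacteria_score", "log_aat"), ("diarrheal_incidence", "log_aat"),
    ("bacteria_score", "log_agp"), ("diarrheal_incidence", "log_agp"),
    # candidate parents of the outcome
    ("female", "mmd"), ("birth_weight", "mmd"), ("vitamin_c", "mmd"),
    ("breastfed_pct", "mmd"), ("diarrheal_incidence", "mmd"),
    ("bacteria_score", "mmd"), ("log_mpo", "mmd"), ("log_neo", "mmd"),
    ("log_aat", "mmd"), ("log_agp", "mmd"),
)


@dataclass
class NetworkSpec:
    """Nodes (name -> (family, data column, layer)) and candidate arcs."""

    nodes: dict[str, tuple[str, str, int]]
    arcs: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = set(self.nodes)
        for s, t in self.arcs:
            if s not in names or t not in names:
                raise NetworkSpecError(f"arc ({s}, {t}) references unknown node")
            if self.nodes[s][2] >= self.nodes[t][2]:
                raise NetworkSpecError(
                    f"arc ({s}, {t}) violates the layer ordering")
        logits = [n for n, (fam, _, _) in self.nodes.items() if fam == LOGIT]
        if logits and logits != ["mmd"]:
            raise NetworkSpecError("mmd must be the unique bernoulli_logit node")
        for s, t in self.arcs:
            if s in logits:
                raise NetworkSpecError("the outcome node must be a sink")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise NetworkSpecError("candidate arc set contains a cycle")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.arcs)
        return g

    def parents(self, node: str) -> list[str]:
        return [s for s, t in self.arcs if t == node]

    def family(self, node: str) -> str:
        return self.nodes[node][0]

    def column(self, node: str) -> str:
        return self.nodes[node][1]

    def drop_node(self, node: str) -> "NetworkSpec":
        if node == "mmd":
            raise NetworkSpecError("cannot drop the outcome node")
        if node not in self.nodes:
            raise NetworkSpecError(f"unknown node {node!r}")
        nodes = {k: v for k, v in self.nodes.items() if k != node}
        arcs = tuple((s, t) for s, t in self.arcs if node not in (s, t))
        return NetworkSpec(nodes=nodes, arcs=arcs)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": {k: list(v) for k, v in self.nodes.items()},
            "arcs": [list(a) for a in self.arcs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(
            nodes={k: tuple(v) for k, v in d["nodes"].items()},
            arcs=tuple(tuple(a) for a in d["arcs"]),
        )


def default_network() -> NetworkSpec:
    """The default layered candidate-arc network."""
    return NetworkSpec(nodes=dict(_DEFAULT_NODES), arcs=_DEFAULT_ARCS)


@dataclass(frozen=True)
class SamplerSettings:
    chains: int = 4
    iterations: int = 5000
    warmup: int = 2500
    seed: int = 0

    def __post_init__(self):
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not 0 < self.warmup < self.iterations:
            raise ValueError("warmup must be in (0, iterations)")


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative defaults: normal(0, coef_sd^2) coefficients and
    intercepts, inverse-gamma(a, b) residual variances."""

    coef_sd: float = 10.0
    sigma2_a: float = 0.01
    sigma2_b: float = 0.01


@dataclass
class Posterior:
    """Post-warmup draws, (chains, kept_iterations) per parameter."""

    draws: dict[str, np.ndarray]
    settings: SamplerSettings
    node_order: list[str]

    _diag_cache: pd.DataFrame | None = field(default=None, repr=False)

    def parameter_names(self) -> list[str]:
        return list(self.draws)

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[name].reshape(-1)

    def diagnostics(self) -> pd.DataFrame:
        """Split R-hat and bulk effective sample size per parameter."""
        if self._diag_cache is None:
            import arviz as az

            ds = az.from_dict(posterior={k: v for k, v in self.draws.items()})
            rhat = az.rhat(ds).to_pandas()
            ess = az.ess(ds).to_pandas()
            self._diag_cache = pd.DataFrame({"rhat": rhat, "ess": ess})
        return self._diag_cache

    @property
    def converged(self) -> bool:
        d = self.diagnostics()
        return bool((d["rhat"] < 1.05).all())


@dataclass
class EdgeSummary:
    arc: tuple[str, str]
    scale: str                      # "beta_linear" or "log_odds"
    median: float
    ci_low: float
    ci_high: float
    retained: bool
    ess: float
    unstable: bool
    odds_ratio: float | None = None
    or_ci_low: float | None = None
    or_ci_high: float | None = None

    def to_row(self) -> dict:
        return {
            "source": self.arc[0], "target": self.arc[1], "scale": self.scale,
            "median": self.median, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "retained": self.retained, "ess": self.ess, "unstable": self.unstable,
            "odds_ratio": self.odds_ratio, "or_ci_low": self.or_ci_low,
            "or_ci_high": self.or_ci_high,
        }


def arc_parameter(source: str, target: str) -> str:
    return f"{target}~{source}"


def _design(spec: NetworkSpec, data: pd.DataFrame, node: str,
            adjust_site: bool) -> tuple[np.ndarray, list[str], np.ndarray]:
    parents = spec.parents(node)
    cols = [data[spec.column(p)].to_numpy(dtype=float) for p in parents]
    names = [arc_parameter(p, node) for p in parents]
    if adjust_site and "site" in data.columns:
        sites = pd.get_dummies(data["site"], dtype=float)
        blocks = [sites.to_numpy()]
        names = [f"{node}~site[{s}]" for s in sites.columns] + names
    else:
        blocks = [np.ones((len(data), 1))]
        names = [f"{node}~intercept"] + names
    X = np.column_stack(blocks + cols) if cols else np.column_stack(blocks)
    y = data[spec.column(node)].to_numpy(dtype=float)
    return X, names, y


def fit_network(spec: NetworkSpec, data: pd.DataFrame,
                settings: SamplerSettings | None = None,
                priors: PriorSpec | None = None) -> Posterior:
    """Joint Gibbs fit of every node model.

    ``data`` must be a complete-case analysis table carrying each node's
    column.  Linear-Gaussian nodes use conjugate normal / inverse-gamma
    sweeps; the MMD node uses Polya-Gamma augmentation with per-site
    intercepts.  Deterministic given (data, settings.seed).
    """
    settings = settings or SamplerSettings()
    priors = priors or PriorSpec()
    nodes = [n for n in spec.nodes]
    for node in nodes:
        col = spec.column(node)
        if col not in data.columns:
            raise NetworkSpecError(f"data is missing column {col!r} for node {node}")
        if data[col].isna().any():
            raise NetworkSpecError(f"missing values in column {col!r}; "
                                   "complete-case filter first")

    kept = settings.iterations - settings.warmup
    draws: dict[str, np.ndarray] = {}
    node_infos = []
    for node in nodes:
        X, names, y = _design(spec, data, node,
                              adjust_site=(spec.family(node) == LOGIT))
        if not np.all(np.isfinite(X)) or not np.all(np.isfinite(y)):
            raise NetworkSpecError(f"non-finite values in node {node}")
        node_infos.append((node, X, names, y))
        for name in names:
            draws[name] = np.empty((settings.chains, kept))
        if spec.family(node) == GAUSSIAN:
            draws[f"{node}~sigma2"] = np.empty((settings.chains, kept))

    root_ss = np.random.SeedSequence(settings.seed)
    chain_seeds = root_ss.spawn(settings.chains)
    for chain, ss in enumerate(chain_seeds):
        rng = np.random.default_rng(ss)
        seed_pg(int(ss.generate_state(1, np.uint32)[0]))
        for node, X, names, y in node_infos:
            if spec.family(node) == GAUSSIAN:
                chain_draws = _gibbs_gaussian_node(
                    X, y, priors, settings, rng)
                for j, name in enumerate(names):
                    draws[name][chain] = chain_draws["beta"][:, j]
                draws[f"{node}~sigma2"][chain] = chain_draws["sigma2"]
            else:
                beta_draws = _gibbs_logit_node(X, y, priors, settings, rng)
                for j, name in enumerate(names):
                    draws[name][chain] = beta_draws[:, j]
    return Posterior(draws=draws, settings=settings, node_order=nodes)


def _gibbs_gaussian_node(X, y, priors: PriorSpec, settings: SamplerSettings,
                         rng: np.random.Generator) -> dict[str, np.ndarray]:
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    prior_prec = np.eye(p) / priors.coef_sd ** 2
    kept = settings.iterations - settings.warmup
    out_beta = np.empty((kept, p))
    out_s2 = np.empty(kept)
    sigma2 = max(float(np.var(y)), 1e-6)
    beta = np.zeros(p)
    a_post = priors.sigma2_a + 0.5 * n
    for it in range(settings.iterations):
        prec = XtX / sigma2 + prior_prec
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xty / sigma2)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        resid = y - X @ beta
        b_post = priors.sigma2_b + 0.5 * float(resid @ resid)
        sigma2 = b_post / rng.gamma(a_post)
        if it >= settings.warmup:
            out_beta[it - settings.warmup] = beta
            out_s2[it - settings.warmup] = sigma2
    return {"beta": out_beta, "sigma2": out_s2}


def _gibbs_logit_node(X, y, priors: PriorSpec, settings: SamplerSettings,
                      rng: np.random.Generator) -> np.ndarray:
    n, p = X.shape
    prior_prec = np.eye(p) / priors.coef_sd ** 2
    kappa = y - 0.5
    Xt_kappa = X.T @ kappa
    kept = settings.iterations - settings.warmup
    out = np.empty((kept, p))
    beta = np.zeros(p)
    for it in range(settings.iterations):
        omega = sample_pg(X @ beta)
        prec = X.T @ (X * omega[:, None]) + prior_prec
        L = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, Xt_kappa)
        z = rng.standard_normal(p)
        beta = mean + np.linalg.solve(L.T, z)
        if it >= settings.warmup:
            out[it - settings.warmup] = beta
    return out


def rwm_logit_posterior(X, y, priors: PriorSpec | None = None,
                        iterations: int = 20000, warmup: int = 5000,
                        seed: int = 0, step: float = 0.0) -> np.ndarray:
    """Random-walk Metropolis draws for one Bernoulli-logit node.

    Verification fallback targeting the same posterior as the Polya-Gamma
    kernel; tuned only through a single proposal scale.
    """
    priors = priors or PriorSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    if step <= 0:
        step = 2.4 / np.sqrt(p * n) * 2.0

    def logpost(b):
        eta = X @ b
        ll = float(y @ eta - np.logaddexp(0.0, eta).sum())
        return ll - 0.5 * float(b @ b) / priors.coef_sd ** 2

    beta = np.zeros(p)
    lp = logpost(beta)
    out = np.empty((iterations - warmup, p))
    for it in range(iterations):
        prop = beta + step * rng.standard_normal(p)
        lp_prop = logpost(prop)
        if np.log(rng.random()) < lp_prop - lp:
            beta, lp = prop, lp_prop
        if it >= warmup:
            out[it - warmup] = beta
    return out


def select_arcs(posterior: Posterior, spec: NetworkSpec,
                level: float = 0.95) -> list[EdgeSummary]:
    """Credibility-interval arc selection.

    An arc is retained when the central ``level`` posterior interval of
    its coefficient excludes zero; arcs into the logistic node also
    report the odds-ratio transform of the same summaries.  Decisions
    backed by fewer than 100 effective draws are flagged unstable.
    """
    alpha = (1.0 - level) / 2.0
    diag = posterior.diagnostics()
    out = []
    for source, target in spec.arcs:
        name = arc_parameter(source, target)
        samples = posterior.stacked(name)
        lo, med, hi = np.quantile(samples, [alpha, 0.5, 1.0 - alpha])
        retained = bool(lo > 0.0 or hi < 0.0)
        ess = float(diag.loc[name, "ess"]) if name in diag.index else float("nan")
        is_logit = spec.family(target) == LOGIT
        out.append(EdgeSummary(
            arc=(source, target),
            scale="log_odds" if is_logit else "beta_linear",
            median=float(med), ci_low=float(lo), ci_high=float(hi),
            retained=retained, ess=ess,
            unstable=bool(np.isfinite(ess) and ess < 100),
            odds_ratio=float(np.exp(med)) if is_logit else None,
            or_ci_low=float(np.exp(lo)) if is_logit else None,
            or_ci_high=float(np.exp(hi)) if is_logit else None,
        ))
    return out


def sensitivity_refit(spec: NetworkSpec, data: pd.DataFrame, drop: str,
                      settings: SamplerSettings | None = None,
                      priors: PriorSpec | None = None,
                      baseline: list[EdgeSummary] | None = None,
                      level: float = 0.95) -> pd.DataFrame:
    """Refit with one node (and its arcs) removed; report per-arc changes.

    Returns a frame with the baseline and refit posterior medians,
    retention flags, and their differences, indexed by arc.  Arcs touching
    the dropped node appear only in the baseline rows.
    """
    settings = settings or SamplerSettings()
    if baseline is None:
        base_post = fit_network(spec, data, settings, priors)
        baseline = select_arcs(base_post, spec, level)
    reduced = spec.drop_node(drop)
    if not reduced.parents("mmd"):
        import warnings

        warnings.warn("dropping this node leaves the outcome with no parents",
                      RuntimeWarning, stacklevel=2)
    refit_post = fit_network(reduced, data, settings, priors)
    refit = {e.arc: e for e in select_arcs(refit_post, reduced, level)}
    rows = []
    for e in baseline:
        r = refit.get(e.arc)
        rows.append({
            "source": e.arc[0], "target": e.arc[1],
            "median_baseline": e.median,
            "median_refit": r.median if r else np.nan,
            "delta_median": (r.median - e.median) if r else np.nan,
            "retained_baseline": e.retained,
            "retained_refit": r.retained if r else None,
            "retention_flip": (r.retained != e.retained) if r else None,
        })
    return pd.DataFrame(rows)
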