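"""Hybrid network: spec structure, Gibbs sampler correctness against
conjugate and Metropolis oracles, arc selection, and sensitivity refits."""

import numpy as np
import pandas as pd
import pytest

from mmdnet import (
    NetworkSpec,
    Posterior,
    SamplerSettings,
    default_network,
    fit_network,
    select_arcs,
    sensitivity_refit,
)
from mmdnet.network import (
    GAUSSIAN,
    LOGIT,
    NetworkSpecError,
    arc_parameter,
    rwm_logit_posterior,
)
from mmdnet.pg import pg_mean, sample_pg, seed_pg

FAST = SamplerSettings(chains=2, iterations=800, warmup=400, seed=9)


class TestSpec:
    def test_default_network_structure(self):
        spec = default_network()
        assert ("female", "mmd") in spec.arcs
        assert ("vitamin_c", "mmd") in spec.arcs
        assert ("log_mpo", "mmd") in spec.arcs
        # the outcome is a sink
        assert not [a for a in spec.arcs if a[0] == "mmd"]
        import networkx as nx
        assert nx.is_directed_acyclic_graph(spec.graph())

    def test_layer_violation_rejected(self):
        spec = default_network()
        with pytest.raises(NetworkSpecError):
            NetworkSpec(nodes=spec.nodes, arcs=spec.arcs + (("log_mpo", "protein"),))

    def test_unknown_node_rejected(self):
        spec = default_network()
        with pytest.raises(NetworkSpecError):
            NetworkSpec(nodes=spec.nodes, arcs=spec.arcs + (("ghost", "mmd"),))

    def test_drop_node_removes_its_arcs(self):
        spec = default_network()
        reduced = spec.drop_node("log_mpo")
        assert "log_mpo" not in reduced.nodes
        assert not [a for a in reduced.arcs if "log_mpo" in a]
        with pytest.raises(NetworkSpecError):
            spec.drop_node("mmd")

    def test_spec_json_roundtrip(self):
        spec = default_network()
        again = NetworkSpec.from_dict(spec.to_dict())
        assert again.nodes == spec.nodes and again.arcs == spec.arcs


class TestPolyaGamma:
    @pytest.mark.parametrize("z", [0.0, 0.7, 2.0, -3.0])
    def test_empirical_mean_matches_closed_form(self, z):
        seed_pg(11)
        draws = sample_pg(np.full(60_000, z))
        assert draws.mean() == pytest.approx(pg_mean(np.array([z]))[0], abs=4e-3)
        assert (draws > 0).all()

    def test_variance_at_zero(self):
        # PG(1,0) has variance 1/24
        seed_pg(12)
        draws = sample_pg(np.zeros(120_000))
        assert draws.var() == pytest.approx(1 / 24, abs=2e-3)


def _single_gaussian_node_spec():
    return NetworkSpec(
        nodes={"x": (GAUSSIAN, "x", 0), "y": (GAUSSIAN, "y", 1)},
        arcs=(("x", "y"),))


def test_gaussian_node_matches_conjugate_posterior():
    """Gibbs posterior mean of the slope agrees with the closed-form
    normal-prior posterior mean (X'X + I/s^2)^-1 X'y within 1e-2."""
    rng = np.random.default_rng(4)
    n = 500
    x = rng.standard_normal(n)
    y = 0.4 + 0.9 * x + rng.normal(0, 0.7, n)
    data = pd.DataFrame({"x": x, "y": y})
    spec = _single_gaussian_node_spec()
    post = fit_network(spec, data, SamplerSettings(chains=2, iterations=3000,
                                                   warmup=1000, seed=1))
    X = np.column_stack([np.ones(n), x])
    oracle = np.linalg.solve(X.T @ X + np.eye(2) / 100.0, X.T @ y)
    assert post.stacked("y~x").mean() == pytest.approx(oracle[1], abs=1e-2)
    assert post.stacked("y~intercept").mean() == pytest.approx(oracle[0], abs=1e-2)


def test_zero_arc_spec_centers_intercepts_at_node_means():
    rng = np.random.default_rng(5)
    data = pd.DataFrame({"x": rng.normal(2.0, 1.0, 400),
                         "y": rng.normal(-1.0, 0.5, 400)})
    spec = NetworkSpec(nodes={"x": (GAUSSIAN, "x", 0), "y": (GAUSSIAN, "y", 1)},
                       arcs=())
    post = fit_network(spec, data, FAST)
    assert post.stacked("x~intercept").mean() == pytest.approx(data["x"].mean(), abs=0.05)
    assert post.stacked("y~intercept").mean() == pytest.approx(data["y"].mean(), abs=0.05)
    assert arc_parameter("x", "y") not in post.draws


def test_logit_node_matches_random_walk_metropolis():
    """The Polya-Gamma kernel and a plain Metropolis sampler target the
    same posterior: their means agree within Monte-Carlo error."""
    rng = np.random.default_rng(6)
    n = 400
    x = rng.standard_normal(n)
    site = np.repeat(["A", "B"], n // 2)
    eta = 0.4 + 0.8 * x
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    data = pd.DataFrame({"x": x, "mmd": y, "site": site})
    spec = NetworkSpec(nodes={"x": (GAUSSIAN, "x", 0), "mmd": (LOGIT, "mmd", 1)},
                       arcs=(("x", "mmd"),))
    post = fit_network(spec, data, SamplerSettings(chains=2, iterations=4000,
                                                   warmup=1000, seed=2))
    X = np.column_stack([pd.get_dummies(site, dtype=float).to_numpy(), x])
    rwm = rwm_logit_posterior(X, y, iterations=60_000, warmup=20_000, seed=3)
    assert post.stacked("mmd~x").mean() == pytest.approx(rwm[:, 2].mean(), abs=0.05)


def test_fit_is_seed_deterministic():
    rng = np.random.default_rng(7)
    data = pd.DataFrame({"x": rng.standard_normal(200),
                         "y": rng.standard_normal(200)})
    spec = _single_gaussian_node_spec()
    a = fit_network(spec, data, FAST)
    b = fit_network(spec, data, FAST)
    c = fit_network(spec, data, SamplerSettings(chains=2, iterations=800,
                                                warmup=400, seed=10))
    assert np.array_equal(a.draws["y~x"], b.draws["y~x"])
    assert not np.array_equal(a.draws["y~x"], c.draws["y~x"])


def test_missing_data_rejected():
    spec = _single_gaussian_node_spec()
    data = pd.DataFrame({"x": [1.0, np.nan], "y": [0.0, 1.0]})
    with pytest.raises(NetworkSpecError):
        fit_network(spec, data, FAST)


class TestSelectArcs:
    def _posterior(self, draws):
        return Posterior(draws=draws, settings=FAST, node_order=["x", "y"])

    def test_interval_rule(self):
        spec = _single_gaussian_node_spec()
        rng = np.random.default_rng(0)
        positive = self._posterior({"y~x": rng.uniform(0.5, 1.0, (2, 400))})
        kept = select_arcs(positive, spec)[0]
        assert kept.retained and kept.ci_low > 0
        symmetric = self._posterior({"y~x": rng.normal(0.0, 1.0, (2, 400))})
        assert not select_arcs(symmetric, spec)[0].retained

    def test_logit_arcs_report_consistent_odds_ratios(self):
        nodes = {"x": (GAUSSIAN, "x", 0), "mmd": (LOGIT, "mmd", 1)}
        spec = NetworkSpec(nodes=nodes, arcs=(("x", "mmd"),))
        rng = np.random.default_rng(1)
        post = self._posterior({"mmd~x": rng.normal(0.3, 0.05, (2, 400))})
        edge = select_arcs(post, spec)[0]
        assert edge.scale == "log_odds"
        assert edge.odds_ratio == pytest.approx(np.exp(edge.median), rel=1e-12)
        assert edge.or_ci_low == pytest.approx(np.exp(edge.ci_low), rel=1e-12)

    def test_few_effective_draws_flagged_unstable(self):
        spec = _single_gaussian_node_spec()
        constant = np.linspace(1.0, 1.0001, 800).reshape(2, 400)
        edge = select_arcs(self._posterior({"y~x": constant}), spec)[0]
        assert edge.unstable


def test_sensitivity_drop_is_localized(analysis_table):
    """Dropping neopterin (no planted pathway to MMD) leaves the
    MPO -> MMD decision unchanged; dropping MPO removes its arc."""
    spec = default_network()
    post = fit_network(spec, analysis_table, FAST)
    baseline = select_arcs(post, spec)
    base_mpo = {e.arc: e for e in baseline}[("log_mpo", "mmd")]
    delta = sensitivity_refit(spec, analysis_table, "log_neo",
                              settings=FAST, baseline=baseline)
    row = delta.set_index(["source", "target"]).loc[("log_mpo", "mmd")]
    assert bool(row["retention_flip"]) is False
    assert abs(row["delta_median"]) < 0.1
    dropped = sensitivity_refit(spec, analysis_table, "log_mpo",
                                settings=FAST, baseline=baseline)
    gone = dropped.set_index(["source", "target"]).loc[("log_mpo", "mmd")]
    assert np.isnan(gone["median_refit"])
    assert base_mpo.retained  # the planted arc is found at study scale
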