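"""Sampler and estimators: closed forms, oracles, determinism."""

import numpy as np
import pytest
from scipy.special import expit, logit

from prosonet import (
    AttributedNetwork,
    Constraint,
    McmcSettings,
    ModelSpec,
    NO_CONSTRAINT,
    SeparationError,
    TermSpec,
    exact_distribution,
    exact_mle,
    global_statistics,
    mcmc_mle,
    mple,
    sample_networks,
)
from prosonet.engine import DegeneracyError, _empty_network
from tests.conftest import make_attributes, make_network

EDGES_ONLY = ModelSpec([TermSpec("edges")])


def _quick(**kw):
    base = dict(burnin=4_000, interval=20, ndraws=2_000)
    base.update(kw)
    return McmcSettings(**base)


class TestSampler:
    def test_zero_coefficient_gives_half_density(self, rng):
        n = 10
        s = sample_networks(
            EDGES_ONLY.with_coefficients([0.0]),
            n_nodes=n,
            settings=_quick(),
            seed=1,
        )
        mean_edges = s.statistics[:, 0].mean()
        D = n * (n - 1)
        se = np.sqrt(D * 0.25 / len(s.statistics)) * 3  # generous: draws correlate
        assert abs(mean_edges - 0.5 * D) < 10 * se

    def test_logit_parameterization_matches_expected_count(self, rng):
        n, p = 12, 0.2
        s = sample_networks(
            EDGES_ONLY.with_coefficients([float(logit(p))]),
            n_nodes=n,
            settings=_quick(ndraws=4_000),
            seed=2,
        )
        D = n * (n - 1)
        assert abs(s.statistics[:, 0].mean() - p * D) < 0.05 * D

    def test_out_degree_cap_never_violated(self, rng):
        s = sample_networks(
            EDGES_ONLY.with_coefficients([0.0]),  # wants density 1/2 per dyad
            n_nodes=9,
            constraint=Constraint(2),
            settings=_quick(ndraws=500),
            seed=3,
            return_networks=True,
        )
        assert s.networks.sum(axis=2).max() <= 2

    def test_seeded_determinism(self, rng):
        spec = EDGES_ONLY.with_coefficients([-1.0])
        a = sample_networks(spec, n_nodes=8, settings=_quick(), seed=7)
        b = sample_networks(spec, n_nodes=8, settings=_quick(), seed=7)
        c = sample_networks(spec, n_nodes=8, settings=_quick(), seed=8)
        assert np.array_equal(a.statistics, b.statistics)
        assert not np.array_equal(a.statistics, c.statistics)

    def test_non_finite_coefficient_refused(self):
        with pytest.raises(DegeneracyError, match="edges"):
            sample_networks(
                EDGES_ONLY.with_coefficients([np.nan]), n_nodes=5, settings=_quick()
            )


class TestMple:
    def test_edges_only_is_logit_density(self, rng):
        net = make_network(20, 0.15, rng)
        fit = mple(net, EDGES_ONLY)
        density = net.n_edges / (20 * 19)
        assert fit.coefficients[0] == pytest.approx(float(logit(density)), abs=1e-6)
        assert fit.method == "MPLE"

    def test_dyad_independent_mple_equals_exact_mle(self, rng):
        # on n = 4 the exact likelihood is enumerable: the pseudo-
        # likelihood must coincide for a dyad-independent model
        attrs = make_attributes(4, rng)
        A = np.zeros((4, 4), bool)
        A[0, 1] = A[1, 0] = A[2, 3] = A[0, 2] = A[3, 1] = True
        net = AttributedNetwork(list(attrs.index), A, attrs)
        spec = ModelSpec([TermSpec("edges"), TermSpec("nodematch", attribute="sex")])
        f_pl = mple(net, spec)
        f_ex = exact_mle(net, spec)
        assert np.allclose(f_pl.coefficients, f_ex.coefficients, atol=1e-5)

    def test_parameter_recovery_edges_only(self):
        theta = -2.0
        n, reps = 100, 20
        p = expit(theta)
        ests = []
        for rep in range(reps):
            net = make_network(n, p, np.random.default_rng(500 + rep))
            ests.append(mple(net, EDGES_ONLY).coefficients[0])
        mc_se = np.std(ests, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(ests) - theta) < 2 * mc_se + 0.01

    def test_complete_graph_is_separable(self, rng):
        attrs = make_attributes(5, rng)
        A = ~np.eye(5, dtype=bool)
        net = AttributedNetwork(list(attrs.index), A, attrs)
        with pytest.raises(SeparationError):
            mple(net, EDGES_ONLY)

    def test_constraint_excludes_capped_dyads(self, rng):
        net = make_network(15, 0.15, rng)
        cap = int(net.out_degrees().max())
        fit = mple(net, EDGES_ONLY, Constraint(cap))
        n_at_cap = int((net.out_degrees() >= cap).sum())
        expected_rows = 15 * 14 - (n_at_cap * 14 - net.adjacency[net.out_degrees() >= cap].sum())
        assert fit.diagnostics["n_dyads"] == expected_rows

    def test_observed_constraint_violation_rejected(self, rng):
        net = make_network(10, 0.5, rng)
        with pytest.raises(ValueError, match="constraint"):
            mple(net, EDGES_ONLY, Constraint(1))


class TestExactOracle:
    def test_distribution_normalizes(self, rng):
        net = _empty_network(3, make_attributes(3, rng))
        spec = ModelSpec([TermSpec("edges"), TermSpec("gwesp", alpha=0.3)])
        _, probs = exact_distribution(net, spec.with_coefficients([-0.5, 0.8]))
        assert probs.sum() == pytest.approx(1.0)

    def test_edges_only_mle_is_logit_density(self, rng):
        attrs = make_attributes(3, rng)
        A = np.zeros((3, 3), bool)
        A[0, 1] = A[1, 2] = True
        net = AttributedNetwork(list(attrs.index), A, attrs)
        fit = exact_mle(net, EDGES_ONLY)
        assert fit.coefficients[0] == pytest.approx(float(logit(2 / 6)), abs=1e-8)

    def test_mle_moment_matches_observed_statistics(self, rng):
        attrs = make_attributes(4, rng)
        attrs["sex"] = [0, 0, 1, 1]
        A = np.zeros((4, 4), bool)
        A[0, 1] = A[1, 0] = A[2, 3] = A[0, 2] = True
        net = AttributedNetwork(list(attrs.index), A, attrs)
        spec = ModelSpec([TermSpec("edges"), TermSpec("nodematch", attribute="sex")])
        fit = exact_mle(net, spec)
        codes, probs = exact_distribution(net, fit.spec)
        from prosonet.engine import enumerate_statistics

        stats, feasible = enumerate_statistics(net, spec)
        expected = probs @ stats[feasible]
        assert np.allclose(expected, fit.observed_stats, atol=1e-7)

    def test_refuses_large_networks(self, rng):
        net = make_network(6, 0.2, rng)
        with pytest.raises(ValueError, match="n = 6"):
            exact_mle(net, EDGES_ONLY)


class TestMcmcMle:
    def test_dyad_independent_agrees_with_mple(self, rng):
        spec = ModelSpec(
            [
                TermSpec("edges"),
                TermSpec("nodematch", attribute="sex"),
                TermSpec("absdiff", attribute="prosociality"),
            ]
        )
        net = make_network(50, 0.12, rng)
        f_pl = mple(net, spec)
        f_mc = mcmc_mle(
            net, spec, settings=_quick(burnin=20_000, interval=50, ndraws=8_000), seed=5
        )
        assert np.max(np.abs(f_pl.coefficients - f_mc.coefficients)) < 0.05

    def test_moment_matching_diagnostic_within_three_mcse(self, rng):
        # "simulations capture the sufficient statistics" at the MLE
        spec = ModelSpec(
            [TermSpec("edges"), TermSpec("odegree0"), TermSpec("gwesp", alpha=0.25)]
        )
        truth = spec.with_coefficients([-3.2, 0.8, 0.5])
        s = sample_networks(
            truth, n_nodes=40, settings=_quick(burnin=50_000, ndraws=200, interval=400),
            seed=9, return_networks=True,
        )
        attrs = make_attributes(40, rng)
        net = AttributedNetwork(list(attrs.index), s.networks[-1].astype(bool), attrs)
        fit = mcmc_mle(
            net, spec, settings=_quick(burnin=30_000, interval=200, ndraws=3_000, tol=1e-3),
            seed=10,
        )
        assert np.all(np.abs(fit.diagnostics["moment_z"]) < 3.0)
        assert np.all(fit.std_errors > 0)

    def test_seeded_determinism(self, rng):
        net = make_network(25, 0.15, rng)
        kw = dict(settings=_quick(burnin=5_000, ndraws=1_000), seed=3)
        a = mcmc_mle(net, EDGES_ONLY, **kw)
        b = mcmc_mle(net, EDGES_ONLY, **kw)
        assert np.array_equal(a.coefficients, b.coefficients)
        assert np.array_equal(a.std_errors, b.std_errors)

    def test_report_echoes_gwesp_decay_and_constraint(self, rng):
        spec = ModelSpec([TermSpec("edges"), TermSpec("gwesp", alpha=0.25)])
        net = make_network(30, 0.08, rng)
        fit = mcmc_mle(
            net, spec, constraint=Constraint(7),
            settings=_quick(burnin=10_000, ndraws=1_000, tol=1e-2), seed=4,
        )
        text = fit.report()
        assert "alpha = 0.25" in text
        assert "out-degree <= 7" in text
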