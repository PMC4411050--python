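"""ERGM statistics: global values, change statistics, model specs."""

import numpy as np
import pytest

from prosonet import (
    AttributedNetwork,
    ModelSpec,
    TermSpec,
    change_matrix,
    change_statistics,
    global_statistics,
    sqrt_product_covariate,
    study_model,
)
from prosonet.terms import MissingAttributeError, is_dyad_independent
from tests.conftest import make_attributes, make_network


def _net_from_adj(A, attrs):
    return AttributedNetwork(list(attrs.index), np.asarray(A, bool), attrs)


def _full_spec(alpha=0.5, sp_type="transitive"):
    return ModelSpec(
        [
            TermSpec("edges"),
            TermSpec("nodematch", attribute="sex"),
            TermSpec("nodeocov", attribute="prosociality"),
            TermSpec("nodeicov", attribute="income"),
            TermSpec("absdiff", attribute="prosociality"),
            TermSpec("edgecov", covariate="sqrt_product:prosociality"),
            TermSpec("odegree0"),
            TermSpec("gwesp", alpha=alpha, sp_type=sp_type),
        ]
    )


class TestSqrtProductCovariate:
    def test_equal_scores_return_the_score(self):
        M = sqrt_product_covariate([4.0, 4.0])
        assert M[0, 1] == pytest.approx(4.0)

    def test_hand_value(self):
        M = sqrt_product_covariate([1.0, 5.0])
        assert M[0, 1] == pytest.approx(np.sqrt(5.0))  # ~2.23607

    def test_stays_on_the_attribute_scale(self, rng):
        x = rng.uniform(1, 5, 30)
        M = sqrt_product_covariate(x)
        off = ~np.eye(30, dtype=bool)
        assert M[off].min() >= 1.0 and M[off].max() <= 5.0
        assert np.allclose(M, M.T)

    def test_nonpositive_scores_rejected(self):
        with pytest.raises(ValueError):
            sqrt_product_covariate([2.0, 0.0])


class TestGlobalStatistics:
    def test_empty_network_all_zero_except_loners(self, rng):
        attrs = make_attributes(6, rng)
        net = _net_from_adj(np.zeros((6, 6)), attrs)
        g = global_statistics(net, _full_spec())
        names = _full_spec().names
        assert g[names.index("odegree0")] == 6
        assert np.all(np.delete(g, names.index("odegree0")) == 0)

    def test_transitive_triangle_gwesp_at_zero_decay(self, rng):
        attrs = make_attributes(3, rng)
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 2] = A[0, 2] = 1  # A->B, B->C, A->C
        net = _net_from_adj(A, attrs)
        spec = ModelSpec([TermSpec("gwesp", alpha=0.0)])
        # only A->C has a (transitive) shared partner
        assert global_statistics(net, spec)[0] == pytest.approx(1.0)

    def test_absdiff_two_nodes(self, rng):
        attrs = make_attributes(2, rng)
        attrs["prosociality"] = [2.0, 3.5]
        net = _net_from_adj([[0, 1], [0, 0]], attrs)
        spec = ModelSpec([TermSpec("absdiff", attribute="prosociality")])
        assert global_statistics(net, spec)[0] == pytest.approx(1.5)

    @pytest.mark.parametrize("sp_type", ["transitive", "cyclic", "any"])
    def test_gwesp_zero_decay_counts_edges_with_partners(self, sp_type, rng):
        from prosonet.terms import SP_CODES, edge_shared_partners

        net = make_network(12, 0.3, rng)
        spec = ModelSpec([TermSpec("gwesp", alpha=0.0, sp_type=sp_type)])
        sp = edge_shared_partners(net.adjacency, SP_CODES[sp_type])
        assert global_statistics(net, spec)[0] == pytest.approx((sp >= 1).sum())

    def test_gwesp_grows_with_closure_at_fixed_edge_count(self, rng):
        attrs = make_attributes(4, rng)
        spec = ModelSpec([TermSpec("gwesp", alpha=0.5)])
        chain = np.zeros((4, 4))
        chain[0, 1] = chain[1, 2] = chain[2, 3] = 1  # path, no triangles
        tri = np.zeros((4, 4))
        tri[0, 1] = tri[1, 2] = tri[0, 2] = 1  # one transitive triangle
        g_chain = global_statistics(_net_from_adj(chain, attrs), spec)[0]
        g_tri = global_statistics(_net_from_adj(tri, attrs), spec)[0]
        assert g_tri > g_chain == 0.0

    def test_edgecov_of_ones_equals_edge_count(self, rng):
        net = make_network(10, 0.25, rng)
        spec = ModelSpec([TermSpec("edges"), TermSpec("edgecov", covariate="ones")])
        g = global_statistics(net, spec)
        assert g[0] == g[1]

    def test_directed_cov_sums_conserve_scores(self, rng):
        # symmetrized ties, constant score c: icov + ocov = 2 c E
        attrs = make_attributes(8, rng)
        attrs["prosociality"] = 3.0
        A = make_network(8, 0.3, rng).adjacency
        A = A | A.T
        np.fill_diagonal(A, False)
        net = _net_from_adj(A, attrs)
        spec = ModelSpec(
            [
                TermSpec("nodeicov", attribute="prosociality"),
                TermSpec("nodeocov", attribute="prosociality"),
            ]
        )
        g = global_statistics(net, spec)
        assert g.sum() == pytest.approx(2 * 3.0 * net.n_edges)

    def test_missing_attribute_is_an_error(self, rng):
        attrs = make_attributes(4, rng)
        attrs.loc[attrs.index[1], "income"] = np.nan
        net = _net_from_adj(np.zeros((4, 4)), attrs)
        with pytest.raises(MissingAttributeError, match="income"):
            global_statistics(net, ModelSpec([TermSpec("nodeicov", attribute="income")]))


class TestChangeStatistics:
    def test_simple_term_deltas(self, rng):
        attrs = make_attributes(3, rng)
        attrs["sex"] = [0, 0, 1]
        net = _net_from_adj(np.zeros((3, 3)), attrs)
        spec = ModelSpec([TermSpec("edges"), TermSpec("nodematch", attribute="sex")])
        same = change_statistics(net, ("n000", "n001"), spec)
        cross = change_statistics(net, ("n000", "n002"), spec)
        assert same.tolist() == [1.0, 1.0]
        assert cross.tolist() == [1.0, 0.0]

    def test_self_loop_dyad_rejected(self, rng):
        net = make_network(4, 0.2, rng)
        with pytest.raises(ValueError, match="self-loop"):
            change_statistics(net, (1, 1), _full_spec())

    @pytest.mark.parametrize("trial", range(40))
    def test_matches_full_recount_on_random_instances(self, trial):
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(3, 9))
        net = make_network(n, float(rng.uniform(0.1, 0.6)), rng)
        spec = _full_spec(
            alpha=float(rng.uniform(0, 1.5)),
            sp_type=["transitive", "cyclic", "any"][trial % 3],
        )
        i, j = map(int, rng.choice(n, size=2, replace=False))
        delta = change_statistics(net, (i, j), spec)
        on, off = net.adjacency.copy(), net.adjacency.copy()
        on[i, j], off[i, j] = True, False
        g_on = global_statistics(_net_from_adj(on, net.attributes), spec)
        g_off = global_statistics(_net_from_adj(off, net.attributes), spec)
        assert np.allclose(delta, g_on - g_off, atol=1e-9)

    def test_change_matrix_agrees_with_per_dyad_calls(self, rng):
        net = make_network(7, 0.35, rng)
        spec = _full_spec(alpha=0.25)
        mats = change_matrix(net, spec)
        for i, j in [(0, 1), (3, 2), (5, 6)]:
            assert np.allclose(mats[:, i, j], change_statistics(net, (i, j), spec))


class TestModelSpec:
    def test_study_model_term_counts(self):
        assert len(study_model(1)) == 13
        assert len(study_model(2)) == 7
        assert study_model(2).names[2] == "edgecov.sqrt_product:prosociality"

    def test_yaml_round_trip(self, tmp_path):
        spec = study_model(2, alpha=0.4).with_coefficients(np.arange(7.0))
        spec.to_yaml(tmp_path / "m.yaml")
        back = ModelSpec.from_yaml(tmp_path / "m.yaml")
        assert back.names == spec.names
        assert np.allclose(back.coefficients, spec.coefficients)
        assert back.terms[-1].alpha == 0.4

    def test_dyad_independence_classification(self):
        assert not is_dyad_independent(study_model(2))
        assert is_dyad_independent(ModelSpec([TermSpec("edges")]))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"kind": "unknown"},
            {"kind": "nodematch"},  # missing attribute
            {"kind": "edges", "attribute": "sex"},
            {"kind": "edgecov"},  # missing covariate
            {"kind": "gwesp", "alpha": -0.1},
            {"kind": "gwesp", "sp_type": "sideways"},
        ],
    )
    def test_invalid_term_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TermSpec(**kwargs)

    def test_coefficient_length_checked(self):
        with pytest.raises(ValueError, match="length"):
            ModelSpec([TermSpec("edges")]).with_coefficients([1.0, 2.0])
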