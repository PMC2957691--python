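"""Raw evidence channels: FS-weight, expression correlation, domain counts."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from binppi.evidence import (
    ChannelSpec,
    compile_evidence_table,
    domain_interaction_score,
    fs_weight,
    gene_expression_corr,
)
from binppi.net_io import DomainData, ProteinPair, canonical_domain_pair

from conftest import build_network


class TestFsWeight:
    def test_no_common_neighbor_is_zero(self):
        net = build_network([("x", "a"), ("y", "b")])
        assert fs_weight(net, ProteinPair("x", "y")) == 0.0

    def test_asymmetric_neighborhoods(self, asymmetric_net):
        # |common|=2, each side has one private neighbor: (4/6)*(4/6)
        assert fs_weight(asymmetric_net, ProteinPair("x", "y")) == pytest.approx(4 / 9)

    def test_single_shared_neighbor(self):
        net = build_network([("x", "z"), ("y", "z")])
        assert fs_weight(net, ProteinPair("x", "y")) == pytest.approx(4 / 9)

    def test_adjacent_pair_endpoints_fall_in_difference_sets(self):
        # x-y edge plus shared z: N_x={y,z}, N_y={x,z}
        net = build_network([("x", "y"), ("x", "z"), ("y", "z")])
        expected = (2 / (1 + 2 + 1)) ** 2
        assert fs_weight(net, ProteinPair("x", "y")) == pytest.approx(expected)

    @given(st.lists(st.tuples(st.integers(0, 12), st.integers(0, 12)), max_size=40))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_symmetric_and_bounded_on_random_graphs(self, edge_ints):
        net = build_network(
            [(f"n{a}", f"n{b}") for a, b in edge_ints if a != b] + [("s", "t")]
        )
        nodes = sorted(net.proteins)
        for i in range(0, len(nodes) - 1, 2):
            pair = ProteinPair(nodes[i], nodes[i + 1])
            score = fs_weight(net, pair)
            assert 0.0 <= score < 1.0
            # symmetry is baked into the unordered pair; check both argument orders
            assert fs_weight(net, ProteinPair(nodes[i + 1], nodes[i])) == score

    def test_new_common_neighbor_never_decreases_score(self):
        edges = [("x", "a"), ("x", "b"), ("y", "b"), ("y", "c")]
        before = fs_weight(build_network(edges), ProteinPair("x", "y"))
        after = fs_weight(
            build_network(edges + [("x", "w"), ("y", "w")]), ProteinPair("x", "y")
        )
        assert after >= before


class TestGeneExpressionCorr:
    def test_identical_profiles(self, expression_matrix):
        assert gene_expression_corr(
            expression_matrix, ProteinPair("up", "up2")
        ) == pytest.approx(1.0)

    def test_perfect_anticorrelation_scores_one(self, expression_matrix):
        # (1,2,3) vs (3,2,1): Pearson -1, absolute value 1
        assert gene_expression_corr(
            expression_matrix, ProteinPair("up", "down")
        ) == pytest.approx(1.0)

    def test_zero_variance_scores_zero_with_warning(self, expression_matrix, caplog):
        with caplog.at_level(logging.WARNING):
            score = gene_expression_corr(expression_matrix, ProteinPair("flat", "up"))
        assert score == 0.0
        assert "zero-variance" in caplog.text

    def test_missing_protein_is_absent(self, expression_matrix):
        assert gene_expression_corr(expression_matrix, ProteinPair("up", "nope")) is None

    @given(
        st.floats(min_value=0.1, max_value=10),
        st.floats(min_value=-5, max_value=5),
        st.booleans(),
    )
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_affine_invariance(self, slope, offset, negate):
        base_expr = pd.DataFrame(
            {"c1": [1.0, 2.0], "c2": [2.0, 4.0], "c3": [3.0, 7.0]},
            index=["up", "up2"],
        )
        expr = base_expr.copy()
        factor = -slope if negate else slope
        expr.loc["up"] = expr.loc["up"] * factor + offset
        base = gene_expression_corr(base_expr, ProteinPair("up", "up2"))
        assert gene_expression_corr(expr, ProteinPair("up", "up2")) == pytest.approx(base)


class TestDomainInteractionScore:
    def test_single_interacting_pair(self):
        dd = DomainData({"x": frozenset({"d1", "d2"}), "y": frozenset({"d3"})},
                        {("d1", "d3")})
        assert domain_interaction_score(dd, ProteinPair("x", "y")) == 1

    def test_homodomain_pair(self):
        dd = DomainData({"x": frozenset({"d1"}), "y": frozenset({"d1"})},
                        {("d1", "d1")})
        assert domain_interaction_score(dd, ProteinPair("x", "y")) == 1

    def test_ordered_combinations_counted(self, domain_data):
        # D_x={d1,d2}, D_y={d1,d3}, ddi={(d1,d1),(d2,d3),(d1,d2)} -> 3
        assert domain_interaction_score(domain_data, ProteinPair("x", "y")) == 3

    def test_unannotated_protein_scores_zero(self, domain_data):
        assert domain_interaction_score(domain_data, ProteinPair("x", "nope")) == 0

    @given(st.data())
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_bruteforce_enumeration(self, data):
        domains = [f"d{i}" for i in range(6)]
        dx = data.draw(st.frozensets(st.sampled_from(domains), max_size=4))
        dy = data.draw(st.frozensets(st.sampled_from(domains), max_size=4))
        ddi_pairs = data.draw(
            st.sets(st.tuples(st.sampled_from(domains), st.sampled_from(domains)),
                    max_size=8)
        )
        ddi = {canonical_domain_pair(a, b) for a, b in ddi_pairs}
        dd = DomainData({"x": dx, "y": dy}, ddi)
        expected = sum(
            1
            for di in dx
            for dj in dy
            if (di, dj) in ddi_pairs_closure(ddi)
        )
        assert domain_interaction_score(dd, ProteinPair("x", "y")) == expected


def ddi_pairs_closure(ddi):
    """Both orientations of each unordered DDI pair (independent oracle)."""
    closure = set()
    for a, b in ddi:
        closure.add((a, b))
        closure.add((b, a))
    return closure


class TestCompileEvidenceTable:
    def test_computed_channel_matches_operation(self, asymmetric_net):
        pairs = [ProteinPair("x", "y"), ProteinPair("a", "b"), ProteinPair("a", "c")]
        table = compile_evidence_table(
            pairs, [ChannelSpec("fs_weight", "computed")], net=asymmetric_net
        )
        assert table.data.shape == (3, 1)
        for p in pairs:
            assert table.data.loc[p, "fs_weight"] == fs_weight(asymmetric_net, p)

    def test_ingested_coverage_reported(self):
        pairs = [ProteinPair("a", "b"), ProteinPair("a", "c"), ProteinPair("b", "c")]
        scores = pd.Series({pairs[0]: 1.0, pairs[1]: 2.0})
        table = compile_evidence_table(pairs, [ChannelSpec("irap", "ingested", scores)])
        assert table.coverage["irap"] == pytest.approx(2 / 3)
        assert np.isnan(table.data.loc[pairs[2], "irap"])
        assert table.filled().loc[pairs[2], "irap"] == 0.0

    def test_empty_pair_list_is_fine(self, asymmetric_net):
        table = compile_evidence_table(
            [], [ChannelSpec("fs_weight", "computed")], net=asymmetric_net
        )
        assert len(table.pairs) == 0

    def test_unknown_channel_lists_available(self, asymmetric_net):
        with pytest.raises(ValueError, match="fs_weight"):
            compile_evidence_table(
                [], [ChannelSpec("bogus", "computed")], net=asymmetric_net
            )
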