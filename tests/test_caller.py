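"""Motif calling rules: micro-examples, invariances, brute-force equivalence."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from graphsv.caller import (
    call_all,
    call_square,
    call_tandem_duplications,
    call_triangle,
    outliers_of,
)
from graphsv.foldchange import LFCTable

from conftest import collapsed_from_edges
from oracles import brute_calls, brute_median, brute_outliers, brute_pop_sd


def lfc_table(node_rows, edge_rows=None, log_base=2.0):
    """Build an LFCTable directly from per-step dicts."""
    steps = range(1, len(node_rows) + 1)
    node = pd.DataFrame(list(node_rows), index=list(steps))
    if edge_rows is None:
        edge = pd.DataFrame(index=list(steps))
    else:
        edge = pd.DataFrame(
            [{f"{min(u,v)}--{max(u,v)}": x for (u, v), x in row.items()} for row in edge_rows],
            index=list(steps),
        )
    return LFCTable(node_lfc=node, edge_lfc=edge, log_base=log_base)


class TestOutliers:
    @pytest.mark.parametrize(
        "values,expected_idx",
        [
            ([1.0, 1.0, 1.0], ()),
            ([0.0, 0.1, 2.0], (2,)),
            ([-1.0, 0.0, 1.0], (0, 2)),
            ([-2.0, 0.0, 0.1], (0,)),
            ([0.0, 0.0, 3.0, 0.0], (2,)),
            ([2.0, 0.0, -2.0, 0.1], (0, 2)),
        ],
    )
    def test_examples_match_independent_arithmetic(self, values, expected_idx):
        res = outliers_of(values)
        oracle_idx, oracle_med, oracle_sd = brute_outliers(values)
        assert res.outliers == expected_idx == oracle_idx
        assert res.median == pytest.approx(oracle_med)
        assert res.sd == pytest.approx(oracle_sd)

    def test_population_sd_values(self):
        res = outliers_of([0.0, 0.1, 2.0])
        assert res.median == pytest.approx(0.1)
        assert res.sd == pytest.approx(brute_pop_sd([0.0, 0.1, 2.0]))
        assert res.sd == pytest.approx(0.9202, abs=1e-4)

    def test_median_of_four_is_mean_of_middle_two(self):
        res = outliers_of([0.0, 10.0, 2.0, 4.0])
        assert res.median == pytest.approx(3.0)
        assert res.median == pytest.approx(brute_median([0.0, 10.0, 2.0, 4.0]))

    def test_sample_sd_option_shrinks_outlier_set(self):
        # population sd flags both extremes; sample sd flags neither
        values = [2.0, 2.1, -2.0, -2.1]
        assert outliers_of(values, ddof=0).outliers == (1, 3)
        assert outliers_of(values, ddof=1).outliers == ()

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        values=st.lists(
            st.floats(min_value=-4, max_value=4).map(lambda v: round(v, 2)),
            min_size=3,
            max_size=4,
        ),
        shift=st.floats(min_value=-10, max_value=10),
    )
    def test_location_invariance(self, values, shift):
        """Adding a constant to every value leaves outlier status unchanged.

        Values sitting exactly one sd from the median are excluded: there
        the strict comparison is decided by round-off, not by the rule.
        """
        from hypothesis import assume

        base = outliers_of(values)
        assume(
            all(abs(abs(v - base.median) - base.sd) > 1e-6 for v in values)
        )
        shifted = outliers_of([v + shift for v in values])
        assert base.outliers == shifted.outliers


class TestTriangleRule:
    def test_single_high_outlier_calls_insertion(self):
        call = call_triangle(["a", "b", "c"], {"a": 0.0, "b": 0.1, "c": 2.0}, 1)
        assert call is not None
        assert call.sv_type == "insertion"
        assert call.called_nodes == ("c",)
        assert call.motif == "triangle"

    def test_single_low_outlier_calls_deletion(self):
        call = call_triangle(["a", "b", "c"], {"a": -2.0, "b": 0.0, "c": 0.1}, 1)
        assert call is not None
        assert call.sv_type == "deletion"
        assert call.called_nodes == ("a",)

    def test_two_outliers_decline_to_call(self):
        assert call_triangle(["a", "b", "c"], {"a": -1.0, "b": 0.0, "c": 1.0}, 1) is None

    def test_constant_values_no_call(self):
        assert call_triangle(["a", "b", "c"], {"a": 0.5, "b": 0.5, "c": 0.5}, 1) is None

    def test_series_reversal_swaps_insertion_and_deletion(self):
        lfc = {"a": 0.0, "b": 0.1, "c": 2.0}
        fwd = call_triangle(["a", "b", "c"], lfc, 1)
        rev = call_triangle(["a", "b", "c"], {k: -v for k, v in lfc.items()}, 1)
        assert fwd.sv_type == "insertion"
        assert rev.sv_type == "deletion"
        assert fwd.called_nodes == rev.called_nodes


class TestSquareRule:
    def test_single_outlier_calls_complex_indel(self):
        call = call_square(("a", "b", "c", "d"), {"a": 0, "b": 0, "c": 3.0, "d": 0}, 1)
        assert call is not None
        assert call.sv_type == "complex_indel"
        assert call.called_nodes == ("c",)

    def test_two_opposite_straddling_outliers_call_both(self):
        lfc = {"a": 2.0, "b": 0.0, "c": -2.0, "d": 0.1}
        call = call_square(("a", "b", "c", "d"), lfc, 1)
        assert call is not None
        assert call.called_nodes == ("a", "c")
        idx, med, sd = brute_outliers([2.0, 0.0, -2.0, 0.1])
        assert idx == (0, 2)
        assert sd == pytest.approx(1.4149, abs=1e-4)

    def test_two_opposite_symmetric_extremes_call(self):
        # median 0, population sd ~2.0506: the +/-2.1 pair lies just beyond
        # one sd at opposite cycle positions, straddling the median
        values = {"a": 2.0, "b": 2.1, "c": -2.0, "d": -2.1}
        idx, med, sd = brute_outliers([2.0, 2.1, -2.0, -2.1])
        assert idx == (1, 3)
        call = call_square(("a", "b", "c", "d"), values, 1)
        assert call is not None
        assert call.called_nodes == ("b", "d")

    def test_two_adjacent_outliers_no_call(self):
        values = [5.0, -5.0, 0.1, 0.0]
        idx, _, _ = brute_outliers(values)
        assert idx == (0, 1)  # adjacent in the cycle
        assert call_square(("a", "b", "c", "d"), dict(zip("abcd", values)), 1) is None

    def test_two_outliers_same_side_no_call(self):
        # both outliers above the median cannot be a deletion+insertion pair
        values = {"a": 0.0, "b": 5.0, "c": 0.2, "d": 5.2}
        call = call_square(("a", "b", "c", "d"), values, 1)
        idx, med, _ = brute_outliers([0.0, 5.0, 0.2, 5.2])
        if len(idx) == 2:
            assert call is None


class TestDuplicationRule:
    def graph(self):
        return collapsed_from_edges(
            [("a", "a"), ("a", "b"), ("b", "c", 2)], lengths={}
        )

    def test_self_loop_above_threshold_called(self):
        lfc = lfc_table(
            [{"a": 0.0, "b": 0.0, "c": 0.0}],
            [{("a", "a"): math.log2(5 / 2), ("a", "b"): 0.0, ("b", "c"): 0.0}],
        )
        calls = call_tandem_duplications(
            self.graph(), lfc.node_lfc.loc[1], lfc.edge_lfc.loc[1], [], 1
        )
        assert [c.called_nodes for c in calls] == [("a",)]
        assert calls[0].motif == "self_loop"

    def test_boundary_lfc_exactly_one_not_called(self):
        lfc = lfc_table(
            [{"a": 0.0, "b": 0.0, "c": 0.0}],
            [{("a", "a"): 1.0, ("a", "b"): 0.0, ("b", "c"): 0.0}],
        )
        calls = call_tandem_duplications(
            self.graph(), lfc.node_lfc.loc[1], lfc.edge_lfc.loc[1], [], 1
        )
        assert calls == []

    def test_parallel_edge_picks_greater_node_lfc(self):
        lfc = lfc_table(
            [{"a": 0.0, "b": 0.2, "c": 0.9}],
            [{("a", "a"): 0.0, ("a", "b"): 0.0, ("b", "c"): 1.5}],
        )
        calls = call_tandem_duplications(
            self.graph(), lfc.node_lfc.loc[1], lfc.edge_lfc.loc[1], [], 1
        )
        assert [c.called_nodes for c in calls] == [("c",)]
        assert calls[0].motif == "parallel_edge"

    def test_equal_node_lfc_breaks_tie_lexicographically(self):
        lfc = lfc_table(
            [{"a": 0.0, "b": 0.5, "c": 0.5}],
            [{("a", "a"): 0.0, ("a", "b"): 0.0, ("b", "c"): 2.0}],
        )
        calls = call_tandem_duplications(
            self.graph(), lfc.node_lfc.loc[1], lfc.edge_lfc.loc[1], [], 1
        )
        assert calls[0].called_nodes == ("b",)

    def test_weight_one_edge_never_duplication(self):
        lfc = lfc_table(
            [{"a": 0.0, "b": 0.0, "c": 0.0}],
            [{("a", "a"): 0.0, ("a", "b"): 3.0, ("b", "c"): 0.0}],
        )
        calls = call_tandem_duplications(
            self.graph(), lfc.node_lfc.loc[1], lfc.edge_lfc.loc[1], [], 1
        )
        assert calls == []

    def test_precedence_skips_already_called_node(self):
        from graphsv.caller import SVCall

        prior = SVCall(
            sv_type="insertion",
            step_pair=1,
            called_nodes=("c",),
            motif="triangle",
            motif_nodes=("a", "b", "c"),
            median=0.0,
            sd=0.1,
            outlier_lfc=(2.0,),
            score=2.0,
        )
        lfc = lfc_table(
            [{"a": 0.0, "b": 0.2, "c": 0.9}],
            [{("a", "a"): 0.0, ("a", "b"): 0.0, ("b", "c"): 1.5}],
        )
        calls = call_tandem_duplications(
            self.graph(), lfc.node_lfc.loc[1], lfc.edge_lfc.loc[1], [prior], 1
        )
        assert calls == []


class TestCallAll:
    def test_empty_graph_empty_calls(self):
        g = collapsed_from_edges([("a", "b")])
        lfc = lfc_table([{"a": 0.0, "b": 0.0}], [{("a", "b"): 0.0}])
        assert call_all(g, lfc).calls == []

    def test_double_bubble_merges_to_one_call_with_support_two(self):
        """A node in two triangles flagging the same SV yields one call."""
        g = collapsed_from_edges(
            [("f1", "v"), ("v", "f2"), ("f1", "f2"), ("f3", "v"), ("v", "f4"), ("f3", "f4")]
        )
        lfc = lfc_table(
            [{"f1": 0.0, "f2": 0.0, "f3": 0.0, "f4": 0.0, "v": 2.0}],
            [{("f1", "v"): 0, ("v", "f2"): 0, ("f1", "f2"): 0, ("f3", "v"): 0, ("v", "f4"): 0, ("f3", "f4"): 0}],
        )
        result = call_all(g, lfc)
        ins = [c for c in result.calls if c.sv_type == "insertion"]
        assert len(ins) == 1
        assert ins[0].called_nodes == ("v",)
        assert ins[0].support == 2
        assert result.motif_counts[1]["triangle"] == 2

    def test_location_invariance_of_full_caller(self):
        g = collapsed_from_edges(
            [("f1", "v"), ("v", "f2"), ("f1", "f2")]
        )
        rows = {"f1": 0.3, "f2": 0.3, "v": -1.7}
        shifted = {k: v + 5.0 for k, v in rows.items()}
        edge = [{("f1", "v"): 0, ("v", "f2"): 0, ("f1", "f2"): 0}]
        base = call_all(g, lfc_table([rows], edge)).calls
        moved = call_all(g, lfc_table([shifted], edge)).calls
        assert [(c.sv_type, c.called_nodes) for c in base] == [
            (c.sv_type, c.called_nodes) for c in moved
        ]


@settings(max_examples=60, deadline=None, derandomize=True)
@given(data=st.data())
def test_call_all_matches_brute_force_on_random_graphs(data):
    """Full caller agrees with a direct scan of triples/quadruples/edges."""
    n = data.draw(st.integers(min_value=3, max_value=10))
    nodes = [f"n{i:02d}" for i in range(n)]
    pairs = [(a, b) for i, a in enumerate(nodes) for b in nodes[i + 1 :]]
    chosen = data.draw(st.sets(st.sampled_from(pairs), min_size=1, max_size=len(pairs)))
    edges = {}
    for u, v in sorted(chosen):
        edges[(u, v)] = data.draw(st.integers(min_value=1, max_value=3))
    for node in nodes[: data.draw(st.integers(min_value=0, max_value=2))]:
        edges[(node, node)] = 1
    grid = st.floats(min_value=-3, max_value=3).map(lambda v: round(v * 4) / 4)
    node_vals = {node: data.draw(grid) for node in nodes}
    edge_vals = {key: data.draw(grid) for key in edges}
    g = collapsed_from_edges([(u, v, w) for (u, v), w in edges.items()])
    lfc = lfc_table([node_vals], [edge_vals])
    result = call_all(g, lfc)
    got = {(c.sv_type, c.step_pair, frozenset(c.called_nodes)) for c in result.calls}
    expected = brute_calls(
        set(g.nodes()), edges, {1: node_vals}, {1: {k: v for k, v in edge_vals.items()}}, [1]
    )
    assert got == expected
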