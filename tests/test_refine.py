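"""Post-processing refinements: splits, promotions, truncation, conflicts."""

import itertools
import random

import networkx as nx
import pytest

from consegs import ConfigParams
from consegs.diagonals import Diagonal, Homology, detect_diagonals
from consegs.refine import (
    RefinementTrace,
    greedy_max_weight_selection,
    identify_micro_rearrangements,
    identify_monogenic_segments,
    merge_truncated_extremities,
    refine_pipeline,
    replay_trace,
    segments_from_diagonals,
    solve_conflict_graph,
    truncate_overlaps,
)

from helpers import brute_force_mwis, cells_matrix, random_cells

PAIR = ("c", "c")


def diag(cells, origin="block"):
    return Diagonal(PAIR, [Homology(*c) for c in cells], origin=origin)


def chains(diags):
    return sorted(tuple((c.i, c.j) for c in d.cells) for d in diags)


# a long + diagonal hosting a completely nested - block, a nested - cell,
# and an adjacent - cell
NESTED_HOST_CELLS = [
    (0, 0, 1), (1, 1, 1), (2, 3, -1), (3, 2, -1), (4, 4, 1),
    (5, 5, 1), (6, 6, -1), (7, 7, 1), (8, 8, -1),
]

# partial nesting: a 2-cell block nested in the host's rows only
PARTIAL_NEST_CELLS = [
    (0, 0, 1), (1, 1, 1), (4, 2, 1), (5, 3, 1), (2, 6, 1), (3, 7, 1),
]


class TestMicroRearrangements:
    def test_completely_nested_block_splits_host(self):
        m = cells_matrix([Homology(*c) for c in NESTED_HOST_CELLS])
        diags = detect_diagonals(m, 2)
        out = identify_micro_rearrangements(diags, imr_gap=1)
        sizes = sorted(d.n for d in out if d.origin != "isolated")
        # host [0,1,4,5,7] split around the nested - block into [0,1] and
        # [4,5,7]; the nested - cells at (6,6) and (8,8) stay isolated here
        assert ((0, 0), (1, 1)) in chains(out)
        assert any(
            tuple((c.i, c.j) for c in d.cells) == ((2, 3), (3, 2))
            for d in out
        )

    def test_partially_nested_block_gives_three_diagonals(self):
        m = cells_matrix([Homology(*c) for c in PARTIAL_NEST_CELLS])
        diags = detect_diagonals(m, 2)
        assert len(diags) == 2  # host bridges its gap, nested block separate
        out = identify_micro_rearrangements(diags, imr_gap=1)
        assert chains(out) == [
            ((0, 0), (1, 1)),
            ((2, 6), (3, 7)),
            ((4, 2), (5, 3)),
        ]

    def test_disjoint_diagonals_unchanged(self):
        a = diag([(0, 0, 1), (1, 1, 1)])
        b = diag([(5, 5, 1), (6, 6, 1)])
        out = identify_micro_rearrangements([a, b], imr_gap=2)
        assert chains(out) == chains([a, b])

    def test_extremity_gap_threshold_gates_the_split(self):
        # nested block far from the host homologies: only a large imr gap
        # identifies it
        cells = [
            (0, 0, 1), (1, 1, 1), (8, 8, 1), (9, 9, 1),
            (3, 5, -1), (4, 4, -1),
        ]
        m = cells_matrix([Homology(*c) for c in cells])
        diags = detect_diagonals(m, 6)
        strict = identify_micro_rearrangements(diags, imr_gap=0)
        loose = identify_micro_rearrangements(diags, imr_gap=3)
        assert len(strict) == len(diags)
        assert len(loose) == len(diags) + 1


class TestMonogenic:
    def test_nested_and_adjacent_opposite_cells_promoted(self):
        m = cells_matrix([Homology(*c) for c in NESTED_HOST_CELLS])
        diags = detect_diagonals(m, 2)
        diags = identify_micro_rearrangements(diags, imr_gap=1)
        out = identify_monogenic_segments(diags, imcs_width=1)
        monos = sorted(
            (d.first.i, d.first.j) for d in out if d.origin == "mono"
        )
        assert monos == [(6, 6), (8, 8)]
        # the host piece around (6,6) was split: (7,7) now stands alone
        assert ((7, 7),) in chains(out)

    def test_same_sign_isolated_cell_not_promoted(self):
        cells = [(0, 0, 1), (1, 1, 1), (3, 3, 1)]
        diags = detect_diagonals(cells_matrix([Homology(*c) for c in cells]), 0)
        out = identify_monogenic_segments(diags, imcs_width=2)
        assert all(d.origin != "mono" for d in out)

    def test_width_zero_without_nesting_is_identity(self):
        a = diag([(0, 0, 1), (1, 1, 1)])
        lone = diag([(5, 8, -1)], origin="isolated")
        out = identify_monogenic_segments([a, lone], imcs_width=0)
        assert lone.origin == "isolated"
        assert chains(out) == chains([a, lone])


class TestTruncation:
    def test_small_overlap_truncated_from_poorer_diagonal(self):
        long = diag([(0, 0, 1), (1, 1, 1), (2, 2, 1), (3, 3, 1)])
        short = diag([(3, 4, 1), (4, 5, 1)])
        out = truncate_overlaps([long, short], truncation_max=2)
        assert chains(out) == [
            ((0, 0), (1, 1), (2, 2), (3, 3)),
            ((4, 5),),
        ]
        trimmed = next(d for d in out if d.n == 1)
        assert trimmed.trunc_head and not trimmed.trunc_tail

    def test_large_overlap_left_to_conflict_graph(self):
        a = diag([(i, i, 1) for i in range(6)])
        b = diag([(i, i + 1, 1) for i in range(6)])
        out = truncate_overlaps([a, b], truncation_max=2)
        assert chains(out) == chains([a, b])

    def test_tie_breaks_truncate_the_later_diagonal(self):
        # equal homology counts in region and overall: the diagonal later in
        # deterministic order loses its overlap cells
        a = diag([(1, 2, -1), (2, 1, -1)])
        b = diag([(3, 2, 1), (4, 3, 1)])
        out = truncate_overlaps([a, b], truncation_max=1)
        assert chains(out) == [((1, 2), (2, 1)), ((4, 3),)]

    def test_kept_configuration_maximises_retained_homologies(self):
        # brute force over both truncation choices: the implementation keeps
        # the configuration retaining the most homologies
        long = diag([(0, 0, 1), (1, 1, 1), (2, 2, 1), (3, 3, 1)])
        short = diag([(3, 4, 1), (4, 5, 1)])
        out = truncate_overlaps([long, short], truncation_max=2)
        kept = sum(d.n for d in out)
        alternatives = []
        for loser, winner in ((long, short), (short, long)):
            region = [
                pos
                for pos, c in enumerate(loser.cells)
                if c.i == 3  # the shared index on axis 1
            ]
            alternatives.append(
                winner.n + (loser.n - len(region))
            )
        assert kept == max(alternatives)


class TestRepair:
    def test_truncation_then_merge_repairs_the_rupture(self):
        d1 = diag([(0, 0, 1), (1, 1, 1), (2, 2, 1), (3, 3, 1)])
        d2 = diag([(3, 4, 1), (4, 5, 1)])
        trace = RefinementTrace()
        out = truncate_overlaps([d1, d2], truncation_max=2, trace=trace)
        out = merge_truncated_extremities(out, gap_max=1, trace=trace)
        assert chains(out) == [((0, 0), (1, 1), (2, 2), (3, 3), (4, 5))]

    def test_without_truncation_nothing_merges(self):
        d1 = diag([(0, 0, 1), (1, 1, 1)])
        d2 = diag([(3, 3, 1), (4, 4, 1)])
        out = merge_truncated_extremities([d1, d2], gap_max=2)
        assert chains(out) == chains([d1, d2])

    def test_opposite_signs_never_merge(self):
        d1 = diag([(0, 0, 1), (1, 1, 1)])
        d1.trunc_tail = True
        d2 = diag([(3, 3, -1), (4, 2, -1)])
        out = merge_truncated_extremities([d1, d2], gap_max=3)
        assert len(out) == 2


class TestConflictGraph:
    def test_heavier_diagonal_wins(self):
        a = diag([(i, i, 1) for i in range(5)])
        b = diag([(i, i + 1, 1) for i in range(3)])
        out = solve_conflict_graph([a, b])
        assert out == [a]

    def test_path_graph_greedy_is_suboptimal_but_maximal(self):
        # A(3) - B(4) - C(3): greedy keeps only B (weight 4) although {A, C}
        # weighs 6 -- a maximal but not maximum independent set
        g = nx.path_graph(3)
        weight = {0: 3, 1: 4, 2: 3}
        selected = greedy_max_weight_selection(g, weight)
        assert selected == [1]
        assert brute_force_mwis(g, weight) == 6

    def test_no_overlaps_is_identity(self):
        a = diag([(0, 0, 1), (1, 1, 1)])
        b = diag([(5, 5, 1), (6, 6, 1)])
        assert solve_conflict_graph([a, b]) == [a, b]

    def test_greedy_against_brute_force_on_random_graphs(self):
        rng = random.Random(31)
        for _ in range(250):
            n = rng.randint(1, 10)
            g = nx.Graph()
            g.add_nodes_from(range(n))
            for u, v in itertools.combinations(range(n), 2):
                if rng.random() < 0.35:
                    g.add_edge(u, v)
            weight = {k: rng.randint(1, 9) for k in range(n)}
            sel = greedy_max_weight_selection(g, weight)
            assert all(
                not g.has_edge(u, v)
                for u, v in itertools.combinations(sel, 2)
            ), "selection must be independent"
            assert all(
                any(g.has_edge(x, s) for s in sel)
                for x in g.nodes
                if x not in sel
            ), "selection must be maximal"
            assert sum(weight[s] for s in sel) <= brute_force_mwis(g, weight)


class TestPipeline:
    def test_all_flags_disabled_returns_diagonals_verbatim(self):
        m = cells_matrix([Homology(*c) for c in NESTED_HOST_CELLS])
        diags = detect_diagonals(m, 2)
        params = ConfigParams(
            gap_max=2,
            imr_gap=None,
            imcs_width=None,
            truncation_max=None,
            report_isolated=True,
        )
        segments = refine_pipeline(diags, m, params)
        assert len(segments) == len(diags)
        assert sorted(s.n_homologies for s in segments) == sorted(
            d.n for d in diags
        )

    def test_empty_matrix_gives_no_segments(self):
        m = cells_matrix([Homology(0, 0, 1)])
        m.cells.clear()
        assert refine_pipeline([], m, ConfigParams()) == []

    def test_non_overlap_of_final_segments(self):
        rng = random.Random(77)
        for _ in range(40):
            cells = random_cells(rng, max_cells=20, size=12)
            m = cells_matrix(cells)
            diags = detect_diagonals(m, rng.randint(0, 2))
            segments = refine_pipeline(diags, m, ConfigParams())
            for axis in (1, 2):
                covered = set()
                for seg in segments:
                    span = seg.span1 if axis == 1 else seg.span2
                    indices = set(range(span[1], span[2]))
                    assert not (indices & covered)
                    covered |= indices

    def test_trace_replay_reproduces_output(self):
        rng = random.Random(55)
        for _ in range(40):
            cells = random_cells(rng, max_cells=20, size=12)
            m = cells_matrix(cells)
            diags = detect_diagonals(m, 2)
            trace = RefinementTrace()
            params = ConfigParams(gap_max=2)
            segments = refine_pipeline(diags, m, params, trace=trace)
            replayed = replay_trace(trace, diags)
            replayed = [d for d in replayed if d.origin != "isolated"]
            assert segments_from_diagonals(replayed, m) == segments

    def test_refinements_never_decrease_segment_count(self):
        rng = random.Random(88)
        for _ in range(30):
            cells = random_cells(rng, max_cells=18, size=12)
            diags = detect_diagonals(cells_matrix(cells), 2)
            after_imr = identify_micro_rearrangements(list(diags), 1)
            assert len(after_imr) >= len(diags)
            after_imcs = identify_monogenic_segments(list(after_imr), 1)
            assert len(after_imcs) >= len(after_imr)
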