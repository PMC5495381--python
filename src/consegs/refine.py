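"""Post-processing of diagonals into non-overlapping conserved segments.

Four refinements turn raw synteny-block diagonals into conserved segments:

1. *identify micro-rearrangements* -- a diagonal completely nested (both
   axes) or partially nested (one axis) inside a gap of a host diagonal marks
   a micro-rearrangement: the host is split at the insertion point;
2. *identify mono-genic conserved segments* -- a single-cell homology nested
   in a host's gap with the opposite sign, or lying within a small
   neighbourhood of an opposite-sign diagonal, is a mono-genic inversion:
   the cell is promoted to a segment and a nesting host is split around it;
3. *solve overlaps* -- small overlaps (<= truncationMax) are resolved by
   truncating the overlap cells from the homology-poorer diagonal; remaining
   overlaps go to a conflict graph solved greedily by repeatedly keeping the
   homology-richest diagonal;
4. *repair incorrect ruptures* -- truncated extremities are re-merged with
   facing diagonals when the merged chain is a valid diagonal, undoing
   spurious breaks caused by local ordering ambiguities.

Every decision is logged in a :class:`RefinementTrace`; replaying the trace
on the input diagonals reproduces the output exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx

from .model import UNKNOWN, ConfigParams, ConservedSegment
from .diagonals import (
    Diagonal,
    HomologyMatrix,
    WILDCARD,
    chebyshev_gap,
    merge_gap,
)


@dataclass
class RefinementTrace:
    """Ordered log of refinement decisions, sufficient to replay them."""

    records: list[dict] = field(default_factory=list)

    def log(self, **record) -> None:
        self.records.append(record)


# ---------------------------------------------------------------------------
# geometry helpers

def _bracket_link(host: Diagonal, lo: int, hi: int, axis: int) -> int | None:
    """Chain link ``k`` of ``host`` whose gap strictly brackets ``[lo, hi]``
    on the given axis (1 = genome-1 index, 2 = genome-2 index)."""
    vals = [c.i if axis == 1 else c.j for c in host.cells]
    for k in range(len(vals) - 1):
        low, high = sorted((vals[k], vals[k + 1]))
        if low < lo and hi < high:
            return k
    return None


def _nesting(inner: Diagonal, host: Diagonal) -> tuple[list[int], int] | None:
    """Axes on which ``inner`` is nested in a single gap of ``host`` and the
    chain link at which to split.  Returns None when not nested at all."""
    b = inner.bbox
    axes: list[int] = []
    link = None
    if inner.chrom_pair[0] == host.chrom_pair[0]:
        k = _bracket_link(host, b[0], b[1], axis=1)
        if k is not None:
            axes.append(1)
            link = k
    if inner.chrom_pair[1] == host.chrom_pair[1]:
        k = _bracket_link(host, b[2], b[3], axis=2)
        if k is not None:
            axes.append(2)
            if link is None:
                link = k
    if not axes:
        return None
    return axes, link


def _extremity_gap(inner: Diagonal, host: Diagonal, axes: list[int]) -> int:
    """Largest, over the two extremities of ``inner``, of the gap to the
    nearest host homology, measured on the nesting axes only (for a partially
    nested block the other axis lies elsewhere in the genome)."""

    def cell_gap(cell) -> int:
        best = None
        for h in host.cells:
            ds = []
            if 1 in axes:
                ds.append(abs(h.i - cell.i) - 1)
            if 2 in axes:
                ds.append(abs(h.j - cell.j) - 1)
            d = max(ds)
            if best is None or d < best:
                best = d
        return best

    return max(cell_gap(inner.first), cell_gap(inner.last))


def _split(host: Diagonal, link: int) -> tuple[Diagonal, Diagonal]:
    left = host.replace_cells(
        host.cells[: link + 1], trunc_tail=False, origin="block"
    )
    right = host.replace_cells(
        host.cells[link + 1 :], trunc_head=False, origin="block"
    )
    return left, right


def _axis_overlap(a: Diagonal, b: Diagonal, axis: int) -> int:
    """Number of shared gene indices of the two bounding boxes on one axis
    (0 when on different chromosomes or disjoint)."""
    if a.chrom_pair[axis - 1] != b.chrom_pair[axis - 1]:
        return 0
    ba, bb = a.bbox, b.bbox
    (lo_a, hi_a) = (ba[0], ba[1]) if axis == 1 else (ba[2], ba[3])
    (lo_b, hi_b) = (bb[0], bb[1]) if axis == 1 else (bb[2], bb[3])
    return max(0, min(hi_a, hi_b) - max(lo_a, lo_b) + 1)


def _overlap_zone(a: Diagonal, b: Diagonal, axis: int) -> tuple[int, int]:
    ba, bb = a.bbox, b.bbox
    (lo_a, hi_a) = (ba[0], ba[1]) if axis == 1 else (ba[2], ba[3])
    (lo_b, hi_b) = (bb[0], bb[1]) if axis == 1 else (bb[2], bb[3])
    return max(lo_a, lo_b), min(hi_a, hi_b)


def _region_cells(d: Diagonal, other: Diagonal) -> list[int]:
    """Chain positions of ``d`` whose cell falls in the overlap zone with
    ``other`` on any overlapping axis."""
    zones = []
    for axis in (1, 2):
        if _axis_overlap(d, other, axis) > 0:
            zones.append((axis, *_overlap_zone(d, other, axis)))
    positions = []
    for pos, cell in enumerate(d.cells):
        for axis, lo, hi in zones:
            v = cell.i if axis == 1 else cell.j
            if lo <= v <= hi:
                positions.append(pos)
                break
    return positions


def diagonals_overlap(a: Diagonal, b: Diagonal) -> bool:
    """Overlap of the orthogonal bounding-box projections on either genome
    axis (including diagonals of different chromosome pairs sharing one
    chromosome)."""
    return _axis_overlap(a, b, 1) > 0 or _axis_overlap(a, b, 2) > 0


# ---------------------------------------------------------------------------
# 1. micro-rearrangements

def identify_micro_rearrangements(
    diags: list[Diagonal],
    imr_gap: int,
    trace: RefinementTrace | None = None,
) -> list[Diagonal]:
    """Split hosts around nested micro-rearranged material.

    Two passes: multi-cell diagonals completely or partially nested within a
    gap of a host are identified first, then isolated homologies completely
    nested (both axes) in a gap of a host are promoted to mono-genic segments
    and their hosts split around them.  Each extremity of the nested material
    must be within a gap of ``imr_gap`` of the nearest host homology,
    measured on the nesting axes.
    """
    trace = trace if trace is not None else RefinementTrace()
    work = _split_nested_blocks(diags, imr_gap, trace)
    return _split_nested_cells(work, imr_gap, trace)


def _split_nested_blocks(
    diags: list[Diagonal], imr_gap: int, trace: RefinementTrace
) -> list[Diagonal]:
    work = list(diags)
    while True:
        candidate = None
        for host in sorted(work, key=Diagonal.sort_key):
            if host.n < 2 or host.origin == "mono":
                continue
            for inner in sorted(work, key=Diagonal.sort_key):
                if inner is host or inner.n < 2 or inner.origin == "mono":
                    continue
                nest = _nesting(inner, host)
                if nest is None:
                    continue
                axes, link = nest
                if _extremity_gap(inner, host, axes) > imr_gap:
                    continue
                candidate = (host, inner, link)
                break
            if candidate:
                break
        if candidate is None:
            return work
        host, inner, link = candidate
        left, right = _split(host, link)
        trace.log(
            op="split",
            host=host.uid,
            nested=inner.uid,
            cut=link,
            out=[left.uid, right.uid],
        )
        work = [d for d in work if d is not host] + [left, right]


def _split_nested_cells(
    diags: list[Diagonal], imr_gap: int, trace: RefinementTrace
) -> list[Diagonal]:
    """Isolated homologies completely nested within gaps of a host diagonal
    are micro-rearrangements of one gene: all hosts are split at the union of
    insertion links (evaluated against the entry snapshot, so neighbouring
    nested cells in consecutive gaps are all identified)."""
    work = list(diags)
    hosts = sorted(
        (d for d in work if d.n >= 2 and d.origin != "mono"),
        key=Diagonal.sort_key,
    )
    cells = sorted(
        (d for d in work if d.n == 1 and d.origin == "isolated"),
        key=Diagonal.sort_key,
    )
    cuts: dict[int, set[int]] = {}
    host_by_uid = {h.uid: h for h in hosts}
    for cell_diag in cells:
        cell = cell_diag.first
        for host in hosts:
            if host.chrom_pair != cell_diag.chrom_pair:
                continue
            k1 = _bracket_link(host, cell.i, cell.i, axis=1)
            k2 = _bracket_link(host, cell.j, cell.j, axis=2)
            if k1 is None or k2 is None:
                continue
            if _extremity_gap(cell_diag, host, [1, 2]) > imr_gap:
                continue
            cell_diag.origin = "mono"
            cuts.setdefault(host.uid, set()).add(k1)
            trace.log(op="promote_cell", cell=cell_diag.uid, host=host.uid)
            break
    for uid, links in sorted(cuts.items()):
        host = host_by_uid[uid]
        pieces = _split_multi(host, sorted(links))
        trace.log(
            op="split_multi",
            host=uid,
            cuts=sorted(links),
            out=[p.uid for p in pieces],
        )
        work = [d for d in work if d is not host] + pieces
    return work


def _split_multi(host: Diagonal, links: list[int]) -> list[Diagonal]:
    pieces = []
    start = 0
    bounds = [*links, host.n - 1]
    for idx, link in enumerate(bounds):
        cells = host.cells[start : link + 1]
        piece = host.replace_cells(cells, origin="block")
        if idx > 0:
            piece.trunc_head = False
        if idx < len(bounds) - 1:
            piece.trunc_tail = False
        pieces.append(piece)
        start = link + 1
    pieces[0].trunc_head = host.trunc_head
    pieces[-1].trunc_tail = host.trunc_tail
    return pieces


# ---------------------------------------------------------------------------
# 2. mono-genic conserved segments

def identify_monogenic_segments(
    diags: list[Diagonal],
    imcs_width: int,
    trace: RefinementTrace | None = None,
) -> list[Diagonal]:
    """Promote isolated single-cell homologies to mono-genic conserved
    segments.

    A cell is promoted when (a) it is completely nested in a gap of a
    diagonal whose sign is opposite to the cell's (the host is then split
    around it), or (b) its gap to the nearest homology of an opposite-sign
    diagonal is at most ``imcs_width``.  Rule (b) uniformly covers the
    neighbourhood of bounding-box edges and of the matrix edges.
    """
    trace = trace if trace is not None else RefinementTrace()
    work = list(diags)
    cells = sorted(
        (d for d in work if d.n == 1 and d.origin == "isolated"),
        key=Diagonal.sort_key,
    )
    for cell_diag in cells:
        cell = cell_diag.first
        if cell.sign == WILDCARD:
            continue
        promoted = False
        # (a) complete nesting with opposite sign
        for host in sorted(work, key=Diagonal.sort_key):
            if (
                host.n < 2
                or host.origin == "mono"
                or host.chrom_pair != cell_diag.chrom_pair
                or host.sign != -cell.sign
            ):
                continue
            k1 = _bracket_link(host, cell.i, cell.i, axis=1)
            k2 = _bracket_link(host, cell.j, cell.j, axis=2)
            if k1 is None or k2 is None:
                continue
            cell_diag.origin = "mono"
            left, right = _split(host, k1)
            trace.log(
                op="promote_nested",
                cell=cell_diag.uid,
                host=host.uid,
                cut=k1,
                out=[left.uid, right.uid],
            )
            work = [d for d in work if d is not host] + [left, right]
            promoted = True
            break
        if promoted:
            continue
        # (b) neighbourhood of an opposite-sign diagonal
        for other in sorted(work, key=Diagonal.sort_key):
            if (
                other is cell_diag
                or other.chrom_pair != cell_diag.chrom_pair
                or other.sign != -cell.sign
            ):
                continue
            gap = min(chebyshev_gap(cell, h) for h in other.cells)
            if gap <= imcs_width:
                cell_diag.origin = "mono"
                trace.log(
                    op="promote_adjacent",
                    cell=cell_diag.uid,
                    neighbor=other.uid,
                )
                break
    return work


# ---------------------------------------------------------------------------
# 3a. truncation of small overlaps

def truncate_overlaps(
    diags: list[Diagonal],
    truncation_max: int,
    trace: RefinementTrace | None = None,
) -> list[Diagonal]:
    """Resolve overlaps of at most ``truncation_max`` gene indices by
    removing the overlap cells from the diagonal with the fewest homologies
    in the overlapping region (ties: fewest homologies overall, then the
    diagonal later in deterministic order).

    Only extremity overlaps are truncated (the removed cells must form a
    prefix or suffix of the losing chain); containments are left to the
    conflict graph.
    """
    trace = trace if trace is not None else RefinementTrace()
    work = list(diags)
    while True:
        action = None
        ordered = sorted(work, key=Diagonal.sort_key)
        for a, b in combinations(ordered, 2):
            ov1 = _axis_overlap(a, b, 1)
            ov2 = _axis_overlap(a, b, 2)
            if ov1 == 0 and ov2 == 0:
                continue
            if ov1 > truncation_max or ov2 > truncation_max:
                continue
            reg_a = _region_cells(a, b)
            reg_b = _region_cells(b, a)
            if not reg_a and not reg_b:
                continue
            if len(reg_a) != len(reg_b):
                loser, winner, region = (
                    (a, b, reg_a) if len(reg_a) < len(reg_b) else (b, a, reg_b)
                )
            elif a.n != b.n:
                loser, winner, region = (
                    (a, b, reg_a) if a.n < b.n else (b, a, reg_b)
                )
            else:
                loser, winner, region = b, a, reg_b
            if not region:
                continue
            is_prefix = region == list(range(len(region)))
            is_suffix = region == list(
                range(loser.n - len(region), loser.n)
            )
            if not (is_prefix or is_suffix):
                continue
            action = (loser, winner, region, is_prefix)
            break
        if action is None:
            return work
        loser, winner, region, is_prefix = action
        keep = [
            c for pos, c in enumerate(loser.cells) if pos not in set(region)
        ]
        if keep:
            new = loser.replace_cells(keep)
            if is_prefix:
                new.trunc_head = True
            else:
                new.trunc_tail = True
            trace.log(
                op="truncate",
                diag=loser.uid,
                end="head" if is_prefix else "tail",
                n_removed=len(region),
                out=new.uid,
                winner=winner.uid,
            )
            work = [d for d in work if d is not loser] + [new]
        else:
            trace.log(
                op="truncate",
                diag=loser.uid,
                end="head" if is_prefix else "tail",
                n_removed=len(region),
                out=None,
                winner=winner.uid,
            )
            work = [d for d in work if d is not loser]


# ---------------------------------------------------------------------------
# 4. repairing incorrect ruptures

def merge_truncated_extremities(
    diags: list[Diagonal],
    gap_max: int,
    trace: RefinementTrace | None = None,
) -> list[Diagonal]:
    """Merge pairs of diagonals across a truncated extremity when the merged
    chain is a valid diagonal with gaps <= ``gap_max``, eliminating false
    conserved-segment extremities created by local ordering ambiguities."""
    trace = trace if trace is not None else RefinementTrace()
    work = list(diags)
    while True:
        best = None
        for a in work:
            if a.origin == "mono":
                continue
            for b in work:
                if b is a or b.origin == "mono":
                    continue
                if not (a.trunc_tail or b.trunc_head):
                    continue
                gap = merge_gap(a, b, gap_max)
                if gap is None:
                    continue
                key = (gap, a.sort_key(), b.sort_key())
                if best is None or key < best[0]:
                    best = (key, a, b)
        if best is None:
            return work
        _, a, b = best
        merged = Diagonal(a.chrom_pair, a.cells + b.cells, origin="block")
        merged.trunc_head = a.trunc_head
        merged.trunc_tail = b.trunc_tail
        trace.log(op="repair_merge", a=a.uid, b=b.uid, out=merged.uid)
        work = [d for d in work if d is not a and d is not b] + [merged]


# ---------------------------------------------------------------------------
# 3b. conflict graph

def greedy_max_weight_selection(
    graph: nx.Graph, weight: dict, tie_key: dict | None = None
) -> list:
    """Greedy resolution of a conflict graph: repeatedly select the heaviest
    vertex, discard its neighbours, and auto-select vertices that become
    isolated, until the graph is empty.  Returns the selected vertices.

    The result is a maximal independent set but not necessarily a maximum-
    weight one.
    """
    g = graph.copy()
    tie_key = tie_key or {}
    selected = []
    while g.number_of_nodes():
        isolated = sorted(
            (n for n, deg in g.degree() if deg == 0),
            key=lambda n: tie_key.get(n, n),
        )
        if isolated:
            selected.extend(isolated)
            g.remove_nodes_from(isolated)
            continue
        pick = min(
            g.nodes, key=lambda n: (-weight[n], tie_key.get(n, n))
        )
        neighbors = list(g.neighbors(pick))
        selected.append(pick)
        g.remove_nodes_from([pick, *neighbors])
    return selected


def solve_conflict_graph(
    diags: list[Diagonal],
    trace: RefinementTrace | None = None,
) -> list[Diagonal]:
    """Select a set of pairwise non-overlapping diagonals: vertices are
    overlapping diagonals, edges are overlaps, and the homology-richest
    vertex is kept at each step."""
    trace = trace if trace is not None else RefinementTrace()
    by_uid = {d.uid: d for d in diags}
    graph = nx.Graph()
    for a, b in combinations(sorted(diags, key=Diagonal.sort_key), 2):
        if diagonals_overlap(a, b):
            graph.add_edge(a.uid, b.uid)
    if graph.number_of_nodes() == 0:
        return list(diags)
    weight = {uid: by_uid[uid].n for uid in graph.nodes}
    tie_key = {uid: by_uid[uid].sort_key() for uid in graph.nodes}
    selected = set(
        greedy_max_weight_selection(graph, weight, tie_key)
    )
    kept = [
        d for d in diags if d.uid not in graph.nodes or d.uid in selected
    ]
    trace.log(
        op="conflict",
        kept=[d.uid for d in kept],
        discarded=[d.uid for d in diags if d.uid in graph.nodes - selected],
    )
    return kept


# ---------------------------------------------------------------------------
# the workflow

def refine_pipeline(
    diags: list[Diagonal],
    matrix: HomologyMatrix,
    params: ConfigParams,
    trace: RefinementTrace | None = None,
) -> list[ConservedSegment]:
    """Apply the enabled refinements in workflow order and convert surviving
    diagonals to conserved segments in original input coordinates.

    The truncation flag also governs rupture repair and the conflict graph
    (a disabled overlap resolution returns the detected diagonals verbatim,
    overlaps included).
    """
    trace = trace if trace is not None else RefinementTrace()
    work = list(diags)
    if params.imr_gap is not None:
        work = identify_micro_rearrangements(work, params.imr_gap, trace)
    if params.imcs_width is not None:
        work = identify_monogenic_segments(work, params.imcs_width, trace)
    if params.truncation_max is not None:
        work = truncate_overlaps(work, params.truncation_max, trace)
        work = merge_truncated_extremities(work, params.gap_max, trace)
        work = solve_conflict_graph(work, trace)
    if not params.report_isolated:
        work = [d for d in work if d.origin != "isolated"]
    return segments_from_diagonals(work, matrix)


def segments_from_diagonals(
    diags: list[Diagonal], matrix: HomologyMatrix
) -> list[ConservedSegment]:
    """Convert diagonals to :class:`ConservedSegment` records; families are
    listed in genome-1 order with genome-1 orientations, spans are half-open
    intervals in original input coordinates."""
    segments = []
    for diag in sorted(diags, key=Diagonal.sort_key):
        c1, c2 = diag.chrom_pair
        ax1 = matrix.axis1_of(c1)
        ax2 = matrix.axis2_of(c2)
        families: list[tuple[str, int]] = []
        for cell in diag.cells:
            orient = ax1.orientations[cell.i]
            if orient == UNKNOWN:
                o2 = ax2.orientations[cell.j]
                orient = diag.sign * o2 if o2 != UNKNOWN else UNKNOWN
            families.append((ax1.families[cell.i], orient))
        b = diag.bbox
        segments.append(
            ConservedSegment(
                families=families,
                span1=(c1, ax1.orig_index[b[0]], ax1.orig_index[b[1]] + 1),
                span2=(c2, ax2.orig_index[b[2]], ax2.orig_index[b[3]] + 1),
                sign=diag.sign,
                n_homologies=diag.n,
                origin=diag.origin,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# trace replay (auditability)

def replay_trace(
    trace: RefinementTrace, initial: list[Diagonal]
) -> list[Diagonal]:
    """Re-apply a trace to the detector's diagonals; the result reproduces
    the refined diagonals exactly."""
    current: dict[int, Diagonal] = {}
    for d in initial:
        clone = d.replace_cells(list(d.cells))
        clone.origin = d.origin if d.origin != "mono" else "isolated"
        object.__setattr__(clone, "uid", d.uid)
        current[d.uid] = clone
    for rec in trace.records:
        op = rec["op"]
        if op in ("split", "promote_nested"):
            host = current.pop(rec["host"])
            left, right = _split(host, rec["cut"])
            object.__setattr__(left, "uid", rec["out"][0])
            object.__setattr__(right, "uid", rec["out"][1])
            current[left.uid] = left
            current[right.uid] = right
            if op == "promote_nested":
                current[rec["cell"]].origin = "mono"
        elif op in ("promote_adjacent", "promote_cell"):
            current[rec["cell"]].origin = "mono"
        elif op == "split_multi":
            host = current.pop(rec["host"])
            pieces = _split_multi(host, rec["cuts"])
            for piece, uid in zip(pieces, rec["out"]):
                object.__setattr__(piece, "uid", uid)
                current[uid] = piece
        elif op == "truncate":
            loser = current.pop(rec["diag"])
            m = rec["n_removed"]
            keep = loser.cells[m:] if rec["end"] == "head" else loser.cells[:-m]
            if rec["out"] is not None:
                new = loser.replace_cells(keep)
                if rec["end"] == "head":
                    new.trunc_head = True
                else:
                    new.trunc_tail = True
                object.__setattr__(new, "uid", rec["out"])
                current[new.uid] = new
        elif op == "repair_merge":
            a = current.pop(rec["a"])
            b = current.pop(rec["b"])
            merged = Diagonal(a.chrom_pair, a.cells + b.cells, origin="block")
            merged.trunc_head = a.trunc_head
            merged.trunc_tail = b.trunc_tail
            object.__setattr__(merged, "uid", rec["out"])
            current[merged.uid] = merged
        elif op == "conflict":
            kept = set(rec["kept"])
            current = {uid: d for uid, d in current.items() if uid in kept}
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown trace op {op!r}")
    return sorted(current.values(), key=Diagonal.sort_key)
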