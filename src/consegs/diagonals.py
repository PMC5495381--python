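"""Signed homology matrix and gapped consistent-diagonal detection.

The matrix of homologies of two genomes is sparse: a cell exists at ``(i, j)``
of a chromosome-pair sub-matrix when the two genes share a family.  The cell
sign is ``+1`` when both orientations are known and equal, ``-1`` when known
and opposite, and wildcard (0) when either is unknown (a collapsed
mixed-orientation cluster).

A consistent diagonal is a chain of cells with strictly increasing ``i`` and
strictly monotone ``j`` whose non-wildcard signs all equal the direction
(+1 ascending, -1 descending) and whose consecutive Chebyshev gaps are at most
``gapMax``.  Synteny blocks conserved in both lineages take this shape, with
non-null gaps arising from dispersed duplicates and data errors.

Detection is two-phase: maximal strict chains (consecutive gap 0) are seeded
in a single scan, then sign-compatible, order-consistent diagonals are merged
greedily, smallest gap first, with deterministic tie-breaking, until no merge
with gap <= gapMax applies.  Every homology belongs to at most one diagonal;
cells left out of multi-cell diagonals are returned as single-cell diagonals
for the later mono-genic calling step.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import count

from .model import UNKNOWN, FamilySet, Genome

WILDCARD = 0


@dataclass(frozen=True)
class Homology:
    """One cell of a chromosome-pair sub-matrix."""

    i: int
    j: int
    sign: int  # +1, -1 or 0 (wildcard)


@dataclass(frozen=True)
class ChromAxis:
    """Per-chromosome gene annotations along one matrix axis."""

    chrom_id: str
    gene_ids: tuple[str, ...]
    families: tuple[str | None, ...]
    orientations: tuple[int, ...]
    orig_index: tuple[int, ...]

    def __len__(self) -> int:
        return len(self.gene_ids)


class HomologyMatrix:
    """Sparse signed homology matrix, organised by chromosome pair.

    Chromosomes are ordered by decreasing gene count along both axes, the
    order in which the matrix is rendered.
    """

    def __init__(
        self,
        axis1: list[ChromAxis],
        axis2: list[ChromAxis],
        cells: dict[tuple[str, str], list[Homology]],
    ):
        self.axis1 = axis1
        self.axis2 = axis2
        self.cells = cells
        self._ax1 = {a.chrom_id: a for a in axis1}
        self._ax2 = {a.chrom_id: a for a in axis2}

    def axis1_of(self, chrom_id: str) -> ChromAxis:
        return self._ax1[chrom_id]

    def axis2_of(self, chrom_id: str) -> ChromAxis:
        return self._ax2[chrom_id]

    @property
    def n_homologies(self) -> int:
        return sum(len(v) for v in self.cells.values())

    def pair_order(self) -> list[tuple[str, str]]:
        order = []
        for a1 in self.axis1:
            for a2 in self.axis2:
                key = (a1.chrom_id, a2.chrom_id)
                if key in self.cells:
                    order.append(key)
        return order


def _axis(genome: Genome, fams: FamilySet) -> list[ChromAxis]:
    axes = []
    for chrom in genome.sorted_by_length():
        axes.append(
            ChromAxis(
                chrom.chrom_id,
                tuple(g.gene_id for g in chrom.genes),
                tuple(fams.family_of(g.gene_id) for g in chrom.genes),
                tuple(g.orientation for g in chrom.genes),
                tuple(chrom.orig_index),
            )
        )
    return axes


def homology_sign(orient1: int, orient2: int) -> int:
    if orient1 == UNKNOWN or orient2 == UNKNOWN:
        return WILDCARD
    return 1 if orient1 == orient2 else -1


def build_homology_matrix(
    g1: Genome, g2: Genome, fams: FamilySet
) -> HomologyMatrix:
    """One homology per same-family gene pair (cartesian within a family)."""
    axis1 = _axis(g1, fams)
    axis2 = _axis(g2, fams)
    cells: dict[tuple[str, str], list[Homology]] = {}
    for ax2 in axis2:
        index: dict[str, list[int]] = {}
        for j, fam in enumerate(ax2.families):
            if fam is not None:
                index.setdefault(fam, []).append(j)
        for ax1 in axis1:
            pair_cells = []
            for i, fam in enumerate(ax1.families):
                if fam is None:
                    continue
                for j in index.get(fam, ()):
                    pair_cells.append(
                        Homology(
                            i,
                            j,
                            homology_sign(
                                ax1.orientations[i], ax2.orientations[j]
                            ),
                        )
                    )
            if pair_cells:
                pair_cells.sort(key=lambda h: (h.i, h.j))
                cells[(ax1.chrom_id, ax2.chrom_id)] = pair_cells
    return HomologyMatrix(axis1, axis2, cells)


def chebyshev_gap(h1: Homology, h2: Homology) -> int:
    """Number of intervening genes between two homologies of one sub-matrix:
    the larger of the two per-axis intervening counts."""
    if h1.i == h2.i and h1.j == h2.j:
        raise ValueError("no gap between coincident homologies")
    return max(abs(h1.i - h2.i), abs(h1.j - h2.j)) - 1


_uid_counter = count()


@dataclass
class Diagonal:
    """A consistent chain of homologies on one chromosome pair.

    ``origin`` records how the diagonal came to be: ``'block'`` for (pieces
    of) multi-cell diagonals, ``'isolated'`` for single cells never chained,
    ``'mono'`` for cells promoted to mono-genic conserved segments.
    """

    chrom_pair: tuple[str, str]
    cells: list[Homology]
    origin: str = "block"
    trunc_head: bool = False
    trunc_tail: bool = False
    uid: int = field(default_factory=lambda: next(_uid_counter))

    @property
    def n(self) -> int:
        return len(self.cells)

    @property
    def first(self) -> Homology:
        return self.cells[0]

    @property
    def last(self) -> Homology:
        return self.cells[-1]

    @property
    def bbox(self) -> tuple[int, int, int, int]:
        js = [c.j for c in self.cells]
        return (self.cells[0].i, self.cells[-1].i, min(js), max(js))

    @property
    def direction(self) -> int | None:
        """Geometric direction; ``None`` when undetermined (single cell of
        unknown sign may join either direction, a signed single cell is bound
        to its sign)."""
        if len(self.cells) >= 2:
            return 1 if self.cells[1].j > self.cells[0].j else -1
        return self.cells[0].sign or None

    @property
    def nonzero_sign(self) -> int | None:
        """Common sign of the non-wildcard cells, None when all wildcard."""
        if not hasattr(self, "_nz"):
            object.__setattr__(
                self,
                "_nz",
                next((c.sign for c in self.cells if c.sign != WILDCARD), None),
            )
        return self._nz

    @property
    def sign(self) -> int:
        """Resolved diagonal sign (+1 or -1)."""
        nz = self.nonzero_sign
        if nz is not None:
            return nz
        d = self.direction
        return d if d is not None else 1

    def sort_key(self) -> tuple:
        b = self.bbox
        return (self.chrom_pair, b[0], b[2], b[1], b[3])

    def replace_cells(self, cells: list[Homology], **kwargs) -> "Diagonal":
        new = Diagonal(self.chrom_pair, cells, origin=self.origin)
        new.trunc_head = kwargs.get("trunc_head", self.trunc_head)
        new.trunc_tail = kwargs.get("trunc_tail", self.trunc_tail)
        if "origin" in kwargs:
            new.origin = kwargs["origin"]
        return new


def merge_gap(a: Diagonal, b: Diagonal, gap_max: int) -> int | None:
    """Gap of the merge ``a`` then ``b``, or None when the merge would break
    a diagonal invariant or exceed ``gap_max``."""
    if a.chrom_pair != b.chrom_pair:
        return None
    la, fb = a.last, b.first
    di = fb.i - la.i
    dj = fb.j - la.j
    if di < 1 or dj == 0:
        return None
    d = 1 if dj > 0 else -1
    if a.direction not in (None, d) or b.direction not in (None, d):
        return None
    if a.nonzero_sign not in (None, d) or b.nonzero_sign not in (None, d):
        return None
    gap = max(di, abs(dj)) - 1
    return gap if gap <= gap_max else None


def _seed_strict_chains(cells: list[Homology]) -> list[list[Homology]]:
    """Maximal strict chains (consecutive gap 0, uniform sign), scanning in
    (i, j) order.  A wildcard head tries the descending direction first, the
    same preference as the merge tie-break (smaller-j candidate wins)."""
    pos = {(c.i, c.j): c for c in cells}
    assigned: set[tuple[int, int]] = set()
    chains = []
    for cell in cells:
        if (cell.i, cell.j) in assigned:
            continue
        chain = [cell]
        assigned.add((cell.i, cell.j))
        if cell.sign == 1:
            dirs = (1,)
        elif cell.sign == -1:
            dirs = (-1,)
        else:
            dirs = (-1, 1)
        for d in dirs:
            while True:
                nxt = pos.get((chain[-1].i + 1, chain[-1].j + d))
                if (
                    nxt is None
                    or (nxt.i, nxt.j) in assigned
                    or nxt.sign not in (WILDCARD, d)
                ):
                    break
                chain.append(nxt)
                assigned.add((nxt.i, nxt.j))
            if len(chain) > 1:
                break
        chains.append(chain)
    return chains


def dump_matrix(
    matrix: HomologyMatrix, diagonals: list["Diagonal"], path
) -> None:
    """Write the matrix cells as TSV (``chrom1 chrom2 i j sign diagonal_id``)
    for visual inspection; cells outside any diagonal get id ``-1``."""
    owner: dict[tuple, int] = {}
    for k, diag in enumerate(sorted(diagonals, key=lambda d: d.sort_key())):
        for cell in diag.cells:
            owner[(diag.chrom_pair, cell.i, cell.j)] = k
    closer = getattr(path, "write", None)
    handle = path if closer else open(path, "w")
    try:
        for pair in matrix.pair_order():
            for cell in matrix.cells[pair]:
                sign = {1: "+1", -1: "-1", WILDCARD: "?"}[cell.sign]
                did = owner.get((pair, cell.i, cell.j), -1)
                handle.write(
                    f"{pair[0]}\t{pair[1]}\t{cell.i}\t{cell.j}\t{sign}\t{did}\n"
                )
    finally:
        if not closer:
            handle.close()


def detect_diagonals(
    matrix: HomologyMatrix, gap_max: int
) -> list[Diagonal]:
    """Chain homologies into maximal consistent diagonals with gaps <=
    ``gap_max``.  Deterministic: merges are applied smallest gap first with
    ties broken on bounding-box starts."""
    if gap_max < 0:
        raise ValueError("gap_max must be >= 0")
    out: list[Diagonal] = []
    for pair in matrix.pair_order():
        cells = matrix.cells[pair]
        diags = [
            Diagonal(pair, chain, origin="block" if len(chain) > 1 else "isolated")
            for chain in _seed_strict_chains(cells)
        ]
        while True:
            best = None
            for a in diags:
                for b in diags:
                    if a is b:
                        continue
                    gap = merge_gap(a, b, gap_max)
                    if gap is None:
                        continue
                    key = (gap, a.sort_key(), b.sort_key())
                    if best is None or key < best[0]:
                        best = (key, a, b)
            if best is None:
                break
            _, a, b = best
            merged = Diagonal(pair, a.cells + b.cells, origin="block")
            diags = [d for d in diags if d is not a and d is not b]
            diags.append(merged)
        out.extend(diags)
    out.sort(key=Diagonal.sort_key)
    return out
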