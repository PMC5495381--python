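"""Shared builders and independent oracles for the test suite.

The oracles here are deliberately naive, from-scratch executable
specifications (exhaustive search, single-step greedy with full
recomputation); they never share code with the implementation paths they
check.
"""

from __future__ import annotations

import itertools

from consegs.model import Chromosome, FamilySet, Genome, OrientedGene
from consegs.diagonals import ChromAxis, Homology, HomologyMatrix


def genome_from_tokens(species: str, *chromosomes: str) -> Genome:
    """Build a genome from strings like ``"A+ B- C+"`` (one per chromosome).
    Gene ids are ``<species>_<token>``."""
    chroms = []
    for k, chrom_tokens in enumerate(chromosomes):
        genes = []
        for token in chrom_tokens.split():
            name, orient = token[:-1], token[-1]
            genes.append(
                OrientedGene(f"{species}_{name}", 1 if orient == "+" else -1)
            )
        chroms.append(Chromosome(f"chr{k}", genes))
    return Genome(species, chroms)


def families_by_name(*genomes: Genome) -> FamilySet:
    """Families from the token naming convention of :func:`genome_from_tokens`:
    the family is the token up to the first dot (so ``C`` and ``C.a`` are one
    family)."""
    fams = FamilySet()
    for genome in genomes:
        for gid in genome.gene_ids():
            token = gid.split("_", 1)[1]
            fams.add(token.split(".")[0], gid)
    return fams


def matrix_pair(cells):
    """Two single-chromosome genomes whose homology matrix has exactly the
    given ``(i, j, sign)`` cells, one family per cell (genome 2 all +1, the
    cell sign is carried by genome 1)."""
    g1_rows = {}
    g2_rows = {}
    fams = FamilySet()
    for k, (i, j, sign) in enumerate(cells):
        fam = f"F{k}"
        g1_rows[i] = OrientedGene(f"x{k}", sign if sign != 0 else 1)
        g2_rows[j] = OrientedGene(f"y{k}", 1)
        fams.add(fam, f"x{k}")
        fams.add(fam, f"y{k}")
    g1 = Genome("s1", [Chromosome("c1", [g1_rows[i] for i in sorted(g1_rows)])])
    g2 = Genome("s2", [Chromosome("c2", [g2_rows[j] for j in sorted(g2_rows)])])
    return g1, g2, fams


def cells_matrix(cells) -> HomologyMatrix:
    """A HomologyMatrix with one chromosome pair holding exactly ``cells``."""
    n = 1 + max(max(c.i for c in cells), max(c.j for c in cells), 0)
    ax = ChromAxis(
        "c",
        tuple(f"g{k}" for k in range(n)),
        tuple(f"f{k}" for k in range(n)),
        tuple([1] * n),
        tuple(range(n)),
    )
    return HomologyMatrix(
        [ax], [ax], {("c", "c"): sorted(cells, key=lambda c: (c.i, c.j))}
    )


# ---------------------------------------------------------------------------
# oracle: naive diagonal chaining (single-step greedy, full recomputation)

def naive_detect(cells, gap_max):
    """Executable specification of gapped consistent-diagonal chaining:
    start from singleton cells, repeatedly apply the single smallest-gap
    order-consistent sign-compatible merge (deterministic tie-break on
    bounding-box starts), recomputing every candidate from the definitions at
    each step.  Returns chains as tuples of (i, j, sign)."""

    def direction(chain):
        if len(chain) >= 2:
            return 1 if chain[1].j > chain[0].j else -1
        return chain[0].sign or None

    def nonzero_sign(chain):
        return next((c.sign for c in chain if c.sign), None)

    def key(chain):
        js = [c.j for c in chain]
        return (chain[0].i, min(js), chain[-1].i, max(js))

    def merge_gap(a, b):
        la, fb = a[-1], b[0]
        di, dj = fb.i - la.i, fb.j - la.j
        if di < 1 or dj == 0:
            return None
        d = 1 if dj > 0 else -1
        if direction(a) not in (None, d) or direction(b) not in (None, d):
            return None
        if nonzero_sign(a) not in (None, d) or nonzero_sign(b) not in (None, d):
            return None
        gap = max(di, abs(dj)) - 1
        return gap if gap <= gap_max else None

    chains = [[c] for c in sorted(cells, key=lambda c: (c.i, c.j))]
    while True:
        best = None
        for a in chains:
            for b in chains:
                if a is b:
                    continue
                gap = merge_gap(a, b)
                if gap is None:
                    continue
                k = (gap, key(a), key(b))
                if best is None or k < best[0]:
                    best = (k, a, b)
        if best is None:
            return sorted(
                tuple((c.i, c.j, c.sign) for c in chain) for chain in chains
            )
        _, a, b = best
        chains = [c for c in chains if c is not a and c is not b] + [a + b]


def brute_force_mwis(graph, weight) -> int:
    """Maximum weight of an independent set, by exhaustive enumeration."""
    nodes = list(graph.nodes)
    best = 0
    for r in range(len(nodes) + 1):
        for sub in itertools.combinations(nodes, r):
            if all(
                not graph.has_edge(u, v)
                for u, v in itertools.combinations(sub, 2)
            ):
                best = max(best, sum(weight[n] for n in sub))
    return best


def brute_force_tandem_partition(positions, gap_max):
    """Partition of same-family positions by exhaustively closing the
    'separated by <= gap_max intervening genes' relation (union-find)."""
    parent = {p: p for p in positions}

    def find(p):
        while parent[p] != p:
            p = parent[p]
        return p

    for a, b in itertools.combinations(positions, 2):
        if abs(a - b) - 1 <= gap_max:
            parent[find(a)] = find(b)
    groups = {}
    for p in positions:
        groups.setdefault(find(p), []).append(p)
    return sorted(sorted(g) for g in groups.values())


def random_cells(rng, max_cells=12, size=10, wildcard_rate=0.1):
    """Random sparse signed matrix cells (at most one cell per coordinate)."""
    n = rng.randint(1, max_cells)
    seen = {}
    for _ in range(n):
        i, j = rng.randrange(size), rng.randrange(size)
        if (i, j) in seen:
            continue
        u = rng.random()
        sign = 0 if u < wildcard_rate else (1 if u < 0.55 + wildcard_rate / 2 else -1)
        seen[(i, j)] = Homology(i, j, sign)
    return list(seen.values())
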