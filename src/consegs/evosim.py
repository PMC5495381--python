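"""Genome-evolution simulator with ground-truth conserved segments.

An ancestral genome evolves along the two branches of a species tree under
chromosomal rearrangements (inversions, reciprocal translocations, fissions,
fusions) and genic events (tandem and dispersed duplications, deletions,
de novo births).  The simulator returns the two extant genomes, the gene
families (one family per ancestral gene) and the true conserved segments.

The registry of true segments follows the evolutionary definition: the
fragments of the ancestral genome after splitting at every rearrangement
breakpoint that separates ancestral genes (in either lineage) and after
removing every ancestral gene deleted in at least one lineage.  Fusions,
duplications and births do not alter conserved segments; a breakpoint falling
between non-ancestral genes cuts nothing; a segment once cut is never
re-joined, so rearrangements later undone still count.

Inversion lengths follow a discretised gamma law (shape 0.1, scale 800
genes, truncated at 1330 genes, renormalised over the truncated support),
heavily skewed toward micro-inversions: about half of all reversed segments
are mono-genic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import gamma as _gamma

from .model import (
    Chromosome,
    ConservedSegment,
    FamilySet,
    Genome,
    OrientedGene,
)
from . import io as cio


@dataclass(frozen=True)
class SimulationConfig:
    """Simulation parameters; event counts are per branch."""

    n_chromosomes: int = 4
    genes_per_chromosome: int = 250
    inversions: int = 50
    translocations: int = 5
    fissions: int = 2
    fusions: int = 2
    duplications: int = 30
    tandem_fraction: float = 0.6
    tandem_offset_max: int = 0
    dup_reversed_prob: float = 0.5
    deletions: int = 30
    births: int = 10
    inv_shape: float = 0.1
    inv_scale: float = 800.0
    inv_truncation: int = 1330
    #: allow rearrangement breakpoints at positions that are already
    #: conserved-segment boundaries.  Off by default: reused breakpoints
    #: produce "done and undone" rearrangements that leave no trace in the
    #: extant genomes, so ground truth would contain undetectable cuts.
    breakpoint_reuse: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_chromosomes,
            self.genes_per_chromosome,
            self.inversions,
            self.translocations,
            self.fissions,
            self.fusions,
            self.duplications,
            self.deletions,
            self.births,
            self.tandem_offset_max,
        )
        if any(c < 0 for c in counts):
            raise ValueError("counts must be >= 0")
        if self.inv_shape <= 0 or self.inv_scale <= 0:
            raise ValueError("gamma shape and scale must be > 0")
        if self.inv_truncation < 1:
            raise ValueError("truncation must be >= 1")
        if not 0.0 <= self.tandem_fraction <= 1.0:
            raise ValueError("tandem_fraction must be in [0, 1]")
        if not 0.0 <= self.dup_reversed_prob <= 1.0:
            raise ValueError("dup_reversed_prob must be in [0, 1]")


def inversion_length_pmf(cfg: SimulationConfig) -> np.ndarray:
    """Probability mass of inversion lengths 1..truncation: the gamma cdf
    increments, renormalised over the truncated support."""
    grid = np.arange(0, cfg.inv_truncation + 1)
    cdf = _gamma.cdf(grid, cfg.inv_shape, scale=cfg.inv_scale)
    pmf = np.diff(cdf)
    return pmf / pmf.sum()


def sample_inversion_length(
    cfg: SimulationConfig,
    rng: np.random.Generator,
    pmf: np.ndarray | None = None,
) -> int:
    if pmf is None:
        pmf = inversion_length_pmf(cfg)
    return int(rng.choice(np.arange(1, cfg.inv_truncation + 1), p=pmf))


@dataclass
class SimGene:
    """A gene in an evolving genome."""

    uid: str
    family: str | None  # None only transiently; births get fresh families
    orientation: int
    ancestral_original: bool  # the ancestral copy itself, not a duplicate


class TrueSegmentRegistry:
    """Partition of the surviving ancestral genes into conserved segments.

    Segments are ordered runs of ancestral genes (named by their family
    identifiers, which name ancestral genes).  ``cut`` splits a segment
    between two genes that are still consecutive in it; ``delete`` removes a
    gene, joining its neighbours without creating a breakpoint.  A segment is
    never re-joined once cut.
    """

    def __init__(self, ancestor: Genome):
        self._segments: list[list[str]] = []
        self._home: dict[str, int] = {}
        self._orientation: dict[str, int] = {}
        self._position: dict[str, tuple[str, int]] = {}
        self._by_pos: dict[str, list[str]] = {}
        for chrom in ancestor.chromosomes:
            seg = []
            for pos, gene in enumerate(chrom.genes):
                fam = gene.gene_id
                seg.append(fam)
                self._orientation[fam] = gene.orientation
                self._position[fam] = (chrom.chrom_id, pos)
            self._segments.append(seg)
            self._by_pos[chrom.chrom_id] = list(seg)
        self._reindex()

    def _reindex(self) -> None:
        self._home = {
            fam: k for k, seg in enumerate(self._segments) for fam in seg
        }

    def alive(self, family: str) -> bool:
        return family in self._home

    def adjacent(self, fam_a: str, fam_b: str) -> bool:
        """True when the two ancestral genes are currently consecutive in one
        segment (their adjacency is still intact)."""
        ka = self._home.get(fam_a)
        kb = self._home.get(fam_b)
        if ka is None or ka != kb:
            return False
        seg = self._segments[ka]
        return abs(seg.index(fam_a) - seg.index(fam_b)) == 1

    def ancestral_position(self, family: str) -> tuple[str, int]:
        return self._position[family]

    def silently_healable(self, fam_a: str, fam_b: str) -> bool:
        """True when making ``fam_a`` and ``fam_b`` physically adjacent would
        recreate a broken ancestral adjacency without leaving any trace in
        the extant genome: they sit on the same ancestral chromosome, their
        adjacency is cut, and every ancestral gene between them is dead."""
        if self.adjacent(fam_a, fam_b):
            return False
        ca, pa = self._position[fam_a]
        cb, pb = self._position[fam_b]
        if ca != cb:
            return False
        lo, hi = sorted((pa, pb))
        between = self._by_pos[ca][lo + 1 : hi]
        return all(fam not in self._home for fam in between)

    def cut(self, fam_a: str, fam_b: str) -> bool:
        """Split the segment holding ``fam_a`` and ``fam_b`` between them if
        they are currently consecutive in it; no-op otherwise."""
        ka = self._home.get(fam_a)
        kb = self._home.get(fam_b)
        if ka is None or kb is None or ka != kb:
            return False
        seg = self._segments[ka]
        pa, pb = seg.index(fam_a), seg.index(fam_b)
        if abs(pa - pb) != 1:
            return False
        at = max(pa, pb)
        left, right = seg[:at], seg[at:]
        self._segments[ka] = left
        self._segments.append(right)
        for fam in right:
            self._home[fam] = len(self._segments) - 1
        return True

    def delete(self, family: str) -> None:
        k = self._home.pop(family, None)
        if k is None:
            return
        self._segments[k].remove(family)

    def segments(self) -> list[list[str]]:
        return [list(s) for s in self._segments if s]

    def to_segments(self) -> list[ConservedSegment]:
        """True conserved segments with ancestral orientations and spans in
        ancestral coordinates (identical on both axes)."""
        out = []
        for seg in self._segments:
            if not seg:
                continue
            families = [(fam, self._orientation[fam]) for fam in seg]
            chrom, start = self._position[seg[0]]
            _, last = self._position[seg[-1]]
            span = (chrom, start, last + 1)
            out.append(
                ConservedSegment(
                    families=families,
                    span1=span,
                    span2=span,
                    sign=1,
                    n_homologies=len(seg),
                )
            )
        out.sort(key=lambda s: (s.span1[0], s.span1[1]))
        return out


@dataclass
class SimulationResult:
    ancestor: Genome
    s1: Genome
    s2: Genome
    families: FamilySet
    truth: TrueSegmentRegistry
    config: SimulationConfig
    event_log: list[tuple] = field(default_factory=list)
    #: per species, uid -> ancestral family for genes that are the ancestral
    #: copy itself (not duplicates or births); used for truth inspection
    originals: dict[str, dict[str, str]] = field(default_factory=dict)


class _Branch:
    """One evolving lineage: a list of chromosomes of :class:`SimGene`."""

    def __init__(self, name: str, ancestor: Genome):
        self.name = name
        self.counter = 0
        self.chromosomes: list[list[SimGene]] = []
        self.chrom_names: list[str] = []
        for chrom in ancestor.chromosomes:
            genes = [
                SimGene(
                    uid=f"{name}_{gene.gene_id}",
                    family=gene.gene_id,
                    orientation=gene.orientation,
                    ancestral_original=True,
                )
                for gene in chrom.genes
            ]
            self.chromosomes.append(genes)
            self.chrom_names.append(f"{name}_{chrom.chrom_id}")

    # -- helpers -----------------------------------------------------------
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def pick_chromosome(self, rng, min_len=1) -> int | None:
        eligible = [
            k for k, c in enumerate(self.chromosomes) if len(c) >= min_len
        ]
        if not eligible:
            return None
        weights = np.array(
            [len(self.chromosomes[k]) for k in eligible], dtype=float
        )
        return int(rng.choice(eligible, p=weights / weights.sum()))

    def pick_gene(self, rng) -> tuple[int, int] | None:
        total = self.n_genes()
        if total == 0:
            return None
        flat = int(rng.integers(total))
        for k, chrom in enumerate(self.chromosomes):
            if flat < len(chrom):
                return k, flat
            flat -= len(chrom)
        raise AssertionError  # pragma: no cover

    def fresh_chrom_name(self) -> str:
        self.counter += 1
        return f"{self.name}_n{self.counter}"

    def drop_empty(self) -> None:
        keep = [
            (n, c)
            for n, c in zip(self.chrom_names, self.chromosomes)
            if c
        ]
        self.chrom_names = [n for n, _ in keep]
        self.chromosomes = [c for _, c in keep]

    def to_genome(self) -> Genome:
        chroms = []
        for name, genes in zip(self.chrom_names, self.chromosomes):
            chroms.append(
                Chromosome(
                    name,
                    [OrientedGene(g.uid, g.orientation) for g in genes],
                )
            )
        return Genome(self.name, chroms)


def _register_breakpoint(
    registry: TrueSegmentRegistry, chrom: list[SimGene], gap: int
) -> None:
    """Record the effect of a physical breakpoint between chromosome
    positions ``gap-1`` and ``gap`` on the true segments.

    The nearest flanking genes that are ancestral originals still present in
    the registry define the ancestral adjacency being broken; if either flank
    is missing (chromosome end, or only non-ancestral genes on one side) or
    the two flanks are not consecutive in a registry segment (already broken
    material), nothing is cut.
    """
    left, right = _flanks(registry, chrom, gap)
    if left is None or right is None:
        return
    registry.cut(left, right)


def _flanks(
    registry: TrueSegmentRegistry, chrom: list[SimGene], gap: int
) -> tuple[str | None, str | None]:
    left = next(
        (
            g.family
            for g in reversed(chrom[:gap])
            if g.ancestral_original and registry.alive(g.family)
        ),
        None,
    )
    right = next(
        (
            g.family
            for g in chrom[gap:]
            if g.ancestral_original and registry.alive(g.family)
        ),
        None,
    )
    return left, right


def _fresh(
    registry: TrueSegmentRegistry, chrom: list[SimGene], gap: int
) -> bool:
    """A breakpoint position is fresh when it does not fall at an existing
    conserved-segment boundary: either a flank is missing (chromosome end /
    non-ancestral material) or the flanking ancestral pair is still
    adjacent."""
    left, right = _flanks(registry, chrom, gap)
    if left is None or right is None:
        return True
    return registry.adjacent(left, right)


def _junction_heals(
    registry: TrueSegmentRegistry,
    left: list[SimGene],
    right: list[SimGene],
    other_pairs: frozenset = frozenset(),
) -> bool:
    """Would joining these two runs create an adjacency of ancestral genes
    that is indistinguishable from conserved synteny -- either re-creating a
    broken ancestral adjacency, or converging on an adjacency the other
    lineage already carries?  Such junctions are breakpoint-reuse artefacts
    that leave no trace in the extant genomes."""
    x = next(
        (
            g.family
            for g in reversed(left)
            if g.ancestral_original and registry.alive(g.family)
        ),
        None,
    )
    y = next(
        (
            g.family
            for g in right
            if g.ancestral_original and registry.alive(g.family)
        ),
        None,
    )
    if x is None or y is None:
        return False
    if registry.adjacent(x, y):
        return False
    if registry.silently_healable(x, y):
        return True
    return frozenset((x, y)) in other_pairs


class _InfeasibleEvent(Exception):
    pass


def _apply_event(
    kind: str,
    branch: _Branch,
    registry: TrueSegmentRegistry,
    cfg: SimulationConfig,
    rng: np.random.Generator,
    pmf: np.ndarray,
    log: list,
    other_pairs: frozenset = frozenset(),
) -> None:
    if kind == "inversion":
        k = branch.pick_chromosome(rng, min_len=1)
        if k is None:
            raise _InfeasibleEvent
        chrom = branch.chromosomes[k]
        length = sample_inversion_length(cfg, rng, pmf)
        if length > len(chrom):
            raise _InfeasibleEvent
        start = int(rng.integers(0, len(chrom) - length + 1))
        # reversing only non-ancestral material does not alter conserved
        # segments, whatever the flanks of the breakpoints
        touches_ancestral = any(
            g.ancestral_original and registry.alive(g.family)
            for g in chrom[start : start + length]
        )
        if touches_ancestral:
            if not cfg.breakpoint_reuse:
                rev = chrom[start : start + length][::-1]
                if not (
                    _fresh(registry, chrom, start)
                    and _fresh(registry, chrom, start + length)
                ) or _junction_heals(
                    registry, chrom[:start], rev, other_pairs
                ) or _junction_heals(
                    registry, rev, chrom[start + length :], other_pairs
                ):
                    raise _InfeasibleEvent
            _register_breakpoint(registry, chrom, start)
            _register_breakpoint(registry, chrom, start + length)
        segment = chrom[start : start + length][::-1]
        for g in segment:
            g.orientation = -g.orientation
        chrom[start : start + length] = segment
        log.append((branch.name, "inversion", k, start, length))
    elif kind == "translocation":
        if len(branch.chromosomes) < 2:
            raise _InfeasibleEvent
        k1, k2 = (
            int(x) for x in rng.choice(len(branch.chromosomes), 2, replace=False)
        )
        c1, c2 = branch.chromosomes[k1], branch.chromosomes[k2]
        g1 = int(rng.integers(0, len(c1) + 1))
        g2 = int(rng.integers(0, len(c2) + 1))
        if not cfg.breakpoint_reuse:
            if not (_fresh(registry, c1, g1) and _fresh(registry, c2, g2)):
                raise _InfeasibleEvent
            if _junction_heals(
                registry, c1[:g1], c2[g2:], other_pairs
            ) or _junction_heals(registry, c2[:g2], c1[g1:], other_pairs):
                raise _InfeasibleEvent
        _register_breakpoint(registry, c1, g1)
        _register_breakpoint(registry, c2, g2)
        branch.chromosomes[k1] = c1[:g1] + c2[g2:]
        branch.chromosomes[k2] = c2[:g2] + c1[g1:]
        branch.drop_empty()
        log.append((branch.name, "translocation", k1, g1, k2, g2))
    elif kind == "fission":
        k = branch.pick_chromosome(rng, min_len=2)
        if k is None:
            raise _InfeasibleEvent
        chrom = branch.chromosomes[k]
        gap = int(rng.integers(1, len(chrom)))
        if not cfg.breakpoint_reuse and not _fresh(registry, chrom, gap):
            raise _InfeasibleEvent
        _register_breakpoint(registry, chrom, gap)
        branch.chromosomes[k] = chrom[:gap]
        branch.chromosomes.append(chrom[gap:])
        branch.chrom_names.append(branch.fresh_chrom_name())
        log.append((branch.name, "fission", k, gap))
    elif kind == "fusion":
        if len(branch.chromosomes) < 2:
            raise _InfeasibleEvent
        k1, k2 = (
            int(x) for x in rng.choice(len(branch.chromosomes), 2, replace=False)
        )
        tail = branch.chromosomes[k2]
        reverse_tail = rng.random() < 0.5
        if reverse_tail:
            tail = tail[::-1]
        if not cfg.breakpoint_reuse and _junction_heals(
            registry, branch.chromosomes[k1], tail, other_pairs
        ):
            raise _InfeasibleEvent
        if reverse_tail:
            for g in tail:
                g.orientation = -g.orientation
        branch.chromosomes[k1] = branch.chromosomes[k1] + tail
        del branch.chromosomes[k2]
        del branch.chrom_names[k2]
        log.append((branch.name, "fusion", k1, k2))
    elif kind == "duplication":
        picked = branch.pick_gene(rng)
        if picked is None:
            raise _InfeasibleEvent
        k, pos = picked
        source = branch.chromosomes[k][pos]
        branch.counter += 1
        orientation = source.orientation
        if rng.random() < cfg.dup_reversed_prob:
            orientation = -orientation
        copy = SimGene(
            uid=f"{branch.name}_d{branch.counter}",
            family=source.family,
            orientation=orientation,
            ancestral_original=False,
        )
        if rng.random() < cfg.tandem_fraction:
            offset = (
                int(rng.integers(0, cfg.tandem_offset_max + 1))
                if cfg.tandem_offset_max
                else 0
            )
            at = min(pos + 1 + offset, len(branch.chromosomes[k]))
            branch.chromosomes[k].insert(at, copy)
            log.append((branch.name, "tandem_dup", k, pos, at))
        else:
            kt = branch.pick_chromosome(rng)
            at = int(rng.integers(0, len(branch.chromosomes[kt]) + 1))
            branch.chromosomes[kt].insert(at, copy)
            log.append((branch.name, "dispersed_dup", k, pos, kt, at))
    elif kind == "deletion":
        picked = branch.pick_gene(rng)
        if picked is None:
            raise _InfeasibleEvent
        k, pos = picked
        gene = branch.chromosomes[k].pop(pos)
        if gene.ancestral_original:
            registry.delete(gene.family)
        branch.drop_empty()
        log.append((branch.name, "deletion", gene.uid))
    elif kind == "birth":
        branch.counter += 1
        copy = SimGene(
            uid=f"{branch.name}_b{branch.counter}",
            family=f"novo_{branch.name}_{branch.counter}",
            orientation=1 if rng.random() < 0.5 else -1,
            ancestral_original=False,
        )
        if not branch.chromosomes:
            raise _InfeasibleEvent
        k = branch.pick_chromosome(rng)
        at = int(rng.integers(0, len(branch.chromosomes[k]) + 1))
        branch.chromosomes[k].insert(at, copy)
        log.append((branch.name, "birth", copy.uid))
    else:  # pragma: no cover - defensive
        raise ValueError(kind)


def make_ancestor(cfg: SimulationConfig, rng: np.random.Generator) -> Genome:
    chroms = []
    idx = 0
    for c in range(cfg.n_chromosomes):
        genes = []
        for _ in range(cfg.genes_per_chromosome):
            genes.append(
                OrientedGene(f"g{idx:05d}", 1 if rng.random() < 0.5 else -1)
            )
            idx += 1
        chroms.append(Chromosome(f"anc{c}", genes))
    return Genome("ancestor", chroms)


def simulate_evolution(cfg: SimulationConfig) -> SimulationResult:
    """Evolve an ancestral genome along two branches and return extant
    genomes, families and the true conserved segments.

    Fully reproducible from ``cfg.seed``; an infeasible event (e.g. a fusion
    with a single chromosome left) is re-drawn, and a configuration for which
    an event stays infeasible after 100 retries is rejected.
    """
    rng = np.random.default_rng(cfg.seed)
    pmf = inversion_length_pmf(cfg)
    ancestor = make_ancestor(cfg, rng)
    registry = TrueSegmentRegistry(ancestor)
    log: list[tuple] = []

    branches = []
    other_pairs: frozenset = frozenset()
    for name in ("s1", "s2"):
        branch = _Branch(name, ancestor)
        events = (
            ["inversion"] * cfg.inversions
            + ["translocation"] * cfg.translocations
            + ["fission"] * cfg.fissions
            + ["fusion"] * cfg.fusions
            + ["duplication"] * cfg.duplications
            + ["deletion"] * cfg.deletions
            + ["birth"] * cfg.births
        )
        order = rng.permutation(len(events))
        for idx in order:
            kind = events[int(idx)]
            for attempt in range(100):
                try:
                    _apply_event(
                        kind, branch, registry, cfg, rng, pmf, log,
                        other_pairs,
                    )
                    break
                except _InfeasibleEvent:
                    continue
            else:
                raise ValueError(
                    f"event {kind!r} infeasible after 100 retries; "
                    "the configuration is too aggressive for the genome size"
                )
        branches.append(branch)
        other_pairs = _ancestral_neighbor_pairs(branch, registry)

    b1, b2 = branches
    # families are defined by ancestral genes of the MRCA; de novo birth
    # families are non-ancestral and stay out of the mapping
    ancestral = set(ancestor.gene_ids())
    fams = FamilySet()
    originals: dict[str, dict[str, str]] = {}
    for branch in branches:
        originals[branch.name] = {}
        for chrom in branch.chromosomes:
            for gene in chrom:
                if gene.family in ancestral:
                    fams.add(gene.family, gene.uid)
                if gene.ancestral_original:
                    originals[branch.name][gene.uid] = gene.family
    return SimulationResult(
        ancestor=ancestor,
        s1=b1.to_genome(),
        s2=b2.to_genome(),
        families=fams,
        truth=registry,
        config=cfg,
        event_log=log,
        originals=originals,
    )


def emit_benchmark_case(cfg: SimulationConfig, out_dir) -> dict[str, Path]:
    """Run a simulation and write the benchmark file set (genome TSVs,
    families TSV, truth segments TSV, config YAML).  Byte-identical across
    runs with the same configuration and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result = simulate_evolution(cfg)
    paths = {
        "ancestor": out / "ancestor.tsv",
        "s1": out / "s1.tsv",
        "s2": out / "s2.tsv",
        "families": out / "families.tsv",
        "truth": out / "truth_segments.tsv",
        "config": out / "config.yaml",
    }
    cio.write_genome(result.ancestor, paths["ancestor"])
    cio.write_genome(result.s1, paths["s1"])
    cio.write_genome(result.s2, paths["s2"])
    cio.write_families(result.families, paths["families"])
    cio.write_segments(
        result.truth.to_segments(), paths["truth"], extra_columns=True
    )
    with open(paths["config"], "w") as handle:
        yaml.safe_dump(asdict(cfg), handle, sort_keys=True)
    return paths


def load_config(path) -> SimulationConfig:
    with open(path) as handle:
        data = yaml.safe_load(handle) or {}
    return SimulationConfig(**data)


def _ancestral_neighbor_pairs(
    branch: _Branch, registry: TrueSegmentRegistry
) -> frozenset:
    """Unordered pairs of ancestral genes that are neighbours (up to
    non-ancestral or dead material) in a branch's extant genome."""
    pairs = set()
    for chrom in branch.chromosomes:
        run = [
            g.family
            for g in chrom
            if g.ancestral_original and registry.alive(g.family)
        ]
        for a, b in zip(run, run[1:]):
            pairs.add(frozenset((a, b)))
    return frozenset(pairs)
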