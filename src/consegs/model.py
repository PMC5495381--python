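"""Domain types for pairwise gene-order comparison.

Genomes are ordered lists of oriented genes grouped into chromosomes; gene
positions are implicit 0-based ranks, not base pairs.  Orientation is the
transcriptional direction relative to the chromosome reading order: ``+1``
when the 5'->3' direction points toward the last gene, ``-1`` otherwise.
The special value ``0`` (printed as ``?``) denotes an unknown orientation and
only ever arises from collapsing a mixed-orientation cluster of tandem
duplicates -- it is rejected in input files.

A family groups all genes descending from one ancestral gene of the most
recent common ancestor (MRCA) of the compared species; family identifiers
therefore name ancestral genes, which is what conserved segments are made of.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping

#: Sentinel orientation for collapsed clusters with conflicting member
#: orientations.
UNKNOWN = 0

_ALLOWED_ORIENTATIONS = (1, -1, UNKNOWN)


@dataclass(frozen=True)
class OrientedGene:
    """A gene identifier with its transcriptional orientation (+1, -1 or 0)."""

    gene_id: str
    orientation: int = 1

    def __post_init__(self) -> None:
        if self.orientation not in _ALLOWED_ORIENTATIONS:
            raise ValueError(
                f"orientation of {self.gene_id!r} must be +1, -1 or 0, "
                f"got {self.orientation!r}"
            )


@dataclass
class Chromosome:
    """An ordered list of oriented genes.

    ``orig_index`` maps each current gene rank back to the rank the gene had
    in the originally loaded chromosome, so spans of transformed genomes can
    be reported in input coordinates.  A freshly loaded chromosome maps every
    gene to itself.
    """

    chrom_id: str
    genes: list[OrientedGene] = field(default_factory=list)
    orig_index: list[int] | None = None

    def __post_init__(self) -> None:
        if self.orig_index is None:
            self.orig_index = list(range(len(self.genes)))
        if len(self.orig_index) != len(self.genes):
            raise ValueError("orig_index length must match gene count")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[OrientedGene]:
        return iter(self.genes)


@dataclass
class Genome:
    """A species label plus an ordered collection of chromosomes."""

    species: str
    chromosomes: list[Chromosome] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for chrom in self.chromosomes:
            for gene in chrom.genes:
                if gene.gene_id in seen:
                    raise ValueError(
                        f"duplicate gene_id {gene.gene_id!r} in genome "
                        f"{self.species!r}"
                    )
                seen.add(gene.gene_id)

    @property
    def n_genes(self) -> int:
        return sum(len(c) for c in self.chromosomes)

    def gene_ids(self) -> list[str]:
        return [g.gene_id for c in self.chromosomes for g in c.genes]

    def chromosome(self, chrom_id: str) -> Chromosome:
        for c in self.chromosomes:
            if c.chrom_id == chrom_id:
                return c
        raise KeyError(chrom_id)

    def sorted_by_length(self) -> list[Chromosome]:
        """Chromosomes by decreasing gene count (matrix rendering order)."""
        return sorted(
            self.chromosomes, key=lambda c: (-len(c), c.chrom_id)
        )


class FamilySet:
    """Mapping gene identifier -> family identifier.

    One family corresponds to one ancestral gene of the MRCA.  Genes absent
    from the mapping are non-ancestral (e.g. de novo births) and are removed
    by the pre-processing filter rather than rejected here.
    """

    def __init__(self, membership: Mapping[str, str] | None = None):
        self._membership: dict[str, str] = dict(membership or {})

    def __len__(self) -> int:
        return len(self._membership)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._membership

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, FamilySet)
            and self._membership == other._membership
        )

    def family_of(self, gene_id: str) -> str | None:
        return self._membership.get(gene_id)

    def add(self, family_id: str, gene_id: str) -> None:
        existing = self._membership.get(gene_id)
        if existing is not None and existing != family_id:
            raise ValueError(
                f"gene {gene_id!r} assigned to two families: "
                f"{existing!r} and {family_id!r}"
            )
        self._membership[gene_id] = family_id

    def items(self) -> Iterable[tuple[str, str]]:
        return self._membership.items()

    def families(self) -> set[str]:
        return set(self._membership.values())

    def families_in(self, genome: Genome) -> set[str]:
        fams = set()
        for gid in genome.gene_ids():
            fam = self._membership.get(gid)
            if fam is not None:
                fams.add(fam)
        return fams


@dataclass
class ConservedSegment:
    """A detected or true conserved segment.

    ``families`` lists the segment's (family, orientation) pairs in the order
    the genes appear along the reference axis (genome 1 for detected
    segments, the ancestral chromosome for true segments).  Orientation is the
    gene's orientation on that axis (0 when unknown).  Spans are half-open
    ``[start, end)`` rank intervals in original input coordinates.
    """

    families: list[tuple[str, int]]
    span1: tuple[str, int, int]
    span2: tuple[str, int, int]
    sign: int = 1
    n_homologies: int = 0
    origin: str = "block"  # 'block', 'mono' or 'isolated'

    def __post_init__(self) -> None:
        if not self.families:
            raise ValueError("a conserved segment holds at least one family")
        for span in (self.span1, self.span2):
            if span[2] <= span[1]:
                raise ValueError(f"empty span {span!r}")
        if self.n_homologies == 0:
            self.n_homologies = len(self.families)

    @property
    def monogenic(self) -> bool:
        return len(self.families) == 1


@dataclass(frozen=True)
class ConfigParams:
    """Tuning knobs of the detection pipeline.

    ``None`` disables the corresponding refinement (the "-" state of a
    benchmark configuration); an integer, even 0, means active.
    """

    gap_max: int = 2
    tandem_gap_max: int = 5
    truncation_max: int | None = 4
    imr_gap: int | None = 1
    imcs_width: int | None = 1
    #: apply the unshared-gene filter before collapsing tandem clusters
    #: (the default); the reverse order is exposed for sensitivity checks.
    filter_first: bool = True
    #: report isolated homologies that were never chained nor promoted as
    #: mono-genic segments.  Off by default: with duplicated genes, isolated
    #: cells are dominated by dispersed copies, so only sign-identified
    #: mono-genic segments are trustworthy.  On perfectly filtered
    #: (duplication-free) inputs every isolated homology is a true mono-genic
    #: conserved segment and reporting them is the correct choice.
    report_isolated: bool = False

    def __post_init__(self) -> None:
        if self.gap_max < 0 or self.tandem_gap_max < 0:
            raise ValueError("gapMax and tandemGapMax must be >= 0")
        for name in ("truncation_max", "imr_gap", "imcs_width"):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValueError(f"{name} must be >= 0 or None")

    def evolve(self, **kwargs) -> "ConfigParams":
        return replace(self, **kwargs)
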