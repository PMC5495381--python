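"""Pre-processing toward "perfectly filtered" genomes.

A perfectly filtered genome would contain exactly the ancestral genes
conserved in both compared species.  Two approximations are applied:

1. :func:`filter_unshared_genes` drops genes whose family has no member in
   the other genome (removes de novo births and genes whose only homolog was
   deleted);
2. :func:`collapse_clusters` rewrites each cluster of tandem duplicates to a
   single representative locus, because within such a cluster the ancestral
   copy cannot be told apart from its tandem duplicates.

Both keep an index mapping back to the input coordinates.  Collapsing is
orientation-dependent (the representative sits at the cluster's first gene,
which changes if the chromosome is read in reverse), but the two segment
extremities it produces are unaffected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import UNKNOWN, Chromosome, FamilySet, Genome, OrientedGene


def filter_unshared_genes(
    g1: Genome, g2: Genome, fams: FamilySet
) -> tuple[Genome, Genome]:
    """Keep only genes whose family has at least one member in the other
    genome.  Genes without a family are always removed.  Empty chromosomes
    are dropped; order and orientations are preserved."""
    fams1 = fams.families_in(g1)
    fams2 = fams.families_in(g2)
    return (
        _filter(g1, fams, fams2),
        _filter(g2, fams, fams1),
    )


def _filter(genome: Genome, fams: FamilySet, keep: set[str]) -> Genome:
    chroms = []
    for chrom in genome.chromosomes:
        genes, orig = [], []
        for pos, gene in enumerate(chrom.genes):
            fam = fams.family_of(gene.gene_id)
            if fam is not None and fam in keep:
                genes.append(gene)
                orig.append(chrom.orig_index[pos])
        if genes:
            chroms.append(Chromosome(chrom.chrom_id, genes, orig))
    return Genome(genome.species, chroms)


@dataclass
class Cluster:
    """A cluster of same-family genes on one chromosome (possibly a single
    gene).  ``members`` are ascending current indices; the representative sits
    at the smallest one."""

    family: str | None
    members: list[int]
    rep_orientation: int

    @property
    def rep_index(self) -> int:
        return self.members[0]


@dataclass
class TandemClustering:
    """Per-chromosome partition of gene indices into tandem clusters."""

    tandem_gap_max: int
    clusters: dict[str, list[Cluster]] = field(default_factory=dict)

    def n_nontrivial(self) -> int:
        return sum(
            1
            for cl in self.clusters.values()
            for c in cl
            if len(c.members) > 1
        )


def cluster_tandem_duplicates(
    genome: Genome, fams: FamilySet, tandem_gap_max: int
) -> TandemClustering:
    """Cluster same-family genes separated by at most ``tandem_gap_max``
    intervening genes (all genes count, whatever their family), chaining the
    relation transitively so arbitrarily long tandem arrays form one cluster.

    Genes without a family form singleton clusters.  The representative
    orientation is the members' common orientation, or unknown (0) when they
    disagree.
    """
    if tandem_gap_max < 0:
        raise ValueError("tandem_gap_max must be >= 0")
    clustering = TandemClustering(tandem_gap_max)
    for chrom in genome.chromosomes:
        by_family: dict[str, list[int]] = {}
        loners: list[Cluster] = []
        for pos, gene in enumerate(chrom.genes):
            fam = fams.family_of(gene.gene_id)
            if fam is None:
                loners.append(Cluster(None, [pos], gene.orientation))
            else:
                by_family.setdefault(fam, []).append(pos)
        clusters = loners
        for fam, positions in by_family.items():
            run = [positions[0]]
            for pos in positions[1:]:
                if pos - run[-1] - 1 <= tandem_gap_max:
                    run.append(pos)
                else:
                    clusters.append(_make_cluster(chrom, fam, run))
                    run = [pos]
            clusters.append(_make_cluster(chrom, fam, run))
        clusters.sort(key=lambda c: c.rep_index)
        clustering.clusters[chrom.chrom_id] = clusters
    return clustering


def _make_cluster(chrom: Chromosome, fam: str, members: list[int]) -> Cluster:
    orientations = {chrom.genes[m].orientation for m in members}
    rep = orientations.pop() if len(orientations) == 1 else UNKNOWN
    return Cluster(fam, list(members), rep)


def collapse_clusters(genome: Genome, clustering: TandemClustering) -> Genome:
    """Replace every cluster by one gene at the representative index with the
    representative orientation; remaining genes are re-indexed compactly."""
    chroms = []
    for chrom in genome.chromosomes:
        reps = {
            c.rep_index: c
            for c in clustering.clusters.get(chrom.chrom_id, [])
        }
        covered = {
            m
            for c in clustering.clusters.get(chrom.chrom_id, [])
            for m in c.members
        }
        genes, orig = [], []
        for pos, gene in enumerate(chrom.genes):
            if pos in reps:
                cluster = reps[pos]
                genes.append(OrientedGene(gene.gene_id, cluster.rep_orientation))
                orig.append(chrom.orig_index[pos])
            elif pos not in covered:
                genes.append(gene)
                orig.append(chrom.orig_index[pos])
        if genes:
            chroms.append(Chromosome(chrom.chrom_id, genes, orig))
    return Genome(genome.species, chroms)


def preprocess_pair(
    g1: Genome,
    g2: Genome,
    fams: FamilySet,
    tandem_gap_max: int = 5,
    filter_first: bool = True,
) -> tuple[Genome, Genome]:
    """Filter unshared genes and collapse tandem clusters on both genomes."""

    def collapse(g: Genome) -> Genome:
        return collapse_clusters(
            g, cluster_tandem_duplicates(g, fams, tandem_gap_max)
        )

    if filter_first:
        g1, g2 = filter_unshared_genes(g1, g2, fams)
        g1, g2 = collapse(g1), collapse(g2)
    else:
        g1, g2 = collapse(g1), collapse(g2)
        g1, g2 = filter_unshared_genes(g1, g2, fams)
    return g1, g2
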