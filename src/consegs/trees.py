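"""Gene families from phylogenetic gene trees pruned at the MRCA.

Two genes belong to the same family if and only if they descend from the same
ancestral gene of the most recent common ancestor (MRCA) of the compared
species.  Given reconciled, event-labelled gene trees, each subtree rooted at
an ancestral gene of the MRCA becomes one family; this splits lineages of
paralogs that duplicated *before* the speciation, while tandem arrays that
expanded *after* it keep a single family.

Dialect
-------
Gene trees are newick with NHX-style comments.  Internal nodes carry a
duplication tag (``D=Y`` for duplications, ``D=N`` for speciations) and may
carry a species tag ``S=<label>``; leaves carry ``S=<species>`` or use
``species|gene_id`` labels.  Trees without any ``D`` tag anywhere are treated
as duplication-free.  The species tree is plain newick.
"""

from __future__ import annotations

import logging
import re

import dendropy

from .model import FamilySet

logger = logging.getLogger(__name__)

_NHX_RE = re.compile(r"&&NHX:?(.*)", re.DOTALL)


def _nhx_tags(node) -> dict[str, str]:
    tags: dict[str, str] = {}
    for comment in node.comments or ():
        m = _NHX_RE.match(comment.strip())
        if not m:
            continue
        for part in m.group(1).split(":"):
            if "=" in part:
                key, _, value = part.partition("=")
                tags[key.strip()] = value.strip()
    return tags


def _leaf_identity(leaf) -> tuple[str, str]:
    """Return (species, gene_id) of a leaf node."""
    label = leaf.taxon.label if leaf.taxon is not None else (leaf.label or "")
    tags = _nhx_tags(leaf)
    if "S" in tags:
        return tags["S"], label
    if "|" in label:
        species, _, gene = label.partition("|")
        return species, gene
    raise ValueError(f"cannot determine species of gene-tree leaf {label!r}")


class _SpeciesTree:
    """Rooted species tree with ancestor queries."""

    def __init__(self, tree: dendropy.Tree):
        self._parent: dict[str, str | None] = {}
        self._label: dict = {}
        for node in tree.preorder_node_iter():
            label = self._node_label(node)
            parent = (
                self._node_label(node.parent_node)
                if node.parent_node is not None
                else None
            )
            self._parent[label] = parent
            self._label[node] = label
        self._tree = tree

    @staticmethod
    def _node_label(node) -> str:
        if node.taxon is not None and node.taxon.label:
            return node.taxon.label
        if node.label:
            return node.label
        # unnamed internal node: synthesise a stable label from its leaf set
        leaves = sorted(
            l.taxon.label for l in node.leaf_iter() if l.taxon is not None
        )
        return "(" + ",".join(leaves) + ")"

    @classmethod
    def read(cls, source) -> "_SpeciesTree":
        if isinstance(source, dendropy.Tree):
            return cls(source)
        tree = dendropy.Tree.get(
            data=str(source),
            schema="newick",
            suppress_internal_node_taxa=False,
            extract_comment_metadata=False,
        )
        return cls(tree)

    def mrca(self, species_a: str, species_b: str) -> str:
        path_a = self._path_to_root(species_a)
        ancestors_a = set(path_a)
        for label in self._path_to_root(species_b):
            if label in ancestors_a:
                return label
        raise ValueError(
            f"no common ancestor of {species_a!r} and {species_b!r}"
        )

    def lca(self, species: set[str]) -> str:
        labels = sorted(species)
        current = labels[0]
        for other in labels[1:]:
            current = self.mrca(current, other)
        return current

    def is_at_or_above(self, label: str, reference: str) -> bool:
        """True when ``label`` lies on the root-ward path from ``reference``
        (inclusive)."""
        node: str | None = reference
        while node is not None:
            if node == label:
                return True
            node = self._parent[node]
        return False

    def _path_to_root(self, label: str) -> list[str]:
        if label not in self._parent:
            raise ValueError(f"unknown species-tree node {label!r}")
        path = []
        node: str | None = label
        while node is not None:
            path.append(node)
            node = self._parent[node]
        return path


def families_from_pruned_trees(
    gene_trees,
    species_tree,
    species_pair: tuple[str, str],
    family_prefix: str = "fam",
) -> FamilySet:
    """Derive a :class:`FamilySet` by pruning gene trees at the MRCA.

    ``gene_trees`` is an iterable of newick strings or ``dendropy.Tree``
    objects.  Each subtree whose root is an ancestral gene of
    ``MRCA(species_pair)`` becomes one family restricted to the two species;
    gene trees that contain no gene of either species are skipped with a log
    message.  Trees carrying some duplication tags but leaving an internal
    node unlabelled are rejected.
    """
    stree = _SpeciesTree.read(species_tree)
    s1, s2 = species_pair
    mrca = stree.mrca(s1, s2)
    fams = FamilySet()
    counter = 0

    for tree_source in gene_trees:
        if isinstance(tree_source, dendropy.Tree):
            tree = tree_source
        else:
            tree = dendropy.Tree.get(
                data=str(tree_source),
                schema="newick",
                suppress_internal_node_taxa=True,
                extract_comment_metadata=False,
            )
        counter = _prune_one(
            tree, stree, mrca, {s1, s2}, fams, family_prefix, counter
        )
    return fams


def _prune_one(tree, stree, mrca, species_pair, fams, prefix, counter) -> int:
    leaves = list(tree.leaf_node_iter())
    identities = {}
    for leaf in leaves:
        identities[leaf] = _leaf_identity(leaf)
    has_tags = any(
        "D" in _nhx_tags(n) for n in tree.preorder_internal_node_iter()
    )

    if not any(sp in species_pair for sp, _ in identities.values()):
        logger.info("gene tree with no gene in %s skipped", species_pair)
        return counter

    def node_species(node) -> str:
        tags = _nhx_tags(node)
        if "S" in tags and tags["S"] in stree._parent:
            return tags["S"]
        species = {
            identities[l][0]
            for l in node.leaf_iter()
            if identities[l][0] in stree._parent
        }
        if not species:
            return mrca
        return stree.lca(species)

    def is_duplication(node) -> bool:
        if not has_tags:
            return False
        tags = _nhx_tags(node)
        if "D" not in tags:
            raise ValueError(
                "internal node without a D (duplication) tag in a "
                "tagged gene tree"
            )
        return tags["D"] in ("Y", "y", "1", "T")

    def family_roots(node):
        members = [
            identities[l] for l in node.leaf_iter()
            if identities[l][0] in species_pair
        ]
        if not members:
            return
        if node.is_leaf():
            yield node
            return
        mapped = node_species(node)
        above_mrca = stree.is_at_or_above(mapped, mrca) and mapped != mrca
        at_or_above = stree.is_at_or_above(mapped, mrca)
        if (is_duplication(node) and at_or_above) or (
            not is_duplication(node) and above_mrca
        ):
            for child in node.child_nodes():
                yield from family_roots(child)
        else:
            yield node

    for root in family_roots(tree.seed_node):
        counter += 1
        family_id = f"{prefix}{counter:05d}"
        if root.is_leaf():
            members = [identities[root]]
        else:
            members = [
                identities[l]
                for l in root.leaf_iter()
                if identities[l][0] in species_pair
            ]
        for _species, gene_id in members:
            fams.add(family_id, gene_id)
    return counter
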