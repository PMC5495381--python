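"""Readers and writers for the package's tabular text formats.

All formats are plain TSV without headers; blank lines and lines starting
with ``#`` are ignored.  Writing then loading any genome or family table
reproduces it exactly.

* genome TSV: ``chrom_id  gene_id  orientation`` with orientation in
  ``{+1, -1, 1}``; one row per gene, file order defines the gene order within
  each chromosome and the order of first appearance defines chromosome order.
* families TSV: ``family_id  gene_id``.
* segments TSV: ``segment_id chrom1 start1 end1 chrom2 start2 end2 sign
  n_homologies families`` where ``families`` comma-joins ``family_id:orient``.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Iterable, TextIO

from .model import (
    UNKNOWN,
    Chromosome,
    ConservedSegment,
    FamilySet,
    Genome,
    OrientedGene,
)


class ParseError(ValueError):
    """Malformed row in one of the tabular formats."""


def _open(path_or_file, mode: str = "r"):
    if hasattr(path_or_file, "read") or hasattr(path_or_file, "write"):
        return path_or_file, False
    return open(path_or_file, mode), True


def _rows(handle: TextIO):
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t")


_ORIENTATIONS = {"+1": 1, "1": 1, "-1": -1}


def load_genome(path, species: str | None = None) -> Genome:
    """Read a genome TSV into a :class:`Genome`.

    The species label defaults to the file's stem.
    """
    handle, close = _open(path)
    if species is None:
        name = getattr(handle, "name", None)
        species = Path(name).stem if name else "genome"
    chrom_order: list[str] = []
    genes: dict[str, list[OrientedGene]] = {}
    seen: set[str] = set()
    try:
        for lineno, fields in _rows(handle):
            if len(fields) != 3:
                raise ParseError(
                    f"line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom_id, gene_id, orient_s = (f.strip() for f in fields)
            if orient_s not in _ORIENTATIONS:
                raise ParseError(
                    f"line {lineno}: orientation must be +1 or -1, "
                    f"got {orient_s!r}"
                )
            if gene_id in seen:
                raise ParseError(f"line {lineno}: duplicate gene_id {gene_id!r}")
            seen.add(gene_id)
            if chrom_id not in genes:
                genes[chrom_id] = []
                chrom_order.append(chrom_id)
            genes[chrom_id].append(
                OrientedGene(gene_id, _ORIENTATIONS[orient_s])
            )
    finally:
        if close:
            handle.close()
    return Genome(
        species,
        [Chromosome(cid, genes[cid]) for cid in chrom_order],
    )


def write_genome(genome: Genome, path) -> None:
    handle, close = _open(path, "w")
    try:
        for chrom in genome.chromosomes:
            for gene in chrom.genes:
                orient = "+1" if gene.orientation > 0 else "-1"
                handle.write(f"{chrom.chrom_id}\t{gene.gene_id}\t{orient}\n")
    finally:
        if close:
            handle.close()


def load_families(path) -> FamilySet:
    """Read a two-column ``family_id  gene_id`` table.

    Repeated identical pairs are deduplicated; a gene listed under two
    distinct families is an error.
    """
    handle, close = _open(path)
    fams = FamilySet()
    try:
        for lineno, fields in _rows(handle):
            if len(fields) != 2:
                raise ParseError(
                    f"line {lineno}: expected 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            family_id, gene_id = (f.strip() for f in fields)
            try:
                fams.add(family_id, gene_id)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: {exc}") from exc
    finally:
        if close:
            handle.close()
    return fams


def write_families(fams: FamilySet, path) -> None:
    handle, close = _open(path, "w")
    try:
        for gene_id, family_id in sorted(fams.items()):
            handle.write(f"{family_id}\t{gene_id}\n")
    finally:
        if close:
            handle.close()


def _orient_str(orient: int) -> str:
    if orient == UNKNOWN:
        return "?"
    return "+1" if orient > 0 else "-1"


def _orient_val(text: str) -> int:
    if text == "?":
        return UNKNOWN
    return 1 if text in ("+1", "1") else -1


def write_segments(
    segments: Iterable[ConservedSegment], path, extra_columns: bool = False
) -> None:
    """Write segments as TSV; ``extra_columns`` appends a ``true=1`` marker
    used by the simulator's ground-truth tables."""
    handle, close = _open(path, "w")
    try:
        for k, seg in enumerate(segments):
            fams = ",".join(
                f"{fam}:{_orient_str(orient)}" for fam, orient in seg.families
            )
            row = [
                str(k),
                seg.span1[0],
                str(seg.span1[1]),
                str(seg.span1[2]),
                seg.span2[0],
                str(seg.span2[1]),
                str(seg.span2[2]),
                _orient_str(seg.sign),
                str(seg.n_homologies),
                fams,
            ]
            if extra_columns:
                row.append("true=1")
            handle.write("\t".join(row) + "\n")
    finally:
        if close:
            handle.close()


def load_segments(path) -> list[ConservedSegment]:
    handle, close = _open(path)
    segments = []
    try:
        for lineno, fields in _rows(handle):
            if len(fields) < 10:
                raise ParseError(
                    f"line {lineno}: expected >= 10 fields, got {len(fields)}"
                )
            (
                _seg_id,
                chrom1,
                start1,
                end1,
                chrom2,
                start2,
                end2,
                sign_s,
                n_hom,
                fams_s,
            ) = fields[:10]
            families = []
            for part in fams_s.split(","):
                fam, _, orient_s = part.rpartition(":")
                families.append((fam, _orient_val(orient_s)))
            segments.append(
                ConservedSegment(
                    families=families,
                    span1=(chrom1, int(start1), int(end1)),
                    span2=(chrom2, int(start2), int(end2)),
                    sign=_orient_val(sign_s),
                    n_homologies=int(n_hom),
                )
            )
    finally:
        if close:
            handle.close()
    return segments


def genome_to_string(genome: Genome) -> str:
    buf = _io.StringIO()
    write_genome(genome, buf)
    return buf.getvalue()


def genome_from_string(text: str, species: str = "genome") -> Genome:
    return load_genome(_io.StringIO(text), species=species)
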