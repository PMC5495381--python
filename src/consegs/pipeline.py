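"""End-to-end detection: pre-process, chain diagonals, refine to segments."""

from __future__ import annotations

from .model import ConfigParams, ConservedSegment, FamilySet, Genome
from .preprocess import preprocess_pair
from .diagonals import build_homology_matrix, detect_diagonals
from .refine import RefinementTrace, refine_pipeline


def find_conserved_segments(
    g1: Genome,
    g2: Genome,
    fams: FamilySet,
    params: ConfigParams | None = None,
    trace: RefinementTrace | None = None,
) -> list[ConservedSegment]:
    """Detect conserved segments between two genomes.

    Runs the homolog filter and tandem-cluster collapsing, builds the signed
    homology matrix, chains consistent diagonals with gaps <= ``gap_max`` and
    applies the enabled refinements.  Spans of the returned segments are in
    the input genomes' gene-rank coordinates.
    """
    params = params or ConfigParams()
    p1, p2 = preprocess_pair(
        g1,
        g2,
        fams,
        tandem_gap_max=params.tandem_gap_max,
        filter_first=params.filter_first,
    )
    matrix = build_homology_matrix(p1, p2, fams)
    diags = detect_diagonals(matrix, params.gap_max)
    return refine_pipeline(diags, matrix, params, trace=trace)
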