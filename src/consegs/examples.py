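"""Small worked examples of ambiguous evolutionary scenarios.

These two constructions illustrate why detection precision and recall cannot
reach 100% even with perfect input data: distinct evolutionary scenarios can
produce identical extant gene arrangements.
"""

from __future__ import annotations

from .model import (
    Chromosome,
    ConfigParams,
    ConservedSegment,
    FamilySet,
    Genome,
    OrientedGene,
)


def reverse_tandem_duplication_case():
    """Gene B tandem-duplicated in reverse and the ancestral copy deleted.

    The extant matrix is indistinguishable from a mono-genic inversion of B,
    so the detector reports three conserved segments while the truth is a
    single segment spanning A to C (oriented extremities {sA, eC}).

    Returns ``(s1, s2, families, truth_segments, params)``.
    """
    s1 = Genome(
        "s1",
        [
            Chromosome(
                "chr1",
                [
                    OrientedGene("A1", 1),
                    OrientedGene("Ba", -1),  # the surviving reverse copy
                    OrientedGene("C1", 1),
                ],
            )
        ],
    )
    s2 = Genome(
        "s2",
        [
            Chromosome(
                "chr1",
                [
                    OrientedGene("A2", 1),
                    OrientedGene("B2", 1),
                    OrientedGene("C2", 1),
                ],
            )
        ],
    )
    fams = FamilySet(
        {"A1": "A", "Ba": "B", "C1": "C", "A2": "A", "B2": "B", "C2": "C"}
    )
    truth = [
        ConservedSegment(
            [("A", 1), ("C", 1)], ("anc", 0, 3), ("anc", 0, 3)
        )
    ]
    params = ConfigParams(gap_max=1, imr_gap=1, imcs_width=1, truncation_max=4)
    return s1, s2, fams, truth, params


def tandem_breakpoint_inversion_case():
    """An inversion breakpoint falling between two tandem duplicates of C.

    In lineage 1, C is duplicated in tandem and the segment ending between
    the two copies is inverted; the ancestral copy is the right one.  The two
    copies play symmetrical roles, so the detector attributes the ancestral
    role to the wrong copy: two false positive and two false negative
    extremities.  Truth: segments {A}, {B}, {C, D}.

    Collapsing is disabled (tandemGapMax = 0) so both tandem copies stay
    visible, which is the configuration in which this ambiguity arises.

    Returns ``(s1, s2, families, truth_segments, params)``.
    """
    s1 = Genome(
        "s1",
        [
            Chromosome(
                "chr1",
                [
                    OrientedGene("A1", 1),
                    OrientedGene("Ca", -1),  # inverted non-ancestral copy
                    OrientedGene("B1", -1),
                    OrientedGene("Cb", 1),   # the ancestral copy
                    OrientedGene("D1", 1),
                ],
            )
        ],
    )
    s2 = Genome(
        "s2",
        [
            Chromosome(
                "chr1",
                [
                    OrientedGene("A2", 1),
                    OrientedGene("B2", 1),
                    OrientedGene("C2", 1),
                    OrientedGene("D2", 1),
                ],
            )
        ],
    )
    fams = FamilySet(
        {
            "A1": "A", "Ca": "C", "B1": "B", "Cb": "C", "D1": "D",
            "A2": "A", "B2": "B", "C2": "C", "D2": "D",
        }
    )
    truth = [
        ConservedSegment([("A", 1)], ("anc", 0, 1), ("anc", 0, 1)),
        ConservedSegment([("B", 1)], ("anc", 1, 2), ("anc", 1, 2)),
        ConservedSegment(
            [("C", 1), ("D", 1)], ("anc", 2, 4), ("anc", 2, 4)
        ),
    ]
    params = ConfigParams(
        gap_max=1, tandem_gap_max=0, imr_gap=1, imcs_width=1, truncation_max=4
    )
    return s1, s2, fams, truth, params
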