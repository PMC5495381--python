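"""Recall/precision/F1 of detected conserved segments against the truth.

Detection quality is measured on three kinds of items derived from segments:

* *extremities*: the two terminal gene ends of each segment.  Oriented items
  are ``(family, side)`` pairs with side ``s`` (5' start) or ``e`` (3' end);
  a mono-genic segment contributes both ends of its single gene.  Unoriented
  extremity items are the terminal family names alone.
* *adjacencies*: consecutive gene-end pairs inside segments, canonicalised so
  an adjacency equals its mirror.
* *gene names*: the families contained in segments.

Items are keyed by family identifiers (ancestral genes), because truth is
defined on the ancestral genome; unrecognised duplicate copies therefore
surface as false positives.  With the detected item set D and the true item
set T: Tp = D ∩ T, Fp = D \\ T, Fn = T \\ D, recall r = |Tp|/|T|, precision
p = |Tp|/|D| and F1 = 2rp/(r+p).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .model import ConfigParams, ConservedSegment
from .pipeline import find_conserved_segments
from .evosim import SimulationConfig, simulate_evolution

KINDS = ("extremity", "adjacency", "gene_name")


@dataclass(frozen=True)
class ItemSet:
    kind: str
    oriented: bool
    items: frozenset

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown item kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.items)


def _gene_ends(family: str, orientation: int) -> tuple[tuple, tuple]:
    """(left end, right end) of a gene as placed on the reference axis; an
    unknown orientation is read as forward."""
    if orientation >= 0:
        return (family, "s"), (family, "e")
    return (family, "e"), (family, "s")


def _segment_items(seg: ConservedSegment, kind: str, oriented: bool):
    genes = seg.families
    if kind == "gene_name":
        for fam, _ in genes:
            yield fam
        return
    if kind == "extremity":
        left, _ = _gene_ends(*genes[0])
        _, right = _gene_ends(*genes[-1])
        if oriented:
            yield left
            yield right
        else:
            yield genes[0][0]
            yield genes[-1][0]
        return
    # adjacency
    for (fam_a, or_a), (fam_b, or_b) in zip(genes, genes[1:]):
        if oriented:
            _, right_a = _gene_ends(fam_a, or_a)
            left_b, _ = _gene_ends(fam_b, or_b)
            yield tuple(sorted((right_a, left_b)))
        else:
            yield tuple(sorted((fam_a, fam_b)))


def extract_items(
    segments: Iterable[ConservedSegment], kind: str, oriented: bool = True
) -> ItemSet:
    """Canonical item set of a collection of segments (set semantics: an item
    occurring in several segments counts once)."""
    items: set = set()
    for seg in segments:
        items.update(_segment_items(seg, kind, oriented))
    return ItemSet(kind, oriented, frozenset(items))


@dataclass
class Metrics:
    """Item-level confusion sets and the derived scores."""

    kind: str
    oriented: bool
    T: frozenset
    D: frozenset
    Tp: frozenset = field(init=False)
    Fp: frozenset = field(init=False)
    Fn: frozenset = field(init=False)
    recall: float = field(init=False)
    precision: float = field(init=False)
    f1: float = field(init=False)

    def __post_init__(self) -> None:
        self.Tp = self.D & self.T
        self.Fp = self.D - self.T
        self.Fn = self.T - self.D
        if self.T:
            self.recall = len(self.Tp) / len(self.T)
        else:
            self.recall = 1.0 if not self.D else 0.0
        if self.D:
            self.precision = len(self.Tp) / len(self.D)
        else:
            self.precision = 1.0 if not self.T else 0.0
        rp = self.recall + self.precision
        self.f1 = 2 * self.recall * self.precision / rp if rp else 0.0


def score_items(detected: ItemSet, truth: ItemSet) -> Metrics:
    if (detected.kind, detected.oriented) != (truth.kind, truth.oriented):
        raise ValueError(
            "detected and truth item sets must share kind and orientation mode"
        )
    return Metrics(detected.kind, detected.oriented, truth.items, detected.items)


def score_segments(
    detected: Sequence[ConservedSegment],
    truth: Sequence[ConservedSegment],
    kinds: Sequence[str] = KINDS,
    modes: Sequence[bool] = (True, False),
) -> list[Metrics]:
    out = []
    for kind in kinds:
        for oriented in modes:
            out.append(
                score_items(
                    extract_items(detected, kind, oriented),
                    extract_items(truth, kind, oriented),
                )
            )
    return out


def benchmark_run(
    cfg: SimulationConfig,
    params_grid: Sequence[ConfigParams],
) -> pd.DataFrame:
    """Simulate once, then detect and score under every parameterisation.

    Returns a tidy table with one row per (parameter set, item kind,
    orientation mode).
    """
    result = simulate_evolution(cfg)
    truth_segments = result.truth.to_segments()
    rows = []
    for params in params_grid:
        detected = find_conserved_segments(
            result.s1, result.s2, result.families, params
        )
        for metrics in score_segments(detected, truth_segments):
            rows.append(
                {
                    "seed": cfg.seed,
                    "gap_max": params.gap_max,
                    "tandem_gap_max": params.tandem_gap_max,
                    "imr_gap": params.imr_gap,
                    "imcs_width": params.imcs_width,
                    "truncation_max": params.truncation_max,
                    "kind": metrics.kind,
                    "oriented": metrics.oriented,
                    "n_true": len(metrics.T),
                    "n_detected": len(metrics.D),
                    "recall": metrics.recall,
                    "precision": metrics.precision,
                    "f1": metrics.f1,
                }
            )
    return pd.DataFrame(rows)
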