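"""Initiation shape: the per-strand shape index and P/B classification.

Transcription initiation within an element is either *peaked* (reads
concentrated at one or a few bases) or *broad* (spread over the element).
The shape index for one strand of an element is

    SI = 2 + Σ_{i ∈ L} p_i log2 p_i

where p_i is the probability of observing a read at base i within the
element span and L is the set of bases with at least one read.  SI is 2
minus the positional entropy in bits: 2 for a point mass, and 2 − log2 L
for a uniform spread over L positions.  A strand with SI > −1.5 is
"peaked" (P), otherwise "broad" (B); divergent elements are then P-P,
P-B or B-B by their unordered pair of strand labels.

Strands with fewer than 50 reads within the span are filtered out rather
than scored (shape is unreliable at low depth); signal is first pooled
across samples of the same tissue.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .core_io import SignalTrack
from .elements import Element

__all__ = [
    "StrandShape",
    "ElementShapeClass",
    "pool_tissue_signal",
    "shape_index",
    "classify_element_shape",
    "score_elements",
    "SI_CUTOFF",
    "MIN_READS",
]

SI_CUTOFF = -1.5
MIN_READS = 50


@dataclass(frozen=True)
class StrandShape:
    element_id: str
    strand: str
    n_reads: int
    n_positions: int  # |L|: positions with >= 1 read
    si: float
    label: str  # P | B

    def __post_init__(self) -> None:
        if self.si > 2.0 + 1e-9:
            raise ValueError("SI cannot exceed 2")


@dataclass(frozen=True)
class ElementShapeClass:
    element_id: str
    category: str  # P-P | P-B | B-B


def pool_tissue_signal(tracks: Sequence[SignalTrack]) -> SignalTrack:
    """Position-wise sum of raw counts across samples of one tissue."""
    if len(tracks) == 0:
        raise ValueError("no tracks to pool")
    end_types = {t.end_type for t in tracks}
    if len(end_types) != 1:
        raise ValueError(f"cannot pool tracks of mixed end types: {sorted(end_types)}")
    out = tracks[0].copy()
    for t in tracks[1:]:
        for chrom, strand in t.keys():
            pos, cnt = t.positions(chrom, strand)
            for p, c in zip(pos.tolist(), cnt.tolist()):
                out.add(chrom, strand, p, c)
    return out


def shape_index(
    pooled: SignalTrack, element: Element, strand: str, min_reads: int = MIN_READS
) -> StrandShape | None:
    """Shape index for one strand of an element; None if under the read filter.

    Only positions within the element span contribute.  The label is P
    iff SI > −1.5 (an SI of exactly −1.5 is B).
    """
    if strand not in ("+", "-"):
        raise ValueError("strand must be '+' or '-'")
    span = element.span
    dense = pooled.dense(span.chrom, strand, span.start, span.end)
    total = int(dense.sum())
    if total < min_reads:
        return None
    counts = dense[dense > 0]
    p = counts / total
    si = 2.0 + float(np.sum(p * np.log2(p)))
    label = "P" if si > SI_CUTOFF else "B"
    return StrandShape(
        element_id=element.element_id,
        strand=strand,
        n_reads=total,
        n_positions=int(len(counts)),
        si=si,
        label=label,
    )


def classify_element_shape(plus: StrandShape, minus: StrandShape) -> ElementShapeClass:
    """P-P / P-B / B-B from the unordered pair of strand labels."""
    if plus is None or minus is None:
        raise ValueError("both strands must be scored to classify element shape")
    if plus.element_id != minus.element_id:
        raise ValueError("strand shapes belong to different elements")
    labels = sorted((plus.label, minus.label))  # 'B' < 'P'
    category = {("B", "B"): "B-B", ("B", "P"): "P-B", ("P", "P"): "P-P"}[tuple(labels)]
    return ElementShapeClass(element_id=plus.element_id, category=category)


def score_elements(
    pooled: SignalTrack, elements: Iterable[Element], min_reads: int = MIN_READS
) -> tuple[list[tuple[StrandShape, StrandShape, ElementShapeClass]], list[str]]:
    """Score all divergent elements; returns (scored, filtered element ids).

    An element is filtered (reported, not an error) when either strand has
    fewer than ``min_reads`` reads within the span.
    """
    scored = []
    filtered: list[str] = []
    for e in elements:
        if e.directionality != "divergent":
            continue
        sp = shape_index(pooled, e, "+", min_reads)
        sm = shape_index(pooled, e, "-", min_reads)
        if sp is None or sm is None:
            filtered.append(e.element_id)
            continue
        scored.append((sp, sm, classify_element_shape(sp, sm)))
    return scored, filtered
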