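"""TRE classification: divergent/unidirectional pairing and genomic annotation.

A transcriptional regulatory element (TRE) detected by nascent 5'-end
signal is *divergent* when initiation peaks on opposite strands sit within
a pairing distance of each other (default 300 bp, summit to summit), and
*unidirectional* when only one strand initiates.  Elements are further
annotated as *proximal* (element midpoint within ±500 bp of an annotated
gene TSS) or *distal*, and as intragenic/intergenic by gene overlap.

Peak calls are normally ingested from an external caller; a naive
sliding-window caller is provided purely as a fixture tool for synthetic
tracks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core_io import GeneAnnotation, GenomicInterval, SignalTrack

__all__ = [
    "Peak",
    "Element",
    "naive_peak_call",
    "pair_divergent",
    "annotate_proximity",
    "annotate_context",
]


@dataclass(frozen=True)
class Peak:
    """A single-strand initiation peak with its summit (max-signal base)."""

    interval: GenomicInterval
    summit: int
    count: int

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("peaks must be stranded")
        if not self.interval.contains(self.summit):
            raise ValueError("summit must lie within the peak interval")
        if self.count < 1:
            raise ValueError("peak count must be >= 1")


@dataclass
class Element:
    """A TRE: one or two strand peaks with directionality and annotations."""

    element_id: str
    span: GenomicInterval
    directionality: str  # divergent | unidirectional
    plus_peak: Peak | None = None
    minus_peak: Peak | None = None
    proximity: str | None = None  # proximal | distal
    context: str | None = None  # intergenic | intragenic

    def __post_init__(self) -> None:
        if self.directionality == "divergent":
            if self.plus_peak is None or self.minus_peak is None:
                raise ValueError("divergent elements require peaks on both strands")
        elif self.directionality == "unidirectional":
            if (self.plus_peak is None) == (self.minus_peak is None):
                raise ValueError("unidirectional elements require exactly one peak")
        else:
            raise ValueError(f"invalid directionality {self.directionality!r}")

    @property
    def peaks(self) -> list[Peak]:
        return [p for p in (self.plus_peak, self.minus_peak) if p is not None]


def naive_peak_call(track: SignalTrack, min_count: int = 5, window: int = 10) -> list[Peak]:
    """Fixture-grade sliding-window peak caller.

    A window start i is *hot* when the signal sum over ``[i, i + window)``
    is at least ``min_count``; maximal runs of hot starts define peak
    regions, trimmed to the covered nonzero positions.  The summit is the
    leftmost position of maximal count.  Intended only to turn synthetic
    tracks into Peak fixtures — real analyses ingest externally called
    peaks.
    """
    if min_count < 1 or window < 1:
        raise ValueError("min_count and window must be >= 1")
    peaks: list[Peak] = []
    for chrom, strand in track.keys():
        pos, cnt = track.positions(chrom, strand)
        lo = int(pos[0]) - window + 1
        hi = int(pos[-1])  # last useful window start
        dense = track.dense(chrom, strand, max(lo, 0), hi + window)
        base = max(lo, 0)
        csum = np.concatenate(([0], np.cumsum(dense)))
        starts = np.arange(base, hi + 1)
        wsum = csum[np.minimum(starts - base + window, len(dense))] - csum[starts - base]
        hot = wsum >= min_count
        if not hot.any():
            continue
        # maximal runs of hot window starts
        idx = np.flatnonzero(hot)
        breaks = np.flatnonzero(np.diff(idx) > 1)
        run_bounds = zip(
            np.concatenate(([0], breaks + 1)), np.concatenate((breaks, [len(idx) - 1]))
        )
        for a, b in run_bounds:
            region_start = int(starts[idx[a]])
            region_end = int(starts[idx[b]]) + window  # exclusive
            seg = dense[region_start - base : region_end - base]
            nz = np.flatnonzero(seg)
            if len(nz) == 0:
                continue
            p_start = region_start + int(nz[0])
            p_end = region_start + int(nz[-1]) + 1
            sub = dense[p_start - base : p_end - base]
            summit = p_start + int(np.argmax(sub))
            peaks.append(
                Peak(GenomicInterval(chrom, p_start, p_end, strand), summit, int(sub.sum()))
            )
    return peaks


def _union_span(a: GenomicInterval, b: GenomicInterval) -> GenomicInterval:
    return GenomicInterval(a.chrom, min(a.start, b.start), max(a.end, b.end), ".")


def pair_divergent(
    plus_peaks: Sequence[Peak], minus_peaks: Sequence[Peak], max_gap: int = 300
) -> list[Element]:
    """Pair opposite-strand peaks within ``max_gap`` bp (summit to summit).

    Greedy nearest-first matching: among unmatched cross-strand pairs on
    the same chromosome with summit distance <= max_gap, repeatedly take
    the closest pair (ties broken to the leftmost plus summit, then the
    leftmost minus summit).  Matched pairs become divergent elements whose
    span is the union of both peak intervals; every unmatched peak becomes
    a unidirectional element.  Each peak joins at most one element, and the
    result does not depend on input ordering.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    for peaks, name in ((plus_peaks, "+"), (minus_peaks, "-")):
        seen = set()
        for p in peaks:
            key = (p.interval.chrom, p.interval.start, p.interval.end, p.summit)
            if key in seen:
                raise ValueError(f"duplicate peak on strand {name}: {key}; deduplicate input")
            seen.add(key)
        if any(p.interval.strand != name for p in peaks):
            raise ValueError(f"peak with wrong strand passed to the {name} list")

    plus = sorted(plus_peaks, key=lambda p: (p.interval.chrom, p.summit, p.interval.start))
    minus = sorted(minus_peaks, key=lambda p: (p.interval.chrom, p.summit, p.interval.start))
    candidates = []
    for i, pp in enumerate(plus):
        for j, mp in enumerate(minus):
            if pp.interval.chrom != mp.interval.chrom:
                continue
            dist = abs(pp.summit - mp.summit)
            if dist <= max_gap:
                candidates.append((dist, pp.summit, mp.summit, i, j))
    candidates.sort()
    used_plus: set[int] = set()
    used_minus: set[int] = set()
    pairs: list[tuple[Peak, Peak]] = []
    for _dist, _ps, _ms, i, j in candidates:
        if i in used_plus or j in used_minus:
            continue
        used_plus.add(i)
        used_minus.add(j)
        pairs.append((plus[i], minus[j]))

    elements: list[Element] = []
    for pp, mp in pairs:
        elements.append(
            Element(
                element_id="",
                span=_union_span(pp.interval, mp.interval),
                directionality="divergent",
                plus_peak=pp,
                minus_peak=mp,
            )
        )
    for i, pp in enumerate(plus):
        if i not in used_plus:
            iv = pp.interval
            elements.append(
                Element("", GenomicInterval(iv.chrom, iv.start, iv.end, "."),
                        "unidirectional", plus_peak=pp)
            )
    for j, mp in enumerate(minus):
        if j not in used_minus:
            iv = mp.interval
            elements.append(
                Element("", GenomicInterval(iv.chrom, iv.start, iv.end, "."),
                        "unidirectional", minus_peak=mp)
            )
    elements.sort(key=lambda e: (e.span.chrom, e.span.start, e.span.end))
    for k, e in enumerate(elements):
        e.element_id = f"{e.span.chrom}:{e.span.start}-{e.span.end}"
    # disambiguate identical spans (possible for nested unidirectional peaks)
    seen_ids: dict[str, int] = {}
    for e in elements:
        n = seen_ids.get(e.element_id, 0)
        seen_ids[e.element_id] = n + 1
        if n:
            e.element_id = f"{e.element_id}.{n}"
    return elements


def annotate_proximity(
    elements: Iterable[Element], genes: GeneAnnotation, cutoff: int = 500
) -> list[Element]:
    """Label elements proximal/distal by midpoint distance to the nearest TSS.

    Proximal iff the unsigned distance from the element-span midpoint to
    the nearest annotated gene TSS on the same chromosome is <= cutoff
    (boundary inclusive: "within ±cutoff").  Elements on chromosomes with
    no genes are distal.
    """
    if len(genes) == 0:
        raise ValueError("gene annotation is empty")
    tss_by_chrom = {
        chrom: np.sort(sub["tss"].to_numpy()) for chrom, sub in genes.df.groupby("chrom")
    }
    out = list(elements)
    for e in out:
        tss = tss_by_chrom.get(e.span.chrom)
        if tss is None or len(tss) == 0:
            e.proximity = "distal"
            continue
        mid = e.span.midpoint
        i = np.searchsorted(tss, mid)
        best = min(
            abs(mid - int(tss[j])) for j in (i - 1, i) if 0 <= j < len(tss)
        )
        e.proximity = "proximal" if best <= cutoff else "distal"
    return out


def annotate_context(elements: Iterable[Element], genes: GeneAnnotation) -> list[Element]:
    """Label elements intragenic/intergenic by >= 1 bp overlap with any gene."""
    if len(genes) == 0:
        raise ValueError("gene annotation is empty")
    by_chrom = {
        chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
        for chrom, sub in genes.df.groupby("chrom")
    }
    out = list(elements)
    for e in out:
        hit = False
        if e.span.chrom in by_chrom:
            starts, ends = by_chrom[e.span.chrom]
            hit = bool(np.any((starts < e.span.end) & (ends > e.span.start)))
        e.context = "intragenic" if hit else "intergenic"
    return out
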