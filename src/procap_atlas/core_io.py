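"""Core data types and readers/writers for per-base nascent-transcription signal.

PRO-cap reduces, after alignment, to strand-specific per-base counts of read
5' (initiation) and 3' (RNAPII position) ends.  This module holds the atomic
containers used by every downstream stage:

* :class:`GenomicInterval` — 0-based, half-open coordinates, the single
  convention used everywhere internally (BED/bedGraph native).
* :class:`SignalTrack` — sparse non-negative integer counts per base, keyed
  by ``(chrom, strand)``.
* :class:`GeneAnnotation` — gene intervals with derived TSS/TTS anchors.
* :class:`ReadPairTable` — matched 5'/3' end positions per read, the input
  to single-molecule pause-distance analysis.

plus bedGraph round-trip IO, interval counting and metaplot aggregation.

Minus-strand bedGraphs in the wild store either positive counts or negated
values; the reader accepts both and stores magnitudes, logging the dialect.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

STRANDS = ("+", "-")

__all__ = [
    "GenomicInterval",
    "SignalTrack",
    "GeneAnnotation",
    "ReadPairTable",
    "read_bedgraph",
    "write_bedgraph",
    "count_in_interval",
    "metaplot",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based, half-open genomic interval ``[start, end)``.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


class SignalTrack:
    """Sparse per-base counts of read ends, keyed by ``(chrom, strand)``.

    Counts are non-negative integers; querying an absent position returns 0.
    ``end_type`` records whether the track holds 5' or 3' ends.
    """

    def __init__(self, end_type: str = "five_prime"):
        if end_type not in ("five_prime", "three_prime"):
            raise ValueError(f"invalid end_type {end_type!r}")
        self.end_type = end_type
        self._data: dict[tuple[str, str], dict[int, int]] = defaultdict(dict)
        self._frozen: dict[tuple[str, str], tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    # -- construction -----------------------------------------------------

    def add(self, chrom: str, strand: str, pos: int, count: int = 1) -> None:
        if count < 0:
            raise ValueError("counts must be non-negative")
        if count == 0:
            return
        d = self._data[(chrom, strand)]
        d[pos] = d.get(pos, 0) + count
        self._frozen.pop((chrom, strand), None)

    def add_positions(self, chrom: str, strand: str, positions: Sequence[int]) -> None:
        """Increment one count at each listed position (vectorised)."""
        if len(positions) == 0:
            return
        pos, cnt = np.unique(np.asarray(positions, dtype=np.int64), return_counts=True)
        d = self._data[(chrom, strand)]
        for p, c in zip(pos.tolist(), cnt.tolist()):
            d[p] = d.get(p, 0) + c
        self._frozen.pop((chrom, strand), None)

    # -- access -----------------------------------------------------------

    def keys(self) -> list[tuple[str, str]]:
        return sorted(k for k, v in self._data.items() if v)

    def chroms(self) -> list[str]:
        return sorted({c for (c, _s), v in self._data.items() if v})

    @property
    def library_size(self) -> int:
        return sum(sum(d.values()) for d in self._data.values())

    def _arrays(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Sorted positions, counts, and exclusive-prefix cumulative counts."""
        key = (chrom, strand)
        if key not in self._frozen:
            d = self._data.get(key, {})
            if d:
                pos = np.fromiter(d.keys(), dtype=np.int64, count=len(d))
                order = np.argsort(pos)
                pos = pos[order]
                cnt = np.fromiter(d.values(), dtype=np.int64, count=len(d))[order]
            else:
                pos = np.empty(0, dtype=np.int64)
                cnt = np.empty(0, dtype=np.int64)
            cum = np.concatenate(([0], np.cumsum(cnt)))
            self._frozen[key] = (pos, cnt, cum)
        return self._frozen[key]

    def positions(self, chrom: str, strand: str) -> tuple[np.ndarray, np.ndarray]:
        pos, cnt, _ = self._arrays(chrom, strand)
        return pos, cnt

    def count_range(self, chrom: str, strand: str, start: int, end: int) -> int:
        """Total counts at positions in ``[start, end)``."""
        pos, _cnt, cum = self._arrays(chrom, strand)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        return int(cum[hi] - cum[lo])

    def dense(self, chrom: str, strand: str, start: int, end: int) -> np.ndarray:
        """Dense count vector over ``[start, end)``."""
        pos, cnt, _ = self._arrays(chrom, strand)
        out = np.zeros(end - start, dtype=np.int64)
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        out[pos[lo:hi] - start] = cnt[lo:hi]
        return out

    def get(self, chrom: str, strand: str, pos: int) -> int:
        return self._data.get((chrom, strand), {}).get(pos, 0)

    def copy(self) -> "SignalTrack":
        t = SignalTrack(self.end_type)
        for key, d in self._data.items():
            t._data[key] = dict(d)
        return t

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SignalTrack):
            return NotImplemented
        mine = {k: v for k, v in self._data.items() if v}
        theirs = {k: v for k, v in other._data.items() if v}
        return self.end_type == other.end_type and mine == theirs


@dataclass
class GeneAnnotation:
    """Gene intervals with derived TSS/TTS positions.

    The TSS is the 5'-most transcribed base (``start`` for +, ``end - 1``
    for −); the TTS is the 3'-most.  gene_ids are unique; strand must be
    ``+`` or ``-``.
    """

    df: pd.DataFrame = field(repr=False)

    REQUIRED = ("gene_id", "chrom", "start", "end", "strand")

    def __post_init__(self) -> None:
        missing = set(self.REQUIRED) - set(self.df.columns)
        if missing:
            raise ValueError(f"gene table missing columns: {sorted(missing)}")
        if self.df["gene_id"].duplicated().any():
            raise ValueError("gene_ids must be unique")
        if not self.df["strand"].isin(["+", "-"]).all():
            raise ValueError("gene strand must be '+' or '-'")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("gene intervals require start < end")
        self.df = self.df.reset_index(drop=True).copy()
        plus = self.df["strand"] == "+"
        self.df["tss"] = np.where(plus, self.df["start"], self.df["end"] - 1)
        self.df["tts"] = np.where(plus, self.df["end"] - 1, self.df["start"])

    def __len__(self) -> int:
        return len(self.df)

    def __iter__(self) -> Iterator[pd.Series]:
        return (row for _, row in self.df.iterrows())

    def subset(self, gene_ids: Iterable[str]) -> "GeneAnnotation":
        ids = set(gene_ids)
        return GeneAnnotation(self.df[self.df["gene_id"].isin(ids)][list(self.REQUIRED)])

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, int, int, str]]) -> "GeneAnnotation":
        """Build from ``(gene_id, chrom, start, end, strand)`` tuples."""
        df = pd.DataFrame(records, columns=list(cls.REQUIRED))
        return cls(df)

    @classmethod
    def from_bed(cls, path: str | Path) -> "GeneAnnotation":
        """Read BED6 (or the first 6 columns of BED12)."""
        rows = []
        for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{i}: BED6 requires 6 columns")
            rows.append((f[3], f[0], int(f[1]), int(f[2]), f[5]))
        return cls.from_records(rows)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GeneAnnotation":
        df = pd.read_csv(path, sep="\t")
        return cls(df[list(cls.REQUIRED)])

    def to_tsv(self, path: str | Path) -> None:
        self.df[list(self.REQUIRED)].to_csv(path, sep="\t", index=False)


class ReadPairTable:
    """Matched 5'/3' read-end positions, one row per sequenced molecule."""

    COLUMNS = ("chrom", "strand", "five_prime_pos", "three_prime_pos")

    def __init__(self, df: pd.DataFrame):
        missing = set(self.COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"read-pair table missing columns: {sorted(missing)}")
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("read-pair strand must be '+' or '-'")
        if (df[["five_prime_pos", "three_prime_pos"]] < 0).any().any():
            raise ValueError("read positions must be >= 0")
        self.df = df[list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReadPairTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bedGraph IO
# ---------------------------------------------------------------------------


def read_bedgraph(
    path: str | Path,
    end_type: str = "five_prime",
    strand: str = "+",
    track: SignalTrack | None = None,
) -> SignalTrack:
    """Read a 4-column bedGraph into a :class:`SignalTrack`.

    Interval values are expanded to per-base counts.  Values must be
    integers; on the minus strand, negated values (a common strand-specific
    dialect) are accepted and stored as magnitudes.  Pass ``track`` to merge
    into an existing track (e.g. the other strand of the same library).
    """
    if strand not in STRANDS:
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    out = track if track is not None else SignalTrack(end_type)
    if out.end_type != end_type:
        raise ValueError("end_type mismatch with supplied track")
    negative_dialect = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(fields)}")
            chrom, s_start, s_end, s_val = fields
            try:
                start, end = int(s_start), int(s_end)
                val = float(s_val)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if not val.is_integer():
                raise ValueError(f"{path}:{lineno}: non-integer value {s_val}")
            val = int(val)
            if val < 0:
                if strand == "-":
                    negative_dialect = True
                    val = -val
                else:
                    raise ValueError(f"{path}:{lineno}: negative value on + strand")
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid interval {start}-{end}")
            if val > 0:
                for pos in range(start, end):
                    out.add(chrom, strand, pos, val)
    if negative_dialect:
        logger.info("%s: negative-value minus-strand bedGraph dialect detected", path)
    return out


def write_bedgraph(track: SignalTrack, chrom: str, strand: str, path: str | Path) -> None:
    """Write one (chrom, strand) of a track as 4-column bedGraph.

    Adjacent positions with equal counts are merged into one interval, so
    ``read_bedgraph(write_bedgraph(t))`` round-trips exactly.
    """
    pos, cnt = track.positions(chrom, strand)
    with open(path, "w") as fh:
        if len(pos) == 0:
            return
        run_start = int(pos[0])
        run_val = int(cnt[0])
        prev = int(pos[0])
        for p, c in zip(pos[1:].tolist(), cnt[1:].tolist()):
            if p == prev + 1 and c == run_val:
                prev = p
                continue
            fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")
            run_start, run_val, prev = p, c, p
        fh.write(f"{chrom}\t{run_start}\t{prev + 1}\t{run_val}\n")


def count_in_interval(
    track: SignalTrack, interval: GenomicInterval, strand_mode: str = "both"
) -> int:
    """Reads whose stored end falls within the interval (half-open).

    ``strand_mode`` is ``both`` (sum strands), ``plus`` or ``minus``.
    An unknown chromosome yields 0 with a logged warning: individual
    libraries may lack minor scaffolds.
    """
    if strand_mode not in ("both", "plus", "minus"):
        raise ValueError(f"invalid strand_mode {strand_mode!r}")
    if interval.chrom not in track.chroms():
        logger.warning("chromosome %s absent from track; count is 0", interval.chrom)
        return 0
    strands = {"both": STRANDS, "plus": ("+",), "minus": ("-",)}[strand_mode]
    return sum(
        track.count_range(interval.chrom, s, interval.start, interval.end) for s in strands
    )


def metaplot(
    tracks: Sequence[SignalTrack],
    anchors: Sequence[GenomicInterval],
    flank: int,
) -> np.ndarray:
    """Average signal profile around anchor centers, length ``2*flank + 1``.

    Signal is summed over tracks and over both strands; each anchor
    contributes the window around its midpoint, with minus-strand anchors
    reversed so that transcriptional downstream is always rightward.
    """
    if flank <= 0:
        raise ValueError("flank must be > 0")
    if len(anchors) == 0:
        raise ValueError("metaplot requires at least one anchor")
    width = 2 * flank + 1
    acc = np.zeros(width, dtype=float)
    for anchor in anchors:
        center = anchor.midpoint
        lo = center - flank
        profile = np.zeros(width, dtype=float)
        for track in tracks:
            for strand in STRANDS:
                start = max(lo, 0)
                if start >= lo + width:
                    continue
                profile[start - lo :] += track.dense(anchor.chrom, strand, start, lo + width)
        if anchor.strand == "-":
            profile = profile[::-1]
        acc += profile
    return acc / len(anchors)
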