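"""Genomic interval primitives and interval arithmetic.

All coordinates are 0-based half-open internally; conversion to 1-based
inclusive happens only at the GFF3 file boundary.  Interval sets used by
the pipeline are small enough (tens of thousands) that sorted-array
algorithms on numpy arrays are both fast and easy to verify against
brute-force scans.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic span [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def overlap_len(self, other: "Interval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def distance(self, other: "Interval") -> int:
        """Gap between two intervals; 0 if they overlap or abut."""
        if self.chrom != other.chrom:
            raise ValueError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)

    def expanded(self, flank: int, chrom_len: int | None = None) -> "Interval":
        start = max(0, self.start - flank)
        end = self.end + flank
        if chrom_len is not None:
            end = min(end, chrom_len)
        return replace(self, start=start, end=end)

    def jaccard(self, other: "Interval") -> float:
        inter = self.overlap_len(other)
        union = len(self) + len(other) - inter
        return inter / union if union else 0.0


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-aware TSS/TTS and sub-genome assignment.

    ``sub_genome`` is derived from the trailing letter of the chromosome
    name (chr1A -> A), mirroring IWGSC naming.  ``length`` is the TPM
    denominator.
    """

    gene_id: str
    interval: Interval
    triad_id: str | None = None

    def __post_init__(self) -> None:
        if self.interval.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id} requires explicit strand")

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def strand(self) -> str:
        return self.interval.strand

    @property
    def tss(self) -> int:
        return self.interval.start if self.strand == "+" else self.interval.end

    @property
    def tts(self) -> int:
        return self.interval.end if self.strand == "+" else self.interval.start

    @property
    def length(self) -> int:
        return len(self.interval)

    @property
    def sub_genome(self) -> str:
        sg = self.chrom[-1]
        if sg not in {"A", "B", "D"}:
            raise ValueError(f"cannot derive sub-genome from chrom {self.chrom!r}")
        return sg


def sort_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


def merge_intervals(
    intervals: Iterable[Interval], max_gap: int = 0
) -> list[Interval]:
    """Merge intervals whose gap is <= max_gap (bedtools merge -d semantics)."""
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    ivs = sort_intervals(intervals)
    merged: list[Interval] = []
    for iv in ivs:
        if (
            merged
            and iv.chrom == merged[-1].chrom
            and iv.start - merged[-1].end <= max_gap
        ):
            prev = merged[-1]
            if iv.end > prev.end:
                merged[-1] = replace(prev, end=iv.end)
        else:
            merged.append(Interval(iv.chrom, iv.start, iv.end))
    return merged


def _by_chrom(intervals: Sequence[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chrom, []).append(iv)
    for ivs in out.values():
        ivs.sort(key=lambda iv: (iv.start, iv.end))
    return out


class IntervalIndex:
    """Sorted-array index for overlap and nearest queries over one set."""

    def __init__(self, intervals: Iterable[Interval]):
        self.by_chrom: dict[str, list[Interval]] = _by_chrom(list(intervals))
        self._starts = {
            c: np.array([iv.start for iv in ivs], dtype=np.int64)
            for c, ivs in self.by_chrom.items()
        }
        # running max of ends supports overlap queries even when intervals nest
        self._maxend = {
            c: np.maximum.accumulate(np.array([iv.end for iv in ivs], dtype=np.int64))
            for c, ivs in self.by_chrom.items()
        }

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_chrom.values())

    def overlapping(self, query: Interval) -> list[Interval]:
        ivs = self.by_chrom.get(query.chrom)
        if not ivs:
            return []
        starts = self._starts[query.chrom]
        maxend = self._maxend[query.chrom]
        hi = int(np.searchsorted(starts, query.end, side="left"))
        lo = int(np.searchsorted(maxend[:hi], query.start, side="right"))
        return [iv for iv in ivs[lo:hi] if iv.end > query.start]

    def any_overlap(self, query: Interval) -> bool:
        return bool(self.overlapping(query))

    def nearest_distance(self, query: Interval) -> int | None:
        """Gap to the nearest interval on the same chromosome (0 if overlapping)."""
        ivs = self.by_chrom.get(query.chrom)
        if not ivs:
            return None
        if self.any_overlap(query):
            return 0
        best = None
        starts = self._starts[query.chrom]
        maxend = self._maxend[query.chrom]
        pos = int(np.searchsorted(starts, query.end, side="left"))
        if pos < len(ivs):
            best = int(starts[pos]) - query.end
        # scan left; the running max of ends bounds what earlier intervals
        # can still achieve, so the scan stops early on sorted data
        for i in range(pos - 1, -1, -1):
            if best is not None and query.start - int(maxend[i]) >= best:
                break
            gap = max(0, query.start - ivs[i].end)
            if best is None or gap < best:
                best = gap
            if best == 0:
                break
        return best


def coverage_fraction(target: Interval, index: IntervalIndex) -> float:
    """Fraction of target covered by the union of indexed intervals."""
    hits = index.overlapping(target)
    if not hits:
        return 0.0
    covered = 0
    last_end = target.start
    for iv in sorted(hits, key=lambda x: x.start):
        s = max(iv.start, last_end)
        e = min(iv.end, target.end)
        if e > s:
            covered += e - s
            last_end = e
    return covered / len(target)
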