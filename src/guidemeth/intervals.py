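"""Genomic interval primitives.

All coordinates are 0-based, half-open.  The overlap rule everywhere in the
package is ">= 1 bp": two intervals overlap iff their half-open spans
intersect.  The query index is backed by an interval tree; its correctness
contract (identical results to a linear scan) is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

from intervaltree import IntervalTree


@dataclass(frozen=True)
class Interval:
    """A genomic interval (0-based, half-open) with optional BED-style fields."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(require 0 <= start < end)"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


class IntervalSet:
    """A queryable collection of intervals, sorted by (chrom, start).

    ``overlapping(chrom, start, end)`` returns exactly the members sharing at
    least one base with the query.
    """

    def __init__(self, intervals: Iterable[Interval] = ()) -> None:
        self.intervals: List[Interval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._trees: Dict[str, IntervalTree] = {}
        # payload is the list index so equal intervals are not deduplicated
        for i, iv in enumerate(self.intervals):
            self._trees.setdefault(iv.chrom, IntervalTree()).addi(
                iv.start, iv.end, i
            )

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __bool__(self) -> bool:
        return bool(self.intervals)

    def overlapping(self, chrom: str, start: int, end: int) -> List[Interval]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        idx = sorted(hit.data for hit in tree.overlap(start, end))
        return [self.intervals[i] for i in idx]

    def overlaps_any(self, iv: Interval) -> bool:
        tree = self._trees.get(iv.chrom)
        return tree is not None and bool(tree.overlap(iv.start, iv.end))

    def total_length(self) -> int:
        return sum(iv.length for iv in self.intervals)


def overlap_count(set_a: IntervalSet, set_b: IntervalSet) -> Tuple[int, int]:
    """Count members of each set that overlap >= 1 member of the other.

    A member overlapping several intervals on the other side counts once,
    which is the convention used for Venn-style DMR set comparisons.
    """
    a_hits = sum(1 for iv in set_a if set_b.overlaps_any(iv))
    b_hits = sum(1 for iv in set_b if set_a.overlaps_any(iv))
    return a_hits, b_hits


def expand_flanks(
    regions: Iterable[Interval],
    flank: int = 100,
    chrom_sizes: Optional[Mapping[str, int]] = None,
) -> List[Interval]:
    """Extend each interval by ``flank`` bp on both sides.

    Clipped to [0, chromosome length); resulting overlaps between expanded
    windows are deliberately not merged, so window counts are preserved.
    """
    out: List[Interval] = []
    for iv in regions:
        start = max(0, iv.start - flank)
        end = iv.end + flank
        if chrom_sizes is not None:
            limit = chrom_sizes.get(iv.chrom)
            if limit is not None:
                end = min(end, limit)
        out.append(replace(iv, start=start, end=end))
    return out
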