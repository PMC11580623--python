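"""1-based fully-closed genomic intervals.

All coordinates in this package are 1-based and inclusive on both ends
(length = end - start + 1), matching how positions are printed in the
genomics literature. BED output is converted to 0-based half-open only at
the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field


class IntervalError(ValueError):
    """Raised for malformed coordinates (start > end, start < 1)."""


def interval_length(start: int, end: int) -> int:
    """Length in bp of the 1-based inclusive interval [start, end]."""
    if start > end:
        raise IntervalError(f"start {start} > end {end}")
    return end - start + 1


@dataclass(frozen=True)
class GenomicRegion:
    """A tagged interval on a chromosome.

    kind is one of ``sex_linked``, ``sex_specific_haploid``, ``sdr``,
    ``flank`` or a free-form tag; ``sex`` marks sex-limited regions
    (e.g. the W-only insertion carries sex='F' under ZW).
    """

    chrom: str
    start: int
    end: int
    kind: str = "region"
    sex: str | None = None
    provenance: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.start < 1:
            raise IntervalError(f"start {self.start} < 1")
        if self.start > self.end:
            raise IntervalError(f"start {self.start} > end {self.end}")

    @property
    def length(self) -> int:
        return interval_length(self.start, self.end)

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def overlaps(self, other: "GenomicRegion") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def overlap_bp(self, other: "GenomicRegion") -> int:
        if not self.overlaps(other):
            return 0
        return min(self.end, other.end) - max(self.start, other.start) + 1


def merge_intervals(intervals, gap: int = 0):
    """Merge 1-based inclusive (start, end) pairs.

    Intervals separated by at most ``gap`` uncovered bases are joined
    (gap=0 merges overlapping or bookended intervals).
    """
    ivs = sorted((int(s), int(e)) for s, e in intervals)
    if not ivs:
        return []
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1] + gap + 1:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(iv) for iv in out]


def union_length(intervals) -> int:
    return sum(interval_length(s, e) for s, e in merge_intervals(intervals))


def jaccard(a, b) -> float:
    """Jaccard overlap of two 1-based inclusive intervals."""
    (s1, e1), (s2, e2) = (a[0], a[1]), (b[0], b[1])
    inter = max(0, min(e1, e2) - max(s1, s2) + 1)
    union = interval_length(s1, e1) + interval_length(s2, e2) - inter
    return inter / union if union else 0.0
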