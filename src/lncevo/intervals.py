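"""Half-open genomic intervals and elementary interval arithmetic.

All coordinates in this package are 0-based half-open on the forward
strand of the chromosome; strand is carried separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A stranded interval on a chromosome, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"start > end: {self}")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", stranded: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if stranded and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_len(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Minimal sorted set of disjoint intervals covering the input bases.

    Book-ended intervals ([a,b) and [b,c)) are merged.  Input must be on a
    single chromosome and strand; the output inherits them.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    strands = {iv.strand for iv in ivs}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValueError("merge_intervals requires one chrom and strand")
    out: list[GenomicInterval] = []
    cur_s, cur_e = ivs[0].start, ivs[0].end
    for iv in ivs[1:]:
        if iv.start <= cur_e:
            cur_e = max(cur_e, iv.end)
        else:
            out.append(GenomicInterval(ivs[0].chrom, cur_s, cur_e, ivs[0].strand))
            cur_s, cur_e = iv.start, iv.end
    out.append(GenomicInterval(ivs[0].chrom, cur_s, cur_e, ivs[0].strand))
    return out


def total_length(intervals: Sequence[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


def subtract_intervals(
    intervals: Sequence[GenomicInterval], mask: Sequence[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases of `intervals` not covered by `mask` (strand-blind, per chrom)."""
    out: list[GenomicInterval] = []
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for m in mask:
        by_chrom.setdefault(m.chrom, []).append(m)
    for iv in intervals:
        cuts = sorted(
            (m for m in by_chrom.get(iv.chrom, []) if m.start < iv.end and iv.start < m.end),
            key=lambda m: m.start,
        )
        pos = iv.start
        for m in cuts:
            if m.start > pos:
                out.append(GenomicInterval(iv.chrom, pos, m.start, iv.strand))
            pos = max(pos, m.end)
            if pos >= iv.end:
                break
        if pos < iv.end:
            out.append(GenomicInterval(iv.chrom, pos, iv.end, iv.strand))
    return out


def union_overlap_len(
    intervals: Sequence[GenomicInterval], others: Sequence[GenomicInterval]
) -> int:
    """Number of bases of the union of `intervals` covered by the union of `others`."""
    n = 0
    by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    merged_a = {c: merge_intervals([GenomicInterval(c, iv.start, iv.end) for iv in ivs])
                for c, ivs in by_chrom.items()}
    by_chrom_b: dict[str, list[GenomicInterval]] = {}
    for iv in others:
        by_chrom_b.setdefault(iv.chrom, []).append(iv)
    for c, ivs in merged_a.items():
        if c not in by_chrom_b:
            continue
        merged_b = merge_intervals([GenomicInterval(c, iv.start, iv.end) for iv in by_chrom_b[c]])
        for a in ivs:
            for b in merged_b:
                n += a.overlap_len(b)
    return n
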