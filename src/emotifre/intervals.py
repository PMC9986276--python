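"""Genomic interval arithmetic for enhancer candidate filtering.

All coordinates are BED-convention 0-based half-open.  The operations here
implement the peak bookkeeping that turns open-chromatin candidate regions
into fixed-length active / non-active enhancer sets: partition by histone-mark
overlap, promoter-proximal exclusion around annotated TSSs, and re-centering
to a fixed window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)


class IntervalParseError(ValueError):
    """Raised when a BED/narrowPeak line cannot be interpreted."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval.

    ``score`` carries the narrowPeak column-5 value when present; ``strand``
    is one of ``+``, ``-`` or ``.`` (unstranded).
    """

    chrom: str
    start: int
    end: int
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class DatasetConfig:
    """Parameters of dataset construction.

    ``promoter_window`` is the (upstream, downstream) offset pair around a
    TSS, in bp, defining the promoter-proximal exclusion zone; the default
    (-1000, +100) mirrors the standard promoter-TSS annotation rule.
    """

    target_length: int = 500
    promoter_window: tuple[int, int] = (-1000, 100)
    max_n_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.promoter_window[0] >= self.promoter_window[1]:
            raise ValueError("promoter_window upstream offset must be < downstream")
        if self.target_length <= 0:
            raise ValueError("target_length must be positive")


def parse_intervals(path: str) -> list[GenomicInterval]:
    """Parse a BED3+/narrowPeak file into intervals, preserving file order.

    Column 5 (0-based index 4), when present and numeric, is kept as the
    score; column 6 as the strand.  Malformed lines raise
    :class:`IntervalParseError` naming the offending line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalParseError(
                    f"{path}:{lineno}: expected >=3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise IntervalParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            score = None
            if len(fields) >= 5:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) >= 6 and fields[5] in "+-." else "."
            try:
                out.append(
                    GenomicInterval(fields[0], start, end, score=score, strand=strand)
                )
            except ValueError as exc:
                raise IntervalParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_intervals(intervals: Iterable[GenomicInterval], path: str) -> None:
    """Write intervals as BED6 (score 0 when absent)."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = 0 if iv.score is None else iv.score
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t.\t{score}\t{iv.strand}\n")


def filter_by_signal(
    candidates: Sequence[GenomicInterval],
    bedgraph_path: str,
    threshold: float,
) -> list[GenomicInterval]:
    """Convenience surrogate for an upstream enhancer-candidate filter: keep
    candidates whose mean signal over a bedGraph track exceeds ``threshold``.

    This is NOT part of the published preprocessing (which consumes an
    already-filtered candidate set); it is offered for users who only have a
    raw signal track.  Bases not covered by any bedGraph record count as
    signal 0.
    """
    records: dict[str, list[tuple[int, int, float]]] = {}
    with open(bedgraph_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise IntervalParseError(
                    f"{bedgraph_path}:{lineno}: expected 4 columns"
                )
            records.setdefault(fields[0], []).append(
                (int(fields[1]), int(fields[2]), float(fields[3]))
            )
    kept = []
    for cand in candidates:
        total = 0.0
        for start, end, value in records.get(cand.chrom, []):
            overlap = min(cand.end, end) - max(cand.start, start)
            if overlap > 0:
                total += overlap * value
        if total / len(cand) > threshold:
            kept.append(cand)
    return kept


def split_by_overlap(
    candidates: Sequence[GenomicInterval], marks: Sequence[GenomicInterval]
) -> tuple[list[GenomicInterval], list[GenomicInterval]]:
    """Partition candidates by any-overlap (>=1 bp) against mark peaks.

    Returns ``(with_mark, without_mark)``; in the enhancer setting the first
    list (open chromatin overlapping an H3K27ac peak) is the active set and
    the second the non-active set.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for m in marks:
        by_chrom.setdefault(m.chrom, []).append((m.start, m.end))
    for spans in by_chrom.values():
        spans.sort()

    import bisect

    with_mark: list[GenomicInterval] = []
    without_mark: list[GenomicInterval] = []
    for cand in candidates:
        spans = by_chrom.get(cand.chrom, [])
        # marks with start < cand.end are the only possible overlappers
        i = bisect.bisect_left(spans, (cand.end, -1))
        hit = any(end > cand.start for _, end in spans[:i])
        (with_mark if hit else without_mark).append(cand)
    return with_mark, without_mark


def promoter_span(
    tss: GenomicInterval, window: tuple[int, int] = (-1000, 100)
) -> tuple[int, int]:
    """Exclusion span around a 1-bp TSS, strand-mirrored.

    On the + strand a window (-u, +d) gives [t-u, t+d); on the - strand
    "upstream" points right, so the span is [t-d, t+u).
    """
    up, down = window
    t = tss.start
    if tss.strand == "-":
        lo, hi = t - down, t - up
    else:
        lo, hi = t + up, t + down
    return max(0, lo), hi


def exclude_promoters(
    intervals: Sequence[GenomicInterval],
    tss: Sequence[GenomicInterval],
    window: tuple[int, int] = (-1000, 100),
) -> list[GenomicInterval]:
    """Drop intervals overlapping any promoter-proximal window; keep order."""
    spans_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for t in tss:
        lo, hi = promoter_span(t, window)
        spans_by_chrom.setdefault(t.chrom, []).append((lo, hi))
    kept = []
    for iv in intervals:
        spans = spans_by_chrom.get(iv.chrom, [])
        if not any(iv.start < hi and lo < iv.end for lo, hi in spans):
            kept.append(iv)
    return kept


def center_fix_length(
    intervals: Sequence[GenomicInterval],
    n: int,
    chrom_sizes: dict[str, int] | None = None,
) -> list[GenomicInterval]:
    """Re-center each interval to exactly ``n`` bp around its midpoint.

    The midpoint is floor((start+end)/2); the output interval is
    [c - floor(n/2), c + ceil(n/2)).  Intervals that would extend past
    chromosome bounds (when ``chrom_sizes`` is given) or below zero are
    dropped with a logged warning.
    """
    if n <= 0:
        raise ValueError("target length must be positive")
    half_lo = n // 2
    half_hi = n - half_lo
    out = []
    n_dropped = 0
    for iv in intervals:
        c = (iv.start + iv.end) // 2
        start, end = c - half_lo, c + half_hi
        size = None if chrom_sizes is None else chrom_sizes.get(iv.chrom)
        if start < 0 or (size is not None and end > size):
            n_dropped += 1
            continue
        out.append(
            GenomicInterval(iv.chrom, start, end, score=iv.score, strand=iv.strand)
        )
    if n_dropped:
        logger.warning("center_fix_length dropped %d out-of-bounds intervals", n_dropped)
    return out
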