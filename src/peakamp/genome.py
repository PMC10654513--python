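"""Genome coordinate conventions, interval algebra, and region classes.

All coordinates are 0-based half-open (BED convention). A promoter built
from ``flank=1000`` is the 2000-bp window ``[tss-1000, tss+1000)``. Overlap
between intervals means >= ``min_overlap_bp`` shared bases (default 1);
strand is ignored for overlap throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: region classes, in label precedence order (promoter wins over dTRE, etc.)
REGION_CLASSES = ("promoter", "dTRE", "enhancer", "remote")


class Genome:
    """An ordered set of named chromosomes with lengths in bp."""

    def __init__(self, chroms: dict[str, int] | Sequence[tuple[str, int]]):
        items = list(chroms.items()) if isinstance(chroms, dict) else list(chroms)
        names = [c for c, _ in items]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in items:
            if int(length) < 1:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        self._lengths: dict[str, int] = {c: int(n) for c, n in items}

    @property
    def chrom_names(self) -> tuple[str, ...]:
        return tuple(self._lengths)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"chromosome {chrom!r} not in genome") from None

    @property
    def total_length(self) -> int:
        return sum(self._lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self._lengths.items())

    def __eq__(self, other) -> bool:
        return isinstance(other, Genome) and self._lengths == other._lengths

    def __repr__(self) -> str:
        return f"Genome({len(self._lengths)} chroms, {self.total_length} bp)"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open interval [start, end) on a chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval", min_overlap_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_overlap_bp


class IntervalSet:
    """A named collection of intervals with sorted/merged normal forms.

    Internally keeps per-chromosome sorted start/end arrays of the *merged*
    intervals for fast overlap queries; the original records are preserved.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = (), name: str = ""):
        self.name = name
        self.intervals: list[GenomicInterval] = sorted(
            intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )
        self._merged_index: dict[str, tuple[np.ndarray, np.ndarray]] | None = None

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __eq__(self, other) -> bool:
        return isinstance(other, IntervalSet) and self.intervals == other.intervals

    @property
    def total_span(self) -> int:
        """Total bp covered after merging (overlaps counted once)."""
        return sum(len(iv) for iv in self.merge())

    def merge(self) -> "IntervalSet":
        """Return the union as pairwise-disjoint sorted intervals.

        Touching intervals ([0,5) and [5,10)) are kept separate: only
        genuinely overlapping (>=1 shared base) intervals coalesce.
        """
        merged: list[GenomicInterval] = []
        for iv in self.intervals:
            if merged and merged[-1].chrom == iv.chrom and iv.start < merged[-1].end:
                last = merged[-1]
                if iv.end > last.end:
                    merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
            else:
                merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
        return IntervalSet(merged, name=self.name)

    def _index(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        if self._merged_index is None:
            idx: dict[str, list[list[int]]] = {}
            for iv in self.merge():
                idx.setdefault(iv.chrom, [[], []])
                idx[iv.chrom][0].append(iv.start)
                idx[iv.chrom][1].append(iv.end)
            self._merged_index = {
                c: (np.asarray(s), np.asarray(e)) for c, (s, e) in idx.items()
            }
        return self._merged_index

    def overlaps(self, iv: GenomicInterval, min_overlap_bp: int = 1) -> bool:
        """True if any interval of this set shares >= min_overlap_bp with iv."""
        idx = self._index()
        if iv.chrom not in idx:
            return False
        starts, ends = idx[iv.chrom]
        # merged intervals are disjoint & sorted: candidates are those whose
        # end exceeds iv.start and whose start precedes iv.end
        i = int(np.searchsorted(ends, iv.start, side="right"))
        while i < len(starts) and starts[i] < iv.end:
            if min(ends[i], iv.end) - max(starts[i], iv.start) >= min_overlap_bp:
                return True
            i += 1
        return False

    def overlaps_any(
        self, query: Iterable[GenomicInterval], min_overlap_bp: int = 1
    ) -> np.ndarray:
        return np.array([self.overlaps(iv, min_overlap_bp) for iv in query], dtype=bool)

    def contains_points(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Membership of point positions (bp) in the merged set."""
        idx = self._index()
        positions = np.asarray(positions)
        if chrom not in idx:
            return np.zeros(positions.shape, dtype=bool)
        starts, ends = idx[chrom]
        i = np.searchsorted(starts, positions, side="right") - 1
        ok = i >= 0
        res = np.zeros(positions.shape, dtype=bool)
        res[ok] = positions[ok] < ends[i[ok]]
        return res


def merge(s: IntervalSet) -> IntervalSet:
    return s.merge()


def subtract(a: IntervalSet, b: IntervalSet, min_overlap_bp: int = 1) -> IntervalSet:
    """Intervals of ``a`` with zero overlap with any interval of ``b``.

    Whole-interval exclusion (the blacklist-filtering semantics): an interval
    of ``a`` touching ``b`` anywhere is dropped entirely, never trimmed.
    """
    if len(b) == 0:
        return IntervalSet(a.intervals, name=a.name)
    keep = ~b.overlaps_any(a.intervals, min_overlap_bp=min_overlap_bp)
    return IntervalSet(
        [iv for iv, k in zip(a.intervals, keep) if k], name=a.name
    )


@dataclass(frozen=True)
class GeneAnnotation:
    """A gene with TSS/TES in genomic coordinates.

    For minus-strand genes ``tss > tes`` numerically; the occupied interval
    is ``[min(tss,tes), max(tss,tes))``.
    """

    gene_id: str
    chrom: str
    tss: int
    tes: int
    strand: str

    def __post_init__(self):
        if self.tss == self.tes:
            raise ValueError(f"gene {self.gene_id}: tss == tes")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def start(self) -> int:
        return min(self.tss, self.tes)

    @property
    def end(self) -> int:
        return max(self.tss, self.tes)

    @property
    def length(self) -> int:
        return self.end - self.start


def promoter_regions(
    genes: Sequence[GeneAnnotation], genome: Genome, flank: int = 1000
) -> IntervalSet:
    """Strand-symmetric promoter windows [tss-flank, tss+flank), clipped.

    One interval per gene (gene_id carried as the interval name); overlapping
    promoters of nearby genes are retained individually, not merged, so that
    per-gene fractions stay well defined. Genes whose TSS falls outside the
    genome are rejected with a logged warning.
    """
    if flank <= 0:
        raise ValueError("flank must be positive")
    out = []
    for g in genes:
        if g.chrom not in genome or not (0 <= g.tss <= genome.length(g.chrom)):
            logger.warning("gene %s: TSS %s:%d outside genome; skipped",
                           g.gene_id, g.chrom, g.tss)
            continue
        lo = max(0, g.tss - flank)
        hi = min(genome.length(g.chrom), g.tss + flank)
        out.append(GenomicInterval(g.chrom, lo, hi, strand=g.strand, name=g.gene_id))
    return IntervalSet(out, name="promoters")


def classify_intervals(
    query: IntervalSet,
    promoters: IntervalSet,
    dtres: IntervalSet,
    enhancers: IntervalSet,
    genome: Genome | None = None,
    min_overlap_bp: int = 1,
) -> list[str]:
    """Label each query interval promoter/dTRE/enhancer/remote.

    Precedence promoter > dTRE > enhancer; anything touching none of the
    three annotation sets is "remote". Order follows ``query.intervals``.
    """
    if genome is not None:
        for iv in query:
            if iv.chrom not in genome:
                raise KeyError(f"chromosome {iv.chrom!r} not in genome")
    labels = []
    for iv in query.intervals:
        if promoters.overlaps(iv, min_overlap_bp):
            labels.append("promoter")
        elif dtres.overlaps(iv, min_overlap_bp):
            labels.append("dTRE")
        elif enhancers.overlaps(iv, min_overlap_bp):
            labels.append("enhancer")
        else:
            labels.append("remote")
    return labels
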