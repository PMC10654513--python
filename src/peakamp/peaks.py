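"""Peak tables, replicate merging, Venn algebra, and background sampling."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genome import Genome, GenomicInterval, IntervalSet
from .tracks import CoverageTrack, SampleMeta, signal_at

logger = logging.getLogger(__name__)


class PeakTable:
    """Intervals + per-sample signal columns, backed by a DataFrame.

    Columns: chrom, start, end, peak_id, then one column per sample signal.
    """

    def __init__(self, df: pd.DataFrame, name: str = ""):
        required = {"chrom", "start", "end"}
        if not required.issubset(df.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        if "peak_id" not in df.columns:
            df.insert(3, "peak_id", [f"{name or 'peak'}_{i}" for i in range(len(df))])
        if df["peak_id"].duplicated().any():
            raise ValueError("peak_ids must be unique")
        self.df = df
        self.name = name

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval], name: str = "") -> "PeakTable":
        rows = [(iv.chrom, iv.start, iv.end) for iv in intervals]
        return cls(pd.DataFrame(rows, columns=["chrom", "start", "end"]), name=name)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), name=str(r.peak_id))
            for r in self.df.itertuples()
        ]

    def interval_set(self) -> IntervalSet:
        return IntervalSet(self.intervals, name=self.name)

    def add_signal(self, column: str, track: CoverageTrack, stat: str = "mean") -> None:
        vals = signal_at(track, self.intervals, stat=stat)
        if np.any(vals < 0):
            raise ValueError("signal columns must be non-negative")
        self.df[column] = vals


@dataclass
class VennResult:
    only_a: int
    only_b: int
    common: int

    @property
    def pct_common(self) -> float:
        total = self.only_a + self.only_b + self.common
        if total == 0:
            return float("nan")  # NA: both inputs empty
        return 100.0 * self.common / total


def _union_merge(tables: Sequence[PeakTable]) -> IntervalSet:
    ivs = [iv for t in tables for iv in t.intervals]
    return IntervalSet(ivs).merge()


def merge_replicates(
    rep1: PeakTable, rep2: PeakTable, mode: Literal["union", "intersection"]
) -> PeakTable:
    """Merge two replicate peak lists.

    union: every merged locus present in either replicate is kept.
    intersection: a merged locus is kept only if it overlaps at least one
    peak from EACH replicate (the both-replicates rule).
    New peak_ids are assigned deterministically by coordinate.
    """
    if mode not in ("union", "intersection"):
        raise ValueError(f"unknown mode {mode!r}")
    merged = _union_merge([rep1, rep2])
    if mode == "intersection":
        s1, s2 = rep1.interval_set(), rep2.interval_set()
        kept = [iv for iv in merged if s1.overlaps(iv) and s2.overlaps(iv)]
    else:
        kept = list(merged)
    return PeakTable.from_intervals(kept, name=f"{rep1.name or 'rep'}_{mode}")


def venn(a: PeakTable, b: PeakTable) -> tuple[VennResult, pd.DataFrame]:
    """Label each merged locus of a ∪ b as a_only / b_only / common.

    Counting is per merged locus (one merged interval = one count), so
    only_a + only_b + common is a well-defined denominator for pct_common.
    """
    merged = _union_merge([a, b])
    sa, sb = a.interval_set(), b.interval_set()
    labels = []
    for iv in merged:
        in_a, in_b = sa.overlaps(iv), sb.overlaps(iv)
        labels.append("common" if in_a and in_b else ("a_only" if in_a else "b_only"))
    df = pd.DataFrame(
        {
            "chrom": [iv.chrom for iv in merged],
            "start": [iv.start for iv in merged],
            "end": [iv.end for iv in merged],
            "label": labels,
        }
    )
    res = VennResult(
        only_a=int((df["label"] == "a_only").sum()),
        only_b=int((df["label"] == "b_only").sum()),
        common=int((df["label"] == "common").sum()),
    )
    return res, df


def exclusive_and_common_classes(
    tables: dict[str, PeakTable]
) -> pd.DataFrame:
    """k-set generalization of venn: each merged locus gets the subset of
    condition names whose peaks overlap it (comma-joined, sorted)."""
    if len(tables) < 2:
        raise ValueError("need at least two conditions")
    merged = _union_merge(list(tables.values()))
    sets = {name: t.interval_set() for name, t in tables.items()}
    rows = []
    for iv in merged:
        members = sorted(name for name, s in sets.items() if s.overlaps(iv))
        rows.append((iv.chrom, iv.start, iv.end, ",".join(members)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "members"])


def class_intervals(classes: pd.DataFrame, members: str) -> list[GenomicInterval]:
    """Merged loci whose membership equals ``members`` exactly."""
    sub = classes[classes["members"] == members]
    return [GenomicInterval(r.chrom, int(r.start), int(r.end)) for r in sub.itertuples()]


def average_peak_size(table: PeakTable) -> int:
    if len(table) == 0:
        raise ValueError("empty peak table has no average size")
    return int(round(float((table.df["end"] - table.df["start"]).mean())))


@dataclass
class BackgroundSpec:
    n_requested: int
    region_size: int
    exclusions: IntervalSet
    seed: int

    def __post_init__(self):
        if self.region_size <= 0:
            raise ValueError("region_size must be positive")
        if self.n_requested <= 0:
            raise ValueError("n_requested must be positive")


def sample_background(spec: BackgroundSpec, genome: Genome) -> IntervalSet:
    """Uniform random regions, then filtered against the exclusion set.

    Chromosome is chosen proportional to its length, start uniform over the
    valid range. Regions overlapping any exclusion are dropped WITHOUT
    resampling, so the returned count may be below ``n_requested`` (the
    filter-then-return behavior; the retained count is logged). Sampling is
    with replacement; duplicate draws are logged.
    """
    rng = np.random.default_rng(spec.seed)
    eligible = [(c, L) for c, L in genome if L >= spec.region_size]
    if not eligible:
        raise ValueError(f"region_size {spec.region_size} exceeds every chromosome")
    names = [c for c, _ in eligible]
    lengths = np.array([L for _, L in eligible], dtype=float)
    probs = lengths / lengths.sum()
    chrom_idx = rng.choice(len(names), size=spec.n_requested, p=probs)
    out = []
    for i in chrom_idx:
        start = int(rng.integers(0, int(lengths[i]) - spec.region_size + 1))
        out.append(GenomicInterval(names[i], start, start + spec.region_size))
    n_dup = len(out) - len({(iv.chrom, iv.start) for iv in out})
    if n_dup:
        logger.info("background sampling: %d duplicate regions drawn", n_dup)
    if len(spec.exclusions):
        keep = ~spec.exclusions.overlaps_any(out)
        out = [iv for iv, k in zip(out, keep) if k]
    logger.info("background sampling: %d requested, %d retained after filtering",
                spec.n_requested, len(out))
    return IntervalSet(out, name="background")
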