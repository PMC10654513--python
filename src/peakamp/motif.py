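"""Heat-shock-element (HSE/HRE) consensus scanning and genomic density nulls.

The HSE is modeled as its canonical consensus: a run of at least
``min_units`` pentamer units nGAAn whose GAA cores alternate strand, i.e.
the core at unit *i* reads GAA for even *i* and TTC for odd *i* (the
GAA-first phase) or the complementary TTC-first phase. An explicit consensus
scanner is used rather than a position-weight matrix: it is exactly
reproducible and has a trivially checkable brute-force oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import Genome, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

_VALID = frozenset(b"ACGTN")


@dataclass(frozen=True)
class HreModel:
    """Consensus HSE: >= min_units alternating nGAAn/nTTCn pentamers.

    ``max_mismatches`` is the number of core positions (of 3) allowed to
    mismatch within each pentamer unit; N never matches a core position.
    """

    min_units: int = 3
    max_mismatches: int = 0

    def __post_init__(self):
        if self.min_units < 2:
            raise ValueError("min_units must be >= 2")
        if not (0 <= self.max_mismatches <= 3):
            raise ValueError("max_mismatches must be in 0..3")


@dataclass(frozen=True)
class MotifHit:
    interval: GenomicInterval
    phase: str  # "GAA-first" | "TTC-first"
    n_units: int
    score: int  # matched core positions


def _core_mismatches(s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per unit-start position, mismatch counts of the 3 core bases vs GAA / TTC."""
    mm_gaa = (
        (s[1:-3] != ord("G")).astype(np.int8)
        + (s[2:-2] != ord("A")).astype(np.int8)
        + (s[3:-1] != ord("A")).astype(np.int8)
    )
    mm_ttc = (
        (s[1:-3] != ord("T")).astype(np.int8)
        + (s[2:-2] != ord("T")).astype(np.int8)
        + (s[3:-1] != ord("C")).astype(np.int8)
    )
    return mm_gaa, mm_ttc


def _true_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start, length) of maximal runs of True."""
    if not len(mask):
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def scan_hre(
    sequence: str, model: HreModel = HreModel(), chrom: str = "seq"
) -> list[MotifHit]:
    """All maximal HSE hits in either phase; case-insensitive.

    Hits are maximal runs: not extendable by another matching pentamer on
    either side. Overlapping hits of different phase are both reported.
    """
    seq = sequence.upper()
    s = np.frombuffer(seq.encode("ascii", errors="replace"), dtype=np.uint8)
    bad = ~np.isin(s, np.frombuffer(bytes(_VALID), dtype=np.uint8))
    if bad.any():
        pos = int(np.argmax(bad))
        raise ValueError(f"non-DNA character {seq[pos]!r} at position {pos}")
    n = len(s)
    if n < 5 * model.min_units:
        return []
    mm_gaa, mm_ttc = _core_mismatches(s)
    g = mm_gaa <= model.max_mismatches
    t = mm_ttc <= model.max_mismatches

    hits: list[MotifHit] = []
    for c in range(5):
        gc, tc = g[c::5], t[c::5]
        if not len(gc):
            continue
        j = np.arange(len(gc))
        even = j % 2 == 0
        # phase alignment A: even chain index -> GAA core; B: even -> TTC
        for mask, even_core in ((np.where(even, gc, tc), "GAA"),
                                (np.where(even, tc, gc), "TTC")):
            for j0, k in _true_runs(mask):
                if k < model.min_units:
                    continue
                starts_gaa = even_core == ("GAA" if j0 % 2 == 0 else "TTC")
                phase = "GAA-first" if starts_gaa else "TTC-first"
                p0 = c + 5 * j0
                units = np.arange(j0, j0 + k)
                unit_pos = c + 5 * units
                first_is_gaa = phase == "GAA-first"
                is_gaa_unit = (units - j0) % 2 == (0 if first_is_gaa else 1)
                mm = np.where(is_gaa_unit, mm_gaa[unit_pos], mm_ttc[unit_pos])
                hits.append(
                    MotifHit(
                        interval=GenomicInterval(chrom, p0, p0 + 5 * k),
                        phase=phase,
                        n_units=k,
                        score=int(3 * k - mm.sum()),
                    )
                )
    hits.sort(key=lambda h: (h.interval.start, h.interval.end, h.phase))
    return hits


def scan_genome(
    sequences: dict[str, str], model: HreModel = HreModel()
) -> list[MotifHit]:
    out = []
    for chrom, seq in sequences.items():
        out.extend(scan_hre(seq, model, chrom=chrom))
    return out


def hits_to_interval_set(hits: Sequence[MotifHit], name: str = "hre_hits") -> IntervalSet:
    return IntervalSet([h.interval for h in hits], name=name)


def observed_vs_expected(
    features: IntervalSet, regions: IntervalSet, genome: Genome
) -> tuple[int, float, float]:
    """Observed vs expected feature density in a region set.

    Features count by midpoint containment (so inside + outside partitions
    the total exactly); expected assumes the same number of features spread
    evenly over the genome: total * merged_region_length / genome_length.
    """
    if genome.total_length <= 0:
        raise ValueError("zero-length genome")
    merged = regions.merge()
    region_len = merged.total_span
    total = len(features)
    observed = 0
    by_chrom: dict[str, list[int]] = {}
    for iv in features:
        by_chrom.setdefault(iv.chrom, []).append(iv.midpoint)
    for chrom, mids in by_chrom.items():
        observed += int(merged.contains_points(chrom, np.array(mids)).sum())
    expected = total * region_len / genome.total_length
    if expected == 0:
        if observed > 0:
            logger.warning("expected density is 0 with observed > 0; ratio = +inf")
            return observed, expected, float("inf")
        return observed, expected, float("nan")
    return observed, expected, observed / expected


def accessibility_stratified_motif_prevalence(
    peak_intervals: Sequence[GenomicInterval],
    atac_signal: np.ndarray,
    hits: IntervalSet,
    n_strata: int = 4,
) -> tuple[pd.DataFrame, float, float]:
    """Fraction of peaks containing an HSE hit, stratified by accessibility.

    Strata are quantile bins of the ATAC value (stratum 0 = most closed).
    The trend statistic is the Spearman rank correlation between the ATAC
    value and the per-peak hit indicator, with its p-value.
    """
    from .stats import spearman

    atac_signal = np.asarray(atac_signal, dtype=float)
    if len(atac_signal) != len(peak_intervals):
        raise ValueError("one ATAC value per peak required")
    if n_strata > len(peak_intervals):
        raise ValueError("more strata than peaks")
    has_hit = hits.overlaps_any(peak_intervals).astype(int)
    order_rank = pd.Series(atac_signal).rank(method="first")
    strata = pd.qcut(order_rank, n_strata, labels=False)
    df = (
        pd.DataFrame({"stratum": strata, "has_hit": has_hit, "atac": atac_signal})
        .groupby("stratum")
        .agg(n=("has_hit", "size"), prevalence=("has_hit", "mean"),
             atac_median=("atac", "median"))
        .reset_index()
    )
    if has_hit.min() == has_hit.max():
        # all peaks hit (or none): no trend by construction
        return df, 0.0, 1.0
    rho, p = spearman(atac_signal, has_hit.astype(float))
    return df, rho, p
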