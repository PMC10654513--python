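"""Coverage tracks, normalization schemes, and peak-centered signal extraction.

Three normalizations are provided, mirroring how different assays are
treated in practice:

* ``scale_to_lowest_depth`` — multiply every track by min(depth)/depth so
  all totals match the shallowest library (used for the TF ChIP tracks);
* ``cpm_normalize`` — counts-per-million (used for ATAC and generic tracks);
* ``proseq_3prime_normalize`` — per-sample factors from the 3' ends of long
  genes, where a brief treatment cannot yet have changed polymerase density,
  making those windows an internal spike-in for nascent-RNA data.

All normalizations are linear, so signal extraction commutes with them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, Genome, GenomicInterval, IntervalSet

logger = logging.getLogger(__name__)

NormState = Literal["raw", "depth_scaled", "cpm", "proseq_3prime"]


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one sequencing track/peak set."""

    sample_id: str
    cell_line: str
    treatment: str  # NHS, HS, As
    assay: str  # chip, atac, pro, input
    replicate: int = 1
    strand: str = "."  # PRO-seq only

    @property
    def condition(self) -> str:
        return f"{self.cell_line}_{self.treatment}"


class CoverageTrack:
    """Per-base counts per chromosome with a declared normalization state."""

    def __init__(
        self,
        genome: Genome,
        data: dict[str, np.ndarray] | None = None,
        norm_state: NormState = "raw",
        meta: SampleMeta | None = None,
    ):
        self.genome = genome
        self.data = data or {
            c: np.zeros(n, dtype=np.float32) for c, n in genome
        }
        for c, arr in self.data.items():
            if len(arr) != genome.length(c):
                raise ValueError(f"array length mismatch on {c}")
        self.norm_state: NormState = norm_state
        self.meta = meta

    @property
    def depth(self) -> float:
        """Total counts over the genome (library depth when raw)."""
        return float(sum(np.sum(a, dtype=np.float64) for a in self.data.values()))

    def copy_scaled(self, factor: float, norm_state: NormState) -> "CoverageTrack":
        return CoverageTrack(
            self.genome,
            {c: (a * factor).astype(np.float32) for c, a in self.data.items()},
            norm_state=norm_state,
            meta=self.meta,
        )

    # ---- bedGraph I/O --------------------------------------------------

    def to_bedgraph(self, path: str) -> None:
        """Write as sorted 4-column bedGraph, run-length compressed, zeros omitted."""
        with open(path, "w") as fh:
            for chrom in self.genome.chrom_names:
                a = self.data[chrom]
                if not len(a):
                    continue
                change = np.nonzero(np.diff(a))[0] + 1
                starts = np.concatenate(([0], change))
                ends = np.concatenate((change, [len(a)]))
                vals = a[starts]
                for s, e, v in zip(starts, ends, vals):
                    if v != 0:
                        v = float(v)
                        vs = str(int(v)) if v.is_integer() else repr(v)
                        fh.write(f"{chrom}\t{s}\t{e}\t{vs}\n")

    @classmethod
    def from_bedgraph(
        cls, path: str, genome: Genome, meta: SampleMeta | None = None,
        norm_state: NormState = "raw",
    ) -> "CoverageTrack":
        track = cls(genome, meta=meta, norm_state=norm_state)
        from .io import _data_lines

        for f in _data_lines(path):
            chrom, start, end, value = f[0], int(f[1]), int(f[2]), float(f[3])
            track.data[chrom][start:end] += value
        return track


@dataclass
class StrandedTrack:
    """Plus/minus strand coverage pair (PRO-seq)."""

    plus: CoverageTrack
    minus: CoverageTrack

    def strand(self, s: str) -> CoverageTrack:
        if s == "+":
            return self.plus
        if s == "-":
            return self.minus
        raise ValueError(f"bad strand {s!r}")

    @property
    def depth(self) -> float:
        return self.plus.depth + self.minus.depth

    def copy_scaled(self, factor: float, norm_state: NormState) -> "StrandedTrack":
        return StrandedTrack(
            self.plus.copy_scaled(factor, norm_state),
            self.minus.copy_scaled(factor, norm_state),
        )


# ---- normalizations ----------------------------------------------------


def scale_to_lowest_depth(tracks: Sequence[CoverageTrack]) -> list[CoverageTrack]:
    """Scale every raw track by min(depth)/depth; totals equalize exactly."""
    if len(tracks) < 2:
        raise ValueError("need at least two tracks to co-scale")
    depths = [t.depth for t in tracks]
    if any(d <= 0 for d in depths):
        raise ValueError("zero-depth track cannot be depth-scaled")
    lowest = min(depths)
    return [
        t.copy_scaled(lowest / d, "depth_scaled") for t, d in zip(tracks, depths)
    ]


def cpm_normalize(track: CoverageTrack) -> CoverageTrack:
    """Counts-per-million: values * 1e6 / depth; normalized sum is 1e6."""
    d = track.depth
    if d <= 0:
        raise ValueError("zero-depth track cannot be CPM-normalized")
    return track.copy_scaled(1e6 / d, "cpm")


def _gene_3prime_window(
    gene: GeneAnnotation, window_offset: int, window_length: int
) -> GenomicInterval:
    """Window at the gene's 3' end: last ``window_length`` bp of the body
    excluding the final ``window_offset`` bp, on the sense strand."""
    if gene.strand == "+":
        lo = gene.tes - window_offset - window_length
        hi = gene.tes - window_offset
    else:
        lo = gene.tes + window_offset
        hi = gene.tes + window_offset + window_length
    return GenomicInterval(gene.chrom, lo, hi, strand=gene.strand)


def proseq_3prime_normalize(
    tracks: dict[str, StrandedTrack],
    genes: Sequence[GeneAnnotation],
    reference: str,
    min_gene_len: int = 60_000,
    window_offset: int = 500,
    window_length: int = 20_000,
) -> dict[str, float]:
    """Per-sample multiplicative factors from the 3' ends of long genes.

    factor(sample) = median over qualifying genes of
    (reference window density / sample window density). The reference's own
    factor is 1 by construction.
    """
    long_genes = [g for g in genes if g.length >= min_gene_len]
    if not long_genes:
        raise ValueError(
            f"no gene of length >= {min_gene_len}; lower min_gene_len"
        )
    if reference not in tracks:
        raise KeyError(f"reference sample {reference!r} not among tracks")

    windows = [_gene_3prime_window(g, window_offset, window_length) for g in long_genes]

    def densities(tr: StrandedTrack) -> np.ndarray:
        vals = []
        for g, w in zip(long_genes, windows):
            arr = tr.strand(g.strand).data[w.chrom][w.start:w.end]
            vals.append(float(np.sum(arr, dtype=np.float64)) / len(w))
        return np.array(vals)

    ref_dens = densities(tracks[reference])
    factors: dict[str, float] = {}
    for sid, tr in tracks.items():
        dens = densities(tr)
        ok = (dens > 0) & (ref_dens > 0)
        n_dropped = int(np.sum(~ok))
        if n_dropped:
            logger.warning("3' normalization %s: %d zero-density genes excluded",
                           sid, n_dropped)
        if not np.any(ok):
            raise ValueError(f"sample {sid}: no gene with nonzero 3' window density")
        factors[sid] = float(np.median(ref_dens[ok] / dens[ok]))
    return factors


# ---- extraction --------------------------------------------------------


def _clip_interval(iv: GenomicInterval, genome: Genome) -> GenomicInterval:
    L = genome.length(iv.chrom)
    if iv.end > L or iv.start < 0:
        logger.warning("interval %s:%d-%d clipped to chromosome bounds",
                       iv.chrom, iv.start, iv.end)
        return GenomicInterval(iv.chrom, max(0, iv.start), min(L, iv.end),
                               strand=iv.strand, name=iv.name)
    return iv


def signal_at(
    track: CoverageTrack,
    intervals: Iterable[GenomicInterval],
    stat: Literal["mean", "sum"] = "mean",
) -> np.ndarray:
    """Aggregate per-base values over each interval."""
    if stat not in ("mean", "sum"):
        raise ValueError(f"unknown stat {stat!r}")
    out = []
    for iv in intervals:
        iv = _clip_interval(iv, track.genome)
        seg = track.data[iv.chrom][iv.start:iv.end]
        s = float(np.sum(seg, dtype=np.float64))
        out.append(s / len(iv) if stat == "mean" else s)
    return np.array(out)


@dataclass
class ProfileMatrix:
    """Loci x position-bin matrix of signal around centers."""

    values: np.ndarray  # (n_loci, n_bins)
    centers: list[GenomicInterval]  # row identities, in row order
    bin_size: int
    flank: int
    row_order: np.ndarray  # permutation applied to the input center list

    @property
    def offsets(self) -> np.ndarray:
        """Bin-start offsets relative to the center, in bp."""
        return np.arange(-self.flank, self.flank, self.bin_size)


def centered_matrix(
    track: CoverageTrack,
    centers: Sequence[GenomicInterval],
    flank: int = 1000,
    bin: int = 50,
    sort_by: CoverageTrack | None = None,
    row_order: np.ndarray | None = None,
) -> ProfileMatrix:
    """Signal matrix centered at loci, optionally sorted by another sample.

    ``sort_by`` orders rows by descending total signal in that track within
    the same windows (ties broken by chrom, then start), the "sorted by
    replicate X" convention; ``row_order`` reuses a previously computed
    order so several tracks can share one sort.
    """
    if (2 * flank) % bin:
        raise ValueError("bin must divide 2*flank")
    n_bins = 2 * flank // bin
    mids = [iv.midpoint for iv in centers]
    mat = np.zeros((len(centers), n_bins))
    for i, (iv, mid) in enumerate(zip(centers, mids)):
        lo, hi = mid - flank, mid + flank
        L = track.genome.length(iv.chrom)
        seg = np.zeros(2 * flank, dtype=np.float64)
        s, e = max(0, lo), min(L, hi)
        if e > s:
            seg[s - lo : e - lo] = track.data[iv.chrom][s:e]
        mat[i] = seg.reshape(n_bins, bin).mean(axis=1)

    if row_order is None:
        if sort_by is not None:
            windows = [
                GenomicInterval(iv.chrom,
                                max(0, m - flank),
                                min(track.genome.length(iv.chrom), m + flank))
                for iv, m in zip(centers, mids)
            ]
            sums = signal_at(sort_by, windows, stat="sum")
        else:
            sums = mat.sum(axis=1)
        keys = list(zip(-sums, [c.chrom for c in centers], [c.start for c in centers]))
        row_order = np.array(sorted(range(len(centers)), key=keys.__getitem__))
    return ProfileMatrix(
        values=mat[row_order],
        centers=[centers[i] for i in row_order],
        bin_size=bin,
        flank=flank,
        row_order=row_order,
    )


def binned_offset_profile(
    track_pairs: dict[str, CoverageTrack],
    centers: Sequence[GenomicInterval],
    bin: int = 500,
    max_offset: int = 2000,
    background: IntervalSet | None = None,
) -> pd.DataFrame:
    """Mean signal +/- 95% CI in fixed-offset bins around centers.

    Bins tile ``[-max_offset - bin/2, +max_offset + bin/2)`` with a dedicated
    center bin "C" spanning ``center +/- bin/2``; offsets label the remaining
    bins by their distance from the center in bp. ``track_pairs`` maps
    condition name (e.g. NHS/HS) to its track. If ``background`` is given, a
    matched reference profile is computed at those region midpoints too.
    """
    if max_offset % bin:
        raise ValueError("max_offset must be a multiple of bin")
    k_max = max_offset // bin
    offsets = np.arange(-k_max, k_max + 1) * bin

    region_sets: dict[str, Sequence[GenomicInterval]] = {"peaks": centers}
    if background is not None and len(background):
        region_sets["background"] = background.intervals
    elif background is not None:
        logger.warning("empty background set; reference profile omitted")

    rows = []
    for region_name, locs in region_sets.items():
        mids = [iv.midpoint for iv in locs]
        for cond, track in track_pairs.items():
            per_bin = {off: [] for off in offsets}
            for iv, mid in zip(locs, mids):
                L = track.genome.length(iv.chrom)
                for off in offsets:
                    lo = mid + off - bin // 2
                    hi = lo + bin
                    s, e = max(0, lo), min(L, hi)
                    if e <= s:
                        continue
                    seg = track.data[iv.chrom][s:e]
                    per_bin[off].append(float(np.sum(seg, dtype=np.float64)) / bin)
            for off in offsets:
                vals = np.array(per_bin[off])
                m = float(vals.mean())
                sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else 0.0
                rows.append({
                    "region": region_name,
                    "condition": cond,
                    "offset": int(off),
                    "offset_label": "C" if off == 0 else f"{off:+d}",
                    "mean": m,
                    "ci_lo": m - 1.96 * sem,
                    "ci_hi": m + 1.96 * sem,
                    "n": len(vals),
                })
    return pd.DataFrame(rows)
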