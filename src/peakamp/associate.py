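"""Cross-tabulations linking peak presence to transcription and accessibility.

Gene bodies are taken as [TSS+offset, TES) on the gene's sense strand with a
default offset of 500 bp to exclude the promoter-proximal pause. Fold
computations use a pseudocount so silent genes yield bounded folds.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GeneAnnotation, GenomicInterval, IntervalSet
from .peaks import PeakTable
from .stats import TestResult, mann_whitney
from .tracks import CoverageTrack, StrandedTrack, signal_at

logger = logging.getLogger(__name__)


def gene_body_density(
    tracks: StrandedTrack, gene: GeneAnnotation, body_start_offset: int = 500
) -> float:
    """Sense-strand reads/bp over the gene body [tss+offset, tes)."""
    if gene.length <= body_start_offset:
        logger.warning("gene %s shorter than body offset; density = NA", gene.gene_id)
        return float("nan")
    if gene.strand == "+":
        lo, hi = gene.tss + body_start_offset, gene.tes
    else:
        lo, hi = gene.tes, gene.tss - body_start_offset
    iv = GenomicInterval(gene.chrom, lo, hi, strand=gene.strand)
    track = tracks.strand(gene.strand)
    return float(signal_at(track, [iv], stat="mean")[0])


def gene_body_density_table(
    tracks_by_condition: dict[str, StrandedTrack],
    genes: Sequence[GeneAnnotation],
    body_start_offset: int = 500,
) -> pd.DataFrame:
    """Per-gene reads/bp per condition (rows genes, columns conditions)."""
    data = {
        cond: [gene_body_density(tr, g, body_start_offset) for g in genes]
        for cond, tr in tracks_by_condition.items()
    }
    return pd.DataFrame(data, index=[g.gene_id for g in genes])


def fold_activation(
    densities: pd.DataFrame,
    treated: str,
    activated: set[str],
    basal: str = "NHS",
    pseudocount: float = 0.5,
) -> tuple[pd.Series, float]:
    """Per-gene fold over basal, and the activated-group mean fold expressed
    relative to the not-activated group's mean fold.

    fold_g = (d_treated + eps) / (d_basal + eps); the returned normalizer is
    mean fold over activated genes / mean fold over not-activated genes, so
    global drift shared by all genes cancels.
    """
    eps = pseudocount
    fold = (densities[treated] + eps) / (densities[basal] + eps)
    act_mask = densities.index.isin(activated)
    if not act_mask.any():
        raise ValueError("no activated genes in table")
    if act_mask.all():
        logger.warning("empty not-activated set; returning unnormalized mean fold")
        return fold, float(fold[act_mask].mean())
    rel = float(fold[act_mask].mean() / fold[~act_mask].mean())
    return fold, rel


def promoter_peak_fraction(
    promoters: IntervalSet,
    peaks: PeakTable,
    gene_subset: set[str] | None = None,
) -> tuple[float, int, int]:
    """Fraction of (a subset of) promoters overlapping >= 1 peak.

    Promoter intervals carry gene ids as names; the same code path serves
    dTREs or any other region universe. Returns (fraction, n_with, n_total).
    """
    universe = [
        iv for iv in promoters
        if gene_subset is None or iv.name in gene_subset
    ]
    if not universe:
        logger.warning("empty promoter subset; fraction = NA")
        return float("nan"), 0, 0
    peak_set = peaks.interval_set()
    n_with = int(peak_set.overlaps_any(universe).sum())
    return n_with / len(universe), n_with, len(universe)


def activation_binding_pivot(
    peak_class: pd.Series, activation_class: pd.Series
) -> dict[str, pd.DataFrame]:
    """Two-way pivots of per-gene peak class vs activation class.

    ``peak_class``: per gene, which treatments have a promoter peak
    (e.g. "HS,As", "HS", "As", "none"); ``activation_class``: analogous
    activation membership. Returns counts plus both row-normalized views
    (composition of activation within each peak class and vice versa), each
    with its denominator column.
    """
    df = pd.DataFrame({"peak": peak_class, "activation": activation_class}).dropna()
    counts = pd.crosstab(df["peak"], df["activation"])
    by_peak = counts.div(counts.sum(axis=1), axis=0)
    by_peak["denominator"] = counts.sum(axis=1)
    by_act = counts.T.div(counts.sum(axis=0), axis=0)
    by_act["denominator"] = counts.sum(axis=0)
    assert int(counts.to_numpy().sum()) == len(df), "pivot must cover the universe"
    return {"counts": counts, "by_peak_class": by_peak,
            "by_activation_class": by_act}


def basal_expression_comparison(
    nhs_density: pd.Series, has_peak: pd.Series
) -> tuple[pd.DataFrame, TestResult]:
    """Basal (untreated) gene-body density for promoters with vs without peaks."""
    idx = nhs_density.index.intersection(has_peak.index)
    d = nhs_density[idx]
    hp = has_peak[idx].astype(bool)
    with_peak = d[hp].to_numpy()
    without = d[~hp].to_numpy()
    if len(with_peak) == 0 or len(without) == 0:
        raise ValueError("both peak classes must be non-empty")
    res = mann_whitney(with_peak, without)
    summary = pd.DataFrame({
        "group": ["with_peak", "without_peak"],
        "n": [len(with_peak), len(without)],
        "median_density": [float(np.median(with_peak)), float(np.median(without))],
    })
    return summary, res


def atac_category_analysis(
    atac_peaks: PeakTable,
    hsf1_peaks: PeakTable,
    promoters: IntervalSet,
    nhs_tracks: dict[str, CoverageTrack],
    treated_tracks: dict[str, CoverageTrack],
) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Accessibility peaks by {promoter, intergenic} x {+TF, -TF}.

    Per category: peak count and the treated:NHS mean-signal ratio per
    replicate (reported as mean and range across replicates); plus, per
    replicate, a Mann-Whitney between per-peak treated/NHS ratios of the
    +TF and -TF intergenic categories.
    """
    ivs = atac_peaks.intervals
    at_promoter = promoters.overlaps_any(ivs)
    with_tf = hsf1_peaks.interval_set().overlaps_any(ivs)
    cat = np.where(at_promoter, "promoter", "intergenic")
    tf = np.where(with_tf, "+TF", "-TF")
    reps = sorted(set(nhs_tracks) & set(treated_tracks))

    per_rep_ratio = {}
    for rep in reps:
        nhs = signal_at(nhs_tracks[rep], ivs, stat="mean")
        tr = signal_at(treated_tracks[rep], ivs, stat="mean")
        per_rep_ratio[rep] = (tr + 1e-9) / (nhs + 1e-9)

    rows = []
    for c in ("promoter", "intergenic"):
        for t in ("+TF", "-TF"):
            mask = (cat == c) & (tf == t)
            n = int(mask.sum())
            if n == 0:
                rows.append({"category": c, "tf": t, "n_peaks": 0,
                             "ratio_mean": float("nan"), "ratio_min": float("nan"),
                             "ratio_max": float("nan")})
                continue
            rep_means = [float(np.mean(per_rep_ratio[rep][mask])) for rep in reps]
            rows.append({"category": c, "tf": t, "n_peaks": n,
                         "ratio_mean": float(np.mean(rep_means)),
                         "ratio_min": float(np.min(rep_means)),
                         "ratio_max": float(np.max(rep_means))})
    table = pd.DataFrame(rows)
    assert int(table["n_peaks"].sum()) == len(ivs), "categories must partition peaks"

    tests: dict[str, TestResult] = {}
    plus_mask = (cat == "intergenic") & (tf == "+TF")
    minus_mask = (cat == "intergenic") & (tf == "-TF")
    for rep in reps:
        if plus_mask.any() and minus_mask.any():
            tests[rep] = mann_whitney(per_rep_ratio[rep][plus_mask],
                                      per_rep_ratio[rep][minus_mask])
    return table, tests


def atac_class_tf_fractions(
    atac_nhs: PeakTable, atac_treated: PeakTable, tf_peaks: PeakTable
) -> pd.DataFrame:
    """Common/exclusive accessibility-peak classes and their TF-overlap fractions."""
    from .peaks import venn

    _, labels = venn(atac_nhs, atac_treated)
    tf_set = tf_peaks.interval_set()
    rows = []
    for label, pretty in (("common", "common"), ("a_only", "NHS_only"),
                          ("b_only", "treated_only")):
        sub = labels[labels["label"] == label]
        ivs = [GenomicInterval(r.chrom, int(r.start), int(r.end))
               for r in sub.itertuples()]
        n = len(ivs)
        n_tf = int(tf_set.overlaps_any(ivs).sum()) if n else 0
        rows.append({"class": pretty, "n": n, "n_with_tf": n_tf,
                     "fraction_with_tf": n_tf / n if n else float("nan")})
    return pd.DataFrame(rows)
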