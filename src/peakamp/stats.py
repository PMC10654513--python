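"""Statistical core: Mann-Whitney, Spearman, basal-amplification analysis,
affinity-matrix construction, correlation clustering, and PCA.

The Mann-Whitney U test returns two-tailed p-values. For small problems
(combined n <= 16) the permutation distribution of U is enumerated exactly
(midranks, so ties are handled); larger problems use the normal
approximation with tie correction and continuity correction. Figure-level
p-values are reported raw, without multiple-testing correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.stats as ss

from .genome import GenomicInterval, IntervalSet
from .peaks import PeakTable, _union_merge
from .tracks import CoverageTrack, signal_at

logger = logging.getLogger(__name__)

EXACT_N_THRESHOLD = 16  # combined sample size at or below which U is enumerated


@dataclass
class TestResult:
    statistic: float
    p: float
    n_x: int
    n_y: int
    method: str  # "exact" | "normal_approx" | "degenerate"


def _u_statistic(ranks: np.ndarray, n_x: int) -> float:
    r1 = float(ranks[:n_x].sum())
    return r1 - n_x * (n_x + 1) / 2.0


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-tailed Mann-Whitney U test (U of the first sample reported)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_x, n_y = len(x), len(y)
    if n_x < 1 or n_y < 1:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("degenerate data: all values identical; p = 1")
        return TestResult(n_x * n_y / 2.0, 1.0, n_x, n_y, "degenerate")
    ranks = ss.rankdata(pooled)
    u_obs = _u_statistic(ranks, n_x)
    mu = n_x * n_y / 2.0
    n = n_x + n_y

    if n <= EXACT_N_THRESHOLD:
        combos = np.array(list(itertools.combinations(range(n), n_x)))
        r1 = ranks[combos].sum(axis=1)
        u_all = r1 - n_x * (n_x + 1) / 2.0
        p = float(np.mean(np.abs(u_all - mu) >= np.abs(u_obs - mu) - 1e-9))
        return TestResult(u_obs, p, n_x, n_y, "exact")

    # normal approximation, tie-corrected variance, continuity correction
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (n * (n - 1))
    sigma2 = n_x * n_y / 12.0 * ((n + 1) - tie_term)
    if sigma2 <= 0:
        logger.warning("degenerate variance; p = 1")
        return TestResult(u_obs, 1.0, n_x, n_y, "degenerate")
    z = (abs(u_obs - mu) - 0.5) / np.sqrt(sigma2)
    p = float(min(1.0, 2.0 * ss.norm.sf(max(z, 0.0))))
    return TestResult(u_obs, max(p, 1e-300), n_x, n_y, "normal_approx")


SPEARMAN_EXACT_N = 8  # exact permutation p at or below this n


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Midrank Spearman rho with two-sided p.

    p is by exact permutation enumeration for n <= 8, else by the
    t approximation. Constant input yields (nan, nan) with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need n >= 3 paired values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        logger.warning("constant input: Spearman rho undefined (NA)")
        return float("nan"), float("nan")
    xr, yr = ss.rankdata(x), ss.rankdata(y)
    rho = float(np.corrcoef(xr, yr)[0, 1])
    if n <= SPEARMAN_EXACT_N:
        xc = xr - xr.mean()
        yc = yr - yr.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        perms = np.array(list(itertools.permutations(range(n))))
        rho_all = (yc[perms] @ xc) / denom
        p = float(np.mean(np.abs(rho_all) >= abs(rho) - 1e-12))
        return rho, p
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    p = float(min(1.0, 2.0 * ss.t.sf(abs(t), df=n - 2)))
    return rho, p


# ---- affinity matrix ---------------------------------------------------


class AffinityMatrix:
    """Consensus peaks x samples matrix of normalized signal.

    Rows are the union-merge of all samples' peaks; values are read counts
    extracted from (depth-scaled) tracks, log2(x+1)-transformed on request.
    Column order is fixed by sorted sample id.
    """

    def __init__(self, df: pd.DataFrame, transform: str = "linear"):
        if df.isna().any().any():
            raise ValueError("affinity matrix must have no missing values")
        self.df = df[sorted(df.columns)]
        self.transform = transform

    @classmethod
    def from_peaks_and_tracks(
        cls,
        peak_tables: dict[str, PeakTable],
        tracks: dict[str, CoverageTrack],
        log2: bool = True,
    ) -> "AffinityMatrix":
        consensus = _union_merge(list(peak_tables.values()))
        intervals = list(consensus)
        cols = {}
        for sid in sorted(tracks):
            cols[sid] = signal_at(tracks[sid], intervals, stat="sum")
        idx = [f"{iv.chrom}:{iv.start}-{iv.end}" for iv in intervals]
        df = pd.DataFrame(cols, index=idx)
        mat = cls(df, transform="linear")
        return mat.log2_transform() if log2 else mat

    @property
    def consensus_intervals(self) -> list[GenomicInterval]:
        out = []
        for key in self.df.index:
            chrom, rng = key.rsplit(":", 1)
            s, e = rng.split("-")
            out.append(GenomicInterval(chrom, int(s), int(e)))
        return out

    def log2_transform(self, pseudocount: float = 1.0) -> "AffinityMatrix":
        if self.transform != "linear":
            raise ValueError("already transformed")
        return AffinityMatrix(np.log2(self.df + pseudocount), transform="log2")


# ---- composite analyses ------------------------------------------------


def amplification_analysis(
    nhs_tracks: dict[str, CoverageTrack],
    stimulus_only_peaks: PeakTable,
    background: IntervalSet,
    treated_tracks: dict[str, CoverageTrack] | None = None,
) -> tuple[pd.DataFrame, dict[str, TestResult]]:
    """Basal signal at stimulus-acquired peak locations vs random background.

    For each basal-condition replicate track: mean per-base signal over the
    stimulus-only peak intervals and over matched background regions, with
    medians/quartiles/10-90 percentiles and a two-tailed Mann-Whitney test.
    If treated tracks are supplied, the treated/basal signal ratio at the
    background regions is reported as a negative control (it should sit
    near 1: background does not amplify).
    """
    if len(stimulus_only_peaks) == 0:
        raise ValueError("empty stimulus-only peak class")
    peak_ivs = stimulus_only_peaks.intervals
    bg_ivs = background.intervals
    rows = []
    tests: dict[str, TestResult] = {}
    for rep, track in sorted(nhs_tracks.items()):
        pv = signal_at(track, peak_ivs, stat="mean")
        bv = signal_at(track, bg_ivs, stat="mean")
        res = mann_whitney(pv, bv)
        tests[rep] = res
        row = {"replicate": rep, "n_peaks": len(pv), "n_background": len(bv),
               "p_two_tailed": res.p, "U": res.statistic}
        for label, vals in (("peak", pv), ("background", bv)):
            for q, tag in ((50, "median"), (25, "q25"), (75, "q75"),
                           (10, "p10"), (90, "p90")):
                row[f"{label}_{tag}"] = float(np.percentile(vals, q))
        if treated_tracks is not None and rep in treated_tracks:
            tb = signal_at(treated_tracks[rep], bg_ivs, stat="mean")
            denom = float(np.mean(bv))
            row["background_treated_over_nhs"] = (
                float(np.mean(tb)) / denom if denom > 0 else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows), tests


def exclusive_peak_correlations(
    affinity: AffinityMatrix,
    class_rows: dict[str, np.ndarray],
    column_pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Spearman rho between sample columns within peak classes.

    ``class_rows`` maps class name to a boolean row mask over the affinity
    matrix; ``column_pairs`` are (basal column, treated column) sample ids.
    Classes with fewer than 3 peaks yield NA with a warning.
    """
    if affinity.transform != "log2":
        raise ValueError("affinity matrix must be log2-transformed")
    rows = []
    for cls, mask in class_rows.items():
        sub = affinity.df.loc[np.asarray(mask, dtype=bool)]
        for a, b in column_pairs:
            if len(sub) < 3:
                logger.warning("class %s has < 3 peaks; rho = NA", cls)
                rho, p = float("nan"), float("nan")
            else:
                rho, p = spearman(sub[a].to_numpy(), sub[b].to_numpy())
            rows.append({"class": cls, "col_a": a, "col_b": b,
                         "rho": rho, "p": p, "n": len(sub)})
    return pd.DataFrame(rows)


def sample_correlation_clustering(
    affinity: AffinityMatrix,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Pairwise Spearman correlation of samples + average-linkage clustering.

    Distance is 1 - rho; leaf order is deterministic (columns pre-sorted by
    sample id, scipy's default ordering otherwise). Constant columns are
    excluded with a warning.
    """
    df = affinity.df
    keep = [c for c in df.columns if df[c].nunique() > 1]
    dropped = set(df.columns) - set(keep)
    if dropped:
        logger.warning("constant columns excluded from clustering: %s", sorted(dropped))
    df = df[keep]
    if df.shape[1] < 3:
        raise ValueError("need >= 3 non-constant samples")
    corr = df.corr(method="spearman")
    dist = 1.0 - corr.to_numpy()
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(len(keep), k=1)]
    linkage = sch.average(condensed)
    order = [keep[i] for i in sch.leaves_list(linkage)]
    return corr, linkage, order


def pca_affinity(
    affinity: AffinityMatrix,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of samples over consensus peaks.

    Samples are the observations and peaks the variables: each peak is
    centered across samples and the SVD of the samples-by-peaks matrix
    taken; returns per-sample scores on each PC and % variance explained.
    Two identical samples therefore land at the same point, and a matrix of
    identical columns collapses to the origin. Sign convention: the
    largest-magnitude sample score on each PC is positive.
    """
    if affinity.transform != "log2":
        raise ValueError("affinity matrix must be log2-transformed")
    X = affinity.df.to_numpy(dtype=float)
    n_peaks, n_samples = X.shape
    if n_samples < 2:
        raise ValueError("need >= 2 samples")
    if n_peaks < n_samples:
        logger.warning("fewer peaks (%d) than samples (%d)", n_peaks, n_samples)
    Y = (X - X.mean(axis=1, keepdims=True)).T  # samples x peaks, peak-centered
    U, S, Vt = np.linalg.svd(Y, full_matrices=False)
    scores = U * S[np.newaxis, :]  # samples x components
    for k in range(scores.shape[1]):
        j = int(np.argmax(np.abs(scores[:, k])))
        if scores[j, k] < 0:
            scores[:, k] = -scores[:, k]
    total = float(np.sum(S**2))
    var_explained = (S**2 / total * 100.0) if total > 0 else np.zeros_like(S)
    cols = [f"PC{k+1}" for k in range(scores.shape[1])]
    return pd.DataFrame(scores, index=affinity.df.columns, columns=cols), var_explained
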