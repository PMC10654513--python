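"""Synthetic multi-assay, multi-condition dataset generator with ground truth.

The generative model encodes the amplification hypothesis for a stress-
responsive transcription factor: a cell-line-specific catalog of binding
sites carries log-normal *basal* intensity; a stimulus multiplies every
active site's intensity by a global amplification factor A_t with
site-level log-normal noise, so sites occupy the same locations before and
after stimulation and only the signal scale changes. Peak "calling" is a
logistic detection gate on log intensity, which is what makes most basal
sites invisible in untreated samples and detected after amplification —
treatment-exclusive peak sets then arise mostly as detection-threshold
effects on shared basal sites, plus a small truly stimulus-exclusive set.

Coverage tracks are Poisson read pileups: per-base rate = background rate
plus each site's intensity spread by a discretized Gaussian kernel summing
to 1, scaled by a per-sample depth multiplier. ATAC tracks get region-class
baselines (promoters most open) and, under the first stimulus, a small
accessibility increase confined to +/-250 bp of remote site centers.
PRO-seq tracks are stranded gene-body pileups with an activated gene subset.

Every random draw flows from ``params.seed`` through named substreams, so a
fixed seed gives byte-identical outputs and inserting a stage does not
perturb the others.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import os
import zlib
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import (GeneAnnotation, Genome, GenomicInterval, IntervalSet,
                     promoter_regions)
from .peaks import PeakTable
from .tracks import CoverageTrack, SampleMeta, StrandedTrack

logger = logging.getLogger(__name__)

#: planted HSE: three alternating pentamer units (GAA-first phase), 15 nt
HSE_SEQUENCE = "AGAAATTTCTAGAAA"


def default_genome() -> Genome:
    """Toy genome: 4 chromosomes x 5 Mb."""
    return Genome({f"chr{i}": 5_000_000 for i in range(1, 5)})


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent RNG substream derived from (seed, stable hash of name)."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])


@dataclass
class GenerativeParams:
    """All knobs of the generator; defaults are the study conditions."""

    # site catalog
    n_sites: int = 3000                      # per cell line
    shared_site_fraction: float = 0.5        # fraction of each catalog shared A/B
    treatment_exclusive_fraction: float = 0.05  # per stimulus, truly exclusive
    min_site_separation: int = 1000          # bp between site centers
    # intensity model
    amplification: dict = field(default_factory=lambda: {"HS": 20.0, "As": 15.0})
    sigma_delta: float = 0.3                 # site-level log-noise on amplification
    mu_basal_log: float = math.log(12.0)     # log expected basal reads per site
    sigma_basal_log: float = 1.0
    background_rate: float = 0.02            # ChIP background, reads/bp
    kernel_sd: int = 75                      # read-pileup kernel, bp
    peak_halfwidth: int = 150                # called peak = center +/- 150
    plant_sites: bool = True                 # False = background-only null tracks
    # logistic peak detection on log intensity
    detect_theta: float = 4.0
    detect_scale: float = 0.5
    # experiment layout
    cell_lines: tuple = ("A", "B")
    treatments: tuple = ("NHS", "HS", "As")
    n_replicates: int = 2
    depth_multipliers: tuple = (1.0, 0.6)    # per replicate
    assays: tuple = ("chip", "atac", "pro")
    # genes / PRO-seq
    n_genes: int = 200
    gene_min_len: int = 10_000
    gene_max_len: int = 100_000
    gene_rate_log_mean: float = math.log(0.05)  # reads/bp gene body
    gene_rate_log_sd: float = 0.5
    activated_fraction: float = 0.15
    activated_common_fraction: float = 0.5   # of activated genes, shared HS/As
    activation_fold: dict = field(default_factory=lambda: {"HS": 8.0, "As": 5.0})
    activation_fold_log_sd: float = 0.2
    pro_background_rate: float = 0.001
    # ATAC
    atac_background: float = 0.005
    atac_baseline: dict = field(default_factory=lambda: {
        "promoter": 0.2, "dTRE": 0.1, "enhancer": 0.1, "remote": 0.02})
    atac_delta_remote: float = 0.1           # HS increase at remote sites, reads/bp
    atac_delta_halfwidth: int = 250
    # annotation elements
    promoter_flank: int = 1000
    n_dtres: int = 60
    dtre_size: int = 400
    n_enhancers: int = 60
    enhancer_size: int = 400
    n_blacklist: int = 10
    blacklist_size: int = 1000
    seed: int = 0

    def validate(self) -> None:
        positive = {
            "n_sites": self.n_sites, "sigma_delta": self.sigma_delta,
            "sigma_basal_log": self.sigma_basal_log,
            "background_rate": self.background_rate,
            "kernel_sd": self.kernel_sd, "peak_halfwidth": self.peak_halfwidth,
            "n_genes": self.n_genes, "pro_background_rate": self.pro_background_rate,
            "atac_background": self.atac_background,
        }
        for name, v in positive.items():
            if v <= 0:
                raise ValueError(f"parameter {name} must be > 0 (got {v})")
        for name, v in self.amplification.items():
            if v <= 0:
                raise ValueError(f"amplification[{name}] must be > 0")
        fractions = {
            "shared_site_fraction": self.shared_site_fraction,
            "treatment_exclusive_fraction": self.treatment_exclusive_fraction,
            "activated_fraction": self.activated_fraction,
            "activated_common_fraction": self.activated_common_fraction,
        }
        for name, v in fractions.items():
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"parameter {name} must be in [0,1] (got {v})")
        if any(d <= 0 for d in self.depth_multipliers):
            raise ValueError("depth multipliers must be > 0")
        if len(self.depth_multipliers) < self.n_replicates:
            raise ValueError("need one depth multiplier per replicate")


def gaussian_kernel(sd: int) -> np.ndarray:
    """Discretized Gaussian over +/-4 sd, normalized to sum 1."""
    r = 4 * sd
    x = np.arange(-r, r + 1)
    k = np.exp(-0.5 * (x / sd) ** 2)
    return k / k.sum()


@dataclass
class SyntheticTruth:
    """Generative record: parameters plus every realized quantity needed to
    recompute expected signals analytically."""

    params: GenerativeParams
    genome: Genome
    sites: pd.DataFrame  # site_id, chrom, center, in_<cell>, class, hre, region,
                         # basal_<cell>, intensity_<cell>_<treatment>
    depth: dict  # sample_id -> depth multiplier
    activated: dict  # treatment -> list of gene ids
    gene_rates: dict  # gene_id -> basal reads/bp
    gene_folds: dict  # (gene_id, treatment) realized fold, activated genes only

    def to_json(self) -> str:
        payload = {
            "params": asdict(self.params),
            "genome": dict(self.genome),
            "sites": self.sites.to_dict(orient="list"),
            "depth": self.depth,
            "activated": {t: sorted(v) for t, v in self.activated.items()},
            "gene_rates": self.gene_rates,
            "gene_folds": {f"{g}|{t}": v for (g, t), v in self.gene_folds.items()},
        }
        return json.dumps(payload, indent=1, sort_keys=True)


@dataclass
class SimulatedDataset:
    genome: Genome
    params: GenerativeParams
    truth: SyntheticTruth
    genes: list[GeneAnnotation]
    promoters: IntervalSet
    dtres: dict  # cell_line -> IntervalSet
    enhancers: IntervalSet
    blacklist: IntervalSet
    chip_tracks: dict  # sample_id -> CoverageTrack
    chip_peaks: dict  # sample_id -> PeakTable
    atac_tracks: dict  # sample_id -> CoverageTrack
    pro_tracks: dict  # sample_id -> StrandedTrack
    sample_meta: dict  # sample_id -> SampleMeta
    sequences: dict | None = None  # chrom -> str (only when requested)
    manifest: pd.DataFrame | None = None


def sample_id(cell: str, treatment: str, assay: str, rep: int) -> str:
    return f"{cell}_{treatment}_{assay}_r{rep}"


# ---- generation stages -------------------------------------------------


def _place_genes(params: GenerativeParams, genome: Genome,
                 rng: np.random.Generator) -> list[GeneAnnotation]:
    lengths = np.array([L for _, L in genome], dtype=float)
    alloc = rng.multinomial(params.n_genes, lengths / lengths.sum())
    genes: list[GeneAnnotation] = []
    gi = 0
    for (chrom, L), n_chrom in zip(genome, alloc):
        cursor = params.promoter_flank + 500
        for _ in range(n_chrom):
            glen = int(rng.integers(params.gene_min_len, params.gene_max_len + 1))
            gap = int(rng.integers(2_000, 20_000))
            if cursor + glen > L - params.promoter_flank - 500:
                raise ValueError(
                    f"gene placement infeasible on {chrom}: need {glen} bp at "
                    f"{cursor} but chromosome length is {L}; reduce n_genes or "
                    "gene lengths")
            strand = "+" if rng.random() < 0.5 else "-"
            tss, tes = (cursor, cursor + glen) if strand == "+" else (cursor + glen, cursor)
            genes.append(GeneAnnotation(f"gene_{gi:04d}", chrom, tss, tes, strand))
            gi += 1
            cursor += glen + gap
    return genes


def _place_elements(params: GenerativeParams, genome: Genome,
                    promoters: IntervalSet, rng: np.random.Generator,
                    n: int, size: int, name: str,
                    avoid: IntervalSet | None = None,
                    max_tries: int = 50) -> IntervalSet:
    chroms = list(genome)
    lengths = np.array([L for _, L in chroms], dtype=float)
    probs = lengths / lengths.sum()
    out: list[GenomicInterval] = []
    for _ in range(n):
        for _try in range(max_tries):
            ci = int(rng.choice(len(chroms), p=probs))
            chrom, L = chroms[ci]
            start = int(rng.integers(0, L - size + 1))
            iv = GenomicInterval(chrom, start, start + size)
            if promoters.overlaps(iv) or (avoid is not None and avoid.overlaps(iv)):
                continue
            out.append(iv)
            break
        else:
            raise ValueError(
                f"could not place {name} element after {max_tries} tries; "
                "genome too crowded")
    return IntervalSet(out, name=name)


def _place_site_centers(params: GenerativeParams, genome: Genome,
                        n_total: int, rng: np.random.Generator
                        ) -> list[tuple[str, int]]:
    """Uniform site centers with a minimum pairwise separation.

    Uses the order-statistics construction: draw sorted uniforms on a
    shortened axis, then re-inflate by the separation, which samples the
    uniform distribution conditional on the separation constraint exactly.
    """
    margin = 4 * params.kernel_sd + max(params.peak_halfwidth,
                                        params.atac_delta_halfwidth) + 10
    sep = params.min_site_separation
    lengths = np.array([L for _, L in genome], dtype=float)
    alloc = rng.multinomial(n_total, lengths / lengths.sum())
    centers: list[tuple[str, int]] = []
    for (chrom, L), k in zip(genome, alloc):
        usable = L - 2 * margin - (k - 1) * sep if k else 0
        if k and usable <= 0:
            raise ValueError(
                f"site placement infeasible on {chrom}: {k} sites with "
                f"separation {sep} exceed length {L}")
        if not k:
            continue
        u = np.sort(rng.random(k)) * usable
        pos = margin + u + np.arange(k) * sep
        centers.extend((chrom, int(p)) for p in pos)
    return centers


def _build_site_catalog(params: GenerativeParams, genome: Genome,
                        promoters: IntervalSet, dtres_all: IntervalSet,
                        enhancers: IntervalSet) -> pd.DataFrame:
    rng = substream(params.seed, "sites")
    cells = list(params.cell_lines)
    n_shared = int(round(params.shared_site_fraction * params.n_sites))
    n_excl = params.n_sites - n_shared
    n_total = n_shared + n_excl * len(cells)
    centers = _place_site_centers(params, genome, n_total, rng)
    order = rng.permutation(n_total)
    rows = []
    idx = 0
    membership: list[tuple[bool, ...]] = []
    membership += [tuple(True for _ in cells)] * n_shared
    for ci in range(len(cells)):
        membership += [tuple(i == ci for i in range(len(cells)))] * n_excl
    stimuli = [t for t in params.treatments if t != "NHS"]
    for i in range(n_total):
        chrom, center = centers[order[i]]
        member = membership[i]
        u = rng.random()
        f = params.treatment_exclusive_fraction
        if u < f and stimuli:
            tclass = f"{stimuli[0]}_only"
        elif u < 2 * f and len(stimuli) > 1:
            tclass = f"{stimuli[1]}_only"
        else:
            tclass = "constitutive"
        rows.append({"site_id": f"site_{idx:05d}", "chrom": chrom, "center": center,
                     **{f"in_{c}": m for c, m in zip(cells, member)},
                     "treatment_class": tclass})
        idx += 1
    df = pd.DataFrame(rows).sort_values(["chrom", "center"]).reset_index(drop=True)

    # region class of each site (for ATAC baselines and HSE planting)
    site_ivs = [GenomicInterval(r.chrom, r.center, r.center + 1) for r in df.itertuples()]
    from .genome import classify_intervals
    df["region"] = classify_intervals(IntervalSet(site_ivs), promoters, dtres_all,
                                      enhancers)

    # basal intensity per cell line (independent draws: basal binding patterns
    # are cell-line specific even at shared sites)
    for c in cells:
        b = rng.lognormal(params.mu_basal_log, params.sigma_basal_log, len(df))
        df[f"basal_{c}"] = np.where(df[f"in_{c}"], b, 0.0)
        if params.plant_sites and np.any(df.loc[df[f"in_{c}"], f"basal_{c}"] <= 0):
            raise ValueError("basal intensity must be positive at member sites")

    # realized per-site intensity per (cell, treatment)
    for c in cells:
        df[f"intensity_{c}_NHS"] = df[f"basal_{c}"]
        for t in stimuli:
            delta = rng.normal(0.0, params.sigma_delta, len(df))
            amplified = (df["treatment_class"] == "constitutive") | (
                df["treatment_class"] == f"{t}_only")
            a = np.where(amplified, params.amplification[t] * np.exp(delta), 1.0)
            df[f"intensity_{c}_{t}"] = df[f"basal_{c}"] * a

    # HSE planting: preferentially at remote (closed-chromatin) sites
    p_hre = np.where(df["region"] == "remote", 0.8, 0.4)
    df["hre"] = rng.random(len(df)) < p_hre
    return df


def _chip_lambda(params: GenerativeParams, genome: Genome, sites: pd.DataFrame,
                 cell: str, treatment: str, depth: float,
                 kernel: np.ndarray) -> dict[str, np.ndarray]:
    r = (len(kernel) - 1) // 2
    lam = {c: np.full(L, params.background_rate * depth) for c, L in genome}
    if params.plant_sites:
        col = f"intensity_{cell}_{treatment}"
        for row in sites.itertuples():
            inten = getattr(row, col.replace("-", "_"))
            if inten <= 0:
                continue
            a = lam[row.chrom]
            lo, hi = row.center - r, row.center + r + 1
            a[lo:hi] += inten * depth * kernel
    return lam


def simulate_dataset(params: GenerativeParams, genome: Genome | None = None,
                     outdir: str | None = None,
                     make_sequences: bool = True) -> SimulatedDataset:
    """Run the full generator; optionally write the file manifest to outdir."""
    params.validate()
    genome = genome or default_genome()
    kernel = gaussian_kernel(params.kernel_sd)

    genes = _place_genes(params, genome, substream(params.seed, "genes"))
    promoters = promoter_regions(genes, genome, flank=params.promoter_flank)
    rng_el = substream(params.seed, "elements")
    dtres = {c: _place_elements(params, genome, promoters, rng_el,
                                params.n_dtres, params.dtre_size, f"dtre_{c}")
             for c in params.cell_lines}
    enhancers = _place_elements(params, genome, promoters, rng_el,
                                params.n_enhancers, params.enhancer_size,
                                "enhancers")
    blacklist = _place_elements(params, genome, promoters, rng_el,
                                params.n_blacklist, params.blacklist_size,
                                "blacklist")
    dtres_all = IntervalSet([iv for s in dtres.values() for iv in s], name="dtres")
    sites = _build_site_catalog(params, genome, promoters, dtres_all, enhancers)

    # activated gene sets (shared across cell lines; common core + specific)
    rng_act = substream(params.seed, "activation")
    stimuli = [t for t in params.treatments if t != "NHS"]
    gene_ids = [g.gene_id for g in genes]
    n_act = int(round(params.activated_fraction * len(gene_ids)))
    n_common = int(round(params.activated_common_fraction * n_act))
    shuffled = list(rng_act.permutation(gene_ids))
    common = shuffled[:n_common]
    activated: dict[str, set] = {}
    cursor = n_common
    for t in stimuli:
        spec = shuffled[cursor:cursor + (n_act - n_common)]
        cursor += n_act - n_common
        activated[t] = set(common) | set(spec)
    gene_rates = {g: float(r) for g, r in zip(
        gene_ids, rng_act.lognormal(params.gene_rate_log_mean,
                                    params.gene_rate_log_sd, len(gene_ids)))}
    gene_folds: dict[tuple, float] = {}
    for t in stimuli:
        for g in sorted(activated[t]):
            gene_folds[(g, t)] = float(
                params.activation_fold[t]
                * rng_act.lognormal(0.0, params.activation_fold_log_sd))

    depth: dict[str, float] = {}
    sample_meta: dict[str, SampleMeta] = {}
    chip_tracks: dict[str, CoverageTrack] = {}
    chip_peaks: dict[str, PeakTable] = {}
    atac_tracks: dict[str, CoverageTrack] = {}
    pro_tracks: dict[str, StrandedTrack] = {}

    # which sites of each cell line are remote (used for the ATAC delta)
    remote = {c: sites[(sites["region"] == "remote") & sites[f"in_{c}"]]
              for c in params.cell_lines}

    for cell in params.cell_lines:
        for treat in params.treatments:
            for rep in range(1, params.n_replicates + 1):
                d = float(params.depth_multipliers[rep - 1])
                if "chip" in params.assays:
                    sid = sample_id(cell, treat, "chip", rep)
                    meta = SampleMeta(sid, cell, treat, "chip", rep)
                    rng = substream(params.seed, f"chip/{sid}")
                    lam = _chip_lambda(params, genome, sites, cell, treat, d, kernel)
                    data = {c: rng.poisson(a).astype(np.float32) for c, a in lam.items()}
                    chip_tracks[sid] = CoverageTrack(genome, data, meta=meta)
                    depth[sid] = d
                    sample_meta[sid] = meta
                    # logistic detection on log effective intensity
                    if params.plant_sites:
                        inten = sites[f"intensity_{cell}_{treat}"].to_numpy() * d
                        with np.errstate(divide="ignore"):
                            logi = np.where(inten > 0, np.log(np.maximum(inten, 1e-300)),
                                            -np.inf)
                        p_det = 1.0 / (1.0 + np.exp(
                            -(logi - params.detect_theta) / params.detect_scale))
                        p_det = np.where(inten > 0, p_det, 0.0)
                        called = rng.random(len(sites)) < p_det
                        hw = params.peak_halfwidth
                        ivs = [GenomicInterval(r.chrom, r.center - hw, r.center + hw)
                               for r in sites[called].itertuples()]
                    else:
                        ivs = []
                    chip_peaks[sid] = PeakTable.from_intervals(ivs, name=sid)

                if "atac" in params.assays:
                    sid = sample_id(cell, treat, "atac", rep)
                    meta = SampleMeta(sid, cell, treat, "atac", rep)
                    rng = substream(params.seed, f"atac/{sid}")
                    lam = {c: np.full(L, params.atac_background * d) for c, L in genome}
                    for iv in promoters:
                        lam[iv.chrom][iv.start:iv.end] += params.atac_baseline["promoter"] * d
                    for iv in dtres[cell]:
                        lam[iv.chrom][iv.start:iv.end] += params.atac_baseline["dTRE"] * d
                    for iv in enhancers:
                        lam[iv.chrom][iv.start:iv.end] += params.atac_baseline["enhancer"] * d
                    hw = params.atac_delta_halfwidth
                    for row in remote[cell].itertuples():
                        lam[row.chrom][row.center - hw:row.center + hw] += (
                            params.atac_baseline["remote"] * d)
                        if treat == "HS":
                            lam[row.chrom][row.center - hw:row.center + hw] += (
                                params.atac_delta_remote * d)
                    data = {c: rng.poisson(a).astype(np.float32) for c, a in lam.items()}
                    atac_tracks[sid] = CoverageTrack(genome, data, meta=meta)
                    depth[sid] = d
                    sample_meta[sid] = meta

                if "pro" in params.assays:
                    sid = sample_id(cell, treat, "pro", rep)
                    meta = SampleMeta(sid, cell, treat, "pro", rep)
                    rng = substream(params.seed, f"pro/{sid}")
                    lam = {s: {c: np.full(L, params.pro_background_rate * d)
                               for c, L in genome} for s in "+-"}
                    for g in genes:
                        rate = gene_rates[g.gene_id] * d
                        if treat != "NHS" and g.gene_id in activated.get(treat, ()):
                            rate *= gene_folds[(g.gene_id, treat)]
                        lam[g.strand][g.chrom][g.start:g.end] += rate
                    plus = CoverageTrack(genome, {c: rng.poisson(a).astype(np.float32)
                                                  for c, a in lam["+"].items()},
                                         meta=meta)
                    minus = CoverageTrack(genome, {c: rng.poisson(a).astype(np.float32)
                                                   for c, a in lam["-"].items()},
                                          meta=meta)
                    pro_tracks[sid] = StrandedTrack(plus, minus)
                    depth[sid] = d
                    sample_meta[sid] = meta

    sequences = None
    if make_sequences:
        rng_seq = substream(params.seed, "sequence")
        sequences = {}
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        for chrom, L in genome:
            arr = bases[rng_seq.integers(0, 4, L)]
            sequences[chrom] = arr.tobytes().decode("ascii")
        if params.plant_sites:
            planted = sites[sites["hre"]]
            for row in planted.itertuples():
                seq = sequences[row.chrom]
                p = row.center - len(HSE_SEQUENCE) // 2
                sequences[row.chrom] = seq[:p] + HSE_SEQUENCE + seq[p + len(HSE_SEQUENCE):]

    truth = SyntheticTruth(params=params, genome=genome, sites=sites,
                           depth=depth, activated={t: sorted(v) for t, v in activated.items()},
                           gene_rates=gene_rates, gene_folds=gene_folds)
    sim = SimulatedDataset(genome=genome, params=params, truth=truth, genes=genes,
                           promoters=promoters, dtres=dtres, enhancers=enhancers,
                           blacklist=blacklist, chip_tracks=chip_tracks,
                           chip_peaks=chip_peaks, atac_tracks=atac_tracks,
                           pro_tracks=pro_tracks, sample_meta=sample_meta,
                           sequences=sequences)
    if outdir is not None:
        sim.manifest = write_dataset(sim, outdir)
    return sim


def expected_signal(truth: SyntheticTruth, interval: GenomicInterval,
                    sample: str) -> float:
    """Analytic expected read count of the generator over an interval.

    Equals background_rate*len plus each contributing site's intensity times
    the kernel mass falling inside the interval, scaled by the sample's
    depth multiplier — exactly the mean of the Poisson draw.
    """
    if sample not in truth.depth:
        raise KeyError(f"unknown sample {sample!r}")
    params = truth.params
    cell, treat, assay, _rep = sample.split("_")
    if assay != "chip":
        raise ValueError("expected_signal is defined for ChIP tracks")
    if interval.chrom not in truth.genome or interval.end > truth.genome.length(interval.chrom):
        raise ValueError("interval outside genome")
    d = truth.depth[sample]
    total = params.background_rate * d * len(interval)
    if not params.plant_sites:
        return total
    kernel = gaussian_kernel(params.kernel_sd)
    r = (len(kernel) - 1) // 2
    ksum = np.concatenate(([0.0], np.cumsum(kernel)))
    col = f"intensity_{cell}_{treat}"
    sub = truth.sites[(truth.sites["chrom"] == interval.chrom)
                      & (truth.sites["center"] >= interval.start - r)
                      & (truth.sites["center"] <= interval.end + r)]
    for row in sub.itertuples():
        inten = getattr(row, col)
        if inten <= 0:
            continue
        lo = max(interval.start - row.center + r, 0)
        hi = min(interval.end - row.center + r, len(kernel))
        if hi > lo:
            total += inten * d * (ksum[hi] - ksum[lo])
    return float(total)


# ---- file emission -----------------------------------------------------


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_dataset(sim: SimulatedDataset, outdir: str) -> pd.DataFrame:
    """Emit the dataset as plain-text files; returns the manifest with hashes."""
    from . import io as pio

    os.makedirs(outdir, exist_ok=True)
    paths: list[str] = []

    def emit(relpath: str, writer) -> None:
        path = os.path.join(outdir, relpath)
        writer(path)
        paths.append(relpath)

    emit("genome.chrom.sizes", lambda p: pio.write_chrom_sizes(sim.genome, p))
    emit("genes.tsv", lambda p: pio.write_gene_tsv(sim.genes, p))
    emit("promoters.bed", lambda p: pio.write_bed(sim.promoters, p))
    for cell, s in sim.dtres.items():
        emit(f"dtres_{cell}.bed", lambda p, s=s: pio.write_bed(s, p))
    emit("enhancers.bed", lambda p: pio.write_bed(sim.enhancers, p))
    emit("blacklist.bed", lambda p: pio.write_bed(sim.blacklist, p))
    for sid, track in sim.chip_tracks.items():
        emit(f"{sid}.bedGraph", lambda p, t=track: t.to_bedgraph(p))
    for sid, table in sim.chip_peaks.items():
        emit(f"{sid}.peaks.bed", lambda p, t=table: pio.write_bed(t.intervals, p))
    for sid, track in sim.atac_tracks.items():
        emit(f"{sid}.bedGraph", lambda p, t=track: t.to_bedgraph(p))
    for sid, st in sim.pro_tracks.items():
        emit(f"{sid}.plus.bedGraph", lambda p, t=st.plus: t.to_bedgraph(p))
        emit(f"{sid}.minus.bedGraph", lambda p, t=st.minus: t.to_bedgraph(p))
    if sim.sequences is not None:
        emit("genome.fa", lambda p: pio.write_fasta(sim.sequences, p))
    for treat, gene_list in sim.truth.activated.items():
        emit(f"activated_{treat}.tsv", lambda p, gl=gene_list: open(p, "w").write(
            "gene_id\n" + "".join(g + "\n" for g in gl)))
    emit("truth.json", lambda p: open(p, "w").write(sim.truth.to_json()))

    manifest = pd.DataFrame({
        "path": paths,
        "sha256": [_sha256(os.path.join(outdir, p)) for p in paths],
    })
    manifest.to_csv(os.path.join(outdir, "manifest.tsv"), sep="\t", index=False)
    return manifest
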