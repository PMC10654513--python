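"""End-to-end orchestration: simulate -> peaks -> signal -> motif -> compare
-> associate, bundled into a machine-readable report.

A single seed drives every stage through named substreams, so rerunning
with the same config reproduces byte-identical tables, and inserting a
stage does not perturb the draws of the others. Every denominator and
filter count is logged at INFO.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .associate import (activation_binding_pivot, atac_category_analysis,
                        atac_class_tf_fractions, fold_activation,
                        gene_body_density_table, promoter_peak_fraction)
from .genome import IntervalSet
from .motif import HreModel, hits_to_interval_set, observed_vs_expected, scan_genome
from .peaks import (BackgroundSpec, PeakTable, average_peak_size, class_intervals,
                    exclusive_and_common_classes, merge_replicates,
                    sample_background, venn)
from .stats import (AffinityMatrix, amplification_analysis,
                    exclusive_peak_correlations, pca_affinity,
                    sample_correlation_clustering)
from .synth import (GenerativeParams, Genome, SimulatedDataset, sample_id,
                    simulate_dataset, substream)
from .tracks import scale_to_lowest_depth

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {"seed", "outdir", "simulate", "genome", "analyses", "merge_mode",
               "flank", "n_background", "min_units"}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str | None = None
    simulate: dict = field(default_factory=dict)
    genome: dict | None = None  # {"chr1": 5000000, ...}; None = generator default
    analyses: tuple = ("peaks", "signal", "motif", "compare", "associate")
    merge_mode: dict = field(default_factory=lambda: {"A": "union", "B": "intersection"})
    flank: int = 1000
    n_background: int = 2000
    min_units: int = 3

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**{k: v for k, v in d.items() if k in _KNOWN_KEYS})
        cfg.analyses = tuple(cfg.analyses)
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class Report:
    config: dict
    seed: int
    version: str
    tables: dict  # name -> DataFrame

    def table_tsv(self, name: str) -> str:
        return self.tables[name].to_csv(sep="\t", index=True)

    def hashes(self) -> dict:
        return {
            name: hashlib.sha256(self.table_tsv(name).encode()).hexdigest()
            for name in sorted(self.tables)
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "config": self.config,
                "tables": {n: self.table_tsv(n) for n in sorted(self.tables)},
                "hashes": self.hashes(),
            },
            indent=1, sort_keys=True,
        )


def _merged_condition_peaks(sim: SimulatedDataset, merge_mode: dict) -> dict:
    """Replicate-merged peak tables keyed by (cell, treatment)."""
    out = {}
    for cell in sim.params.cell_lines:
        mode = merge_mode.get(cell, "union")
        for treat in sim.params.treatments:
            reps = [sim.chip_peaks[sample_id(cell, treat, "chip", r)]
                    for r in range(1, sim.params.n_replicates + 1)]
            merged = reps[0]
            for other in reps[1:]:
                merged = merge_replicates(merged, other, mode=mode)
            out[(cell, treat)] = merged
            logger.info("merged peaks %s %s (%s): %d", cell, treat, mode, len(merged))
    return out


def run_pipeline(config: RunConfig) -> Report:
    genome = Genome(config.genome) if config.genome else None
    sim_overrides = dict(config.simulate)
    params = GenerativeParams(**sim_overrides, seed=config.seed)
    need_seq = "motif" in config.analyses
    sim = simulate_dataset(params, genome=genome, outdir=config.outdir,
                           make_sequences=need_seq)
    genome = sim.genome
    tables: dict[str, pd.DataFrame] = {}
    tables["sample_manifest"] = pd.DataFrame(
        [{"sample_id": sid, "cell_line": m.cell_line, "treatment": m.treatment,
          "assay": m.assay, "replicate": m.replicate,
          "depth_multiplier": sim.truth.depth[sid]}
         for sid, m in sorted(sim.sample_meta.items())]
    ).set_index("sample_id")

    cond_peaks = _merged_condition_peaks(sim, config.merge_mode)
    classes_by_cell = {
        cell: exclusive_and_common_classes(
            {t: cond_peaks[(cell, t)] for t in sim.params.treatments})
        for cell in sim.params.cell_lines
    }

    if "peaks" in config.analyses:
        rows = []
        for cell in sim.params.cell_lines:
            res, _ = venn(cond_peaks[(cell, "HS")], cond_peaks[(cell, "As")])
            rows.append({"cell_line": cell, "a": "HS", "b": "As",
                         "only_a": res.only_a, "only_b": res.only_b,
                         "common": res.common, "pct_common": res.pct_common})
        tables["fig2_venn"] = pd.DataFrame(rows).set_index("cell_line")
        cls_counts = []
        for cell, cls in classes_by_cell.items():
            vc = cls["members"].value_counts()
            for members, n in vc.items():
                cls_counts.append({"cell_line": cell, "members": members, "n": int(n)})
        tables["fig6_peak_classes"] = pd.DataFrame(cls_counts).set_index("cell_line")

    chip_scaled = dict(zip(
        sorted(sim.chip_tracks),
        scale_to_lowest_depth([sim.chip_tracks[s] for s in sorted(sim.chip_tracks)]),
    ))
    affinity = AffinityMatrix.from_peaks_and_tracks(sim.chip_peaks, chip_scaled)

    if "signal" in config.analyses:
        tables["affinity_matrix"] = affinity.df

    if "motif" in config.analyses:
        hits = scan_genome(sim.sequences, HreModel(min_units=config.min_units))
        hit_set = hits_to_interval_set(hits)
        logger.info("motif scan: %d hits over %d bp genome",
                    len(hits), genome.total_length)
        rows = []
        obs, exp, ratio = observed_vs_expected(hit_set, sim.promoters, genome)
        rows.append({"features": "hse_motifs", "regions": "promoters",
                     "observed": obs, "expected": exp, "ratio": ratio})
        for cell in sim.params.cell_lines:
            obs, exp, ratio = observed_vs_expected(hit_set, sim.dtres[cell], genome)
            rows.append({"features": "hse_motifs", "regions": f"dtres_{cell}",
                         "observed": obs, "expected": exp, "ratio": ratio})
            peaks_set = cond_peaks[(cell, "HS")].interval_set()
            obs, exp, ratio = observed_vs_expected(peaks_set, sim.promoters, genome)
            rows.append({"features": f"peaks_{cell}_HS", "regions": "promoters",
                         "observed": obs, "expected": exp, "ratio": ratio})
        tables["fig5_observed_expected"] = pd.DataFrame(rows).set_index("features")

    if "compare" in config.analyses:
        amp_rows = []
        for cell in sim.params.cell_lines:
            hs_only = class_intervals(classes_by_cell[cell], "HS")
            if not hs_only:
                logger.warning("no HS-only peaks for %s; amplification skipped", cell)
                continue
            hs_only_table = PeakTable.from_intervals(hs_only, name=f"{cell}_HS_only")
            exclusions = IntervalSet(
                list(sim.promoters)
                + [iv for s in sim.dtres.values() for iv in s]
                + [iv for t in sim.params.treatments
                   for iv in cond_peaks[(cell, t)].intervals],
                name="exclusions")
            bg_seed = int(substream(config.seed, f"background/{cell}").integers(2**31))
            spec = BackgroundSpec(n_requested=config.n_background,
                                  region_size=average_peak_size(hs_only_table),
                                  exclusions=exclusions, seed=bg_seed)
            background = sample_background(spec, genome)
            nhs = {f"r{r}": chip_scaled[sample_id(cell, "NHS", "chip", r)]
                   for r in range(1, sim.params.n_replicates + 1)}
            treated = {f"r{r}": chip_scaled[sample_id(cell, "HS", "chip", r)]
                       for r in range(1, sim.params.n_replicates + 1)}
            summary, _tests = amplification_analysis(nhs, hs_only_table, background,
                                                     treated_tracks=treated)
            summary.insert(0, "cell_line", cell)
            amp_rows.append(summary)
        if amp_rows:
            tables["fig6b_amplification"] = pd.concat(amp_rows).set_index("cell_line")

        # cell-line- and treatment-exclusive correlation structure
        consensus = affinity.consensus_intervals
        class_rows = {}
        for cell in sim.params.cell_lines:
            other = [c for c in sim.params.cell_lines if c != cell]
            own = IntervalSet([iv for t in sim.params.treatments
                               for iv in cond_peaks[(cell, t)].intervals])
            other_set = IntervalSet([iv for c in other for t in sim.params.treatments
                                     for iv in cond_peaks[(c, t)].intervals])
            mask = own.overlaps_any(consensus) & ~other_set.overlaps_any(consensus)
            class_rows[f"{cell}_exclusive"] = mask
        for cell in sim.params.cell_lines:
            for t in ("HS", "As"):
                ivs = class_intervals(classes_by_cell[cell], t)
                s = IntervalSet(ivs)
                class_rows[f"{cell}_{t}_only"] = s.overlaps_any(consensus)
        pairs = []
        for cell in sim.params.cell_lines:
            for t in ("HS", "As"):
                for c2 in sim.params.cell_lines:
                    pairs.append((sample_id(cell, "NHS", "chip", 1),
                                  sample_id(c2, t, "chip", 1)))
        tables["fig6_correlations"] = exclusive_peak_correlations(
            affinity, class_rows, sorted(set(pairs))).set_index("class")

        corr, _link, order = sample_correlation_clustering(affinity)
        tables["fig6f_sample_correlation"] = corr
        tables["fig6f_leaf_order"] = pd.DataFrame({"order": range(len(order)),
                                                   "sample_id": order}).set_index("order")
        scores, var = pca_affinity(affinity)
        tables["fig4g_pca_scores"] = scores
        tables["fig4g_pca_variance"] = pd.DataFrame(
            {"PC": [f"PC{i+1}" for i in range(len(var))], "pct_variance": var}
        ).set_index("PC")

    if "associate" in config.analyses:
        rows = []
        for cell in sim.params.cell_lines:
            for t in ("HS", "As"):
                frac, n_with, n_tot = promoter_peak_fraction(
                    sim.promoters, cond_peaks[(cell, t)])
                rows.append({"cell_line": cell, "treatment": t, "universe": "all",
                             "fraction": frac, "n_with": n_with, "n_total": n_tot})
                act = set(sim.truth.activated.get(t, []))
                frac, n_with, n_tot = promoter_peak_fraction(
                    sim.promoters, cond_peaks[(cell, t)], gene_subset=act)
                rows.append({"cell_line": cell, "treatment": t,
                             "universe": "activated", "fraction": frac,
                             "n_with": n_with, "n_total": n_tot})
        tables["fig3a_promoter_fractions"] = pd.DataFrame(rows).set_index("cell_line")

        if "pro" in sim.params.assays:
            cell = sim.params.cell_lines[0]
            dens = gene_body_density_table(
                {t: sim.pro_tracks[sample_id(cell, t, "pro", 1)]
                 for t in sim.params.treatments}, sim.genes)
            fa_rows = []
            for t in ("HS", "As"):
                act = set(sim.truth.activated.get(t, []))
                _fold, rel = fold_activation(dens, t, act)
                fa_rows.append({"treatment": t, "relative_mean_fold": rel,
                                "n_activated": len(act)})
            tables["fig2g_fold_activation"] = pd.DataFrame(fa_rows).set_index("treatment")

            # per-gene peak class vs activation class pivot (first cell line)
            peak_class = {}
            promoter_map = {iv.name: iv for iv in sim.promoters}
            hs_set = cond_peaks[(cell, "HS")].interval_set()
            as_set = cond_peaks[(cell, "As")].interval_set()
            for gid, iv in promoter_map.items():
                hs, as_ = hs_set.overlaps(iv), as_set.overlaps(iv)
                peak_class[gid] = ("HS,As" if hs and as_ else
                                   "HS" if hs else "As" if as_ else "none")
            act_class = {}
            hs_act = set(sim.truth.activated.get("HS", []))
            as_act = set(sim.truth.activated.get("As", []))
            for gid in promoter_map:
                h, a = gid in hs_act, gid in as_act
                act_class[gid] = ("HS,As" if h and a else
                                  "HS" if h else "As" if a else "none")
            pivots = activation_binding_pivot(pd.Series(peak_class),
                                              pd.Series(act_class))
            tables["fig3g_pivot_counts"] = pivots["counts"]

        if "atac" in sim.params.assays:
            cell = sim.params.cell_lines[0]
            # accessibility "peaks" at desk scale = annotated open elements
            atac_open = PeakTable.from_intervals(
                list(sim.promoters.merge())
                + list(sim.dtres[cell]) + list(sim.enhancers),
                name="atac_open")
            table, _tests = atac_category_analysis(
                atac_peaks=atac_open,
                hsf1_peaks=cond_peaks[(cell, "HS")],
                promoters=sim.promoters,
                nhs_tracks={f"r{r}": sim.atac_tracks[sample_id(cell, "NHS", "atac", r)]
                            for r in range(1, sim.params.n_replicates + 1)},
                treated_tracks={f"r{r}": sim.atac_tracks[sample_id(cell, "HS", "atac", r)]
                                for r in range(1, sim.params.n_replicates + 1)},
            )
            tables["fig7d_atac_categories"] = table.set_index("category")

    cfg_dict = dataclasses.asdict(config)
    cfg_dict["analyses"] = list(config.analyses)
    return Report(config=cfg_dict, seed=config.seed, version=__version__,
                  tables=tables)


def write_report(report: Report, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(report.to_json())
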