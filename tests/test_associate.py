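import numpy as np
import pandas as pd
import pytest

from peakamp.associate import (activation_binding_pivot, atac_category_analysis,
                               atac_class_tf_fractions,
                               basal_expression_comparison, fold_activation,
                               gene_body_density, gene_body_density_table,
                               promoter_peak_fraction)
from peakamp.genome import (GeneAnnotation, Genome, GenomicInterval, IntervalSet,
                            promoter_regions)
from peakamp.peaks import PeakTable
from peakamp.tracks import CoverageTrack, StrandedTrack


@pytest.fixture
def genome():
    return Genome({"chr1": 100_000})


def stranded(genome, plus=0.0, minus=0.0):
    p, m = CoverageTrack(genome), CoverageTrack(genome)
    for c in p.data:
        p.data[c][:] = plus
        m.data[c][:] = minus
    return StrandedTrack(p, m)


class TestGeneBodyDensity:
    def test_uniform_sense_coverage_gives_rate(self, genome):
        gene = GeneAnnotation("g", "chr1", 10_000, 30_000, "+")
        assert gene_body_density(stranded(genome, plus=3.0), gene) == pytest.approx(3.0)

    def test_antisense_signal_ignored(self, genome):
        gene = GeneAnnotation("g", "chr1", 10_000, 30_000, "+")
        assert gene_body_density(stranded(genome, minus=5.0), gene) == 0.0

    def test_minus_strand_gene_uses_minus_track(self, genome):
        gene = GeneAnnotation("g", "chr1", 30_000, 10_000, "-")
        assert gene_body_density(stranded(genome, minus=2.0), gene) == pytest.approx(2.0)

    def test_short_gene_is_na(self, genome):
        gene = GeneAnnotation("g", "chr1", 10_000, 10_300, "+")
        assert np.isnan(gene_body_density(stranded(genome, plus=1.0), gene))

    def test_recovers_planted_rate_within_poisson_error(self, small_sim):
        from peakamp.synth import sample_id

        tr = small_sim.pro_tracks[sample_id("A", "NHS", "pro", 1)]
        for gene in small_sim.genes[:5]:
            rate = small_sim.truth.gene_rates[gene.gene_id]
            d = small_sim.truth.depth[sample_id("A", "NHS", "pro", 1)]
            got = gene_body_density(tr, gene)
            n_bases = gene.length - 500
            se = np.sqrt(rate * d / n_bases)
            assert abs(got - rate * d) < 5 * se + 0.01


class TestFoldActivation:
    def _dens(self, folds):
        nhs = np.full(len(folds), 4.0)
        return pd.DataFrame({"NHS": nhs, "HS": nhs * np.array(folds)},
                            index=[f"g{i}" for i in range(len(folds))])

    def test_no_change_gives_unit_folds_and_ratio(self):
        dens = self._dens([1.0] * 10)
        fold, rel = fold_activation(dens, "HS", activated={"g0", "g1"})
        assert np.allclose(fold, 1.0)
        assert rel == pytest.approx(1.0)

    def test_planted_eightfold_recovered(self):
        folds = [8.0] * 5 + [1.0] * 15
        dens = self._dens(folds)
        _, rel = fold_activation(dens, "HS", activated={f"g{i}" for i in range(5)},
                                 pseudocount=0.0)
        assert rel == pytest.approx(8.0, rel=0.05)

    def test_invariant_under_global_track_rescaling(self):
        dens = self._dens([4.0] * 5 + [1.0] * 10)
        act = {f"g{i}" for i in range(5)}
        _, rel1 = fold_activation(dens, "HS", act, pseudocount=0.0)
        _, rel2 = fold_activation(dens * 10.0, "HS", act, pseudocount=0.0)
        assert rel1 == pytest.approx(rel2)

    def test_generator_hs_fold_exceeds_as_fold(self, small_sim):
        """The generator's stronger heat-shock activation shows up as a
        larger normalized fold than the chemical stimulus."""
        from peakamp.synth import sample_id

        dens = gene_body_density_table(
            {t: small_sim.pro_tracks[sample_id("A", t, "pro", 1)]
             for t in ("NHS", "HS", "As")}, small_sim.genes)
        rels = {}
        for t in ("HS", "As"):
            act = set(small_sim.truth.activated[t])
            _, rels[t] = fold_activation(dens, t, act)
        assert rels["HS"] > rels["As"] > 1.0


class TestPromoterPeakFraction:
    def _setup(self, genome):
        genes = [GeneAnnotation(f"g{i}", "chr1", 5_000 + i * 9_000,
                                7_000 + i * 9_000, "+") for i in range(10)]
        return genes, promoter_regions(genes, genome)

    def test_no_peaks_zero(self, genome):
        _, proms = self._setup(genome)
        frac, n_with, n_tot = promoter_peak_fraction(
            proms, PeakTable.from_intervals([]))
        assert (frac, n_with, n_tot) == (0.0, 0, 10)

    def test_all_promoters_covered(self, genome):
        _, proms = self._setup(genome)
        peaks = PeakTable.from_intervals([GenomicInterval("chr1", 0, 100_000)])
        frac, _, _ = promoter_peak_fraction(proms, peaks)
        assert frac == 1.0

    def test_designed_fraction_recovered(self, genome):
        genes, proms = self._setup(genome)
        peaks = PeakTable.from_intervals(
            [GenomicInterval("chr1", genes[i].tss - 50, genes[i].tss + 50)
             for i in (0, 3, 6)])
        frac, n_with, _ = promoter_peak_fraction(proms, peaks)
        assert n_with == 3 and frac == pytest.approx(0.3)

    def test_gene_subset_universe(self, genome):
        genes, proms = self._setup(genome)
        peaks = PeakTable.from_intervals(
            [GenomicInterval("chr1", genes[0].tss - 50, genes[0].tss + 50)])
        frac, _, n_tot = promoter_peak_fraction(proms, peaks,
                                                gene_subset={"g0", "g1"})
        assert n_tot == 2 and frac == pytest.approx(0.5)

    def test_empty_subset_is_na(self, genome):
        _, proms = self._setup(genome)
        frac, _, n_tot = promoter_peak_fraction(
            proms, PeakTable.from_intervals([]), gene_subset={"nope"})
        assert np.isnan(frac) and n_tot == 0


class TestPivots:
    def test_single_cell_pivot(self):
        pk = pd.Series({"g0": "HS,As", "g1": "HS,As"})
        act = pd.Series({"g0": "HS,As", "g1": "HS,As"})
        out = activation_binding_pivot(pk, act)
        assert out["counts"].shape == (1, 1)
        assert out["counts"].iloc[0, 0] == 2

    def test_marginals_cover_universe(self):
        rng = np.random.default_rng(20)
        genes = [f"g{i}" for i in range(200)]
        pk = pd.Series(rng.choice(["HS", "As", "HS,As", "none"], 200), index=genes)
        act = pd.Series(rng.choice(["HS", "As", "none"], 200), index=genes)
        out = activation_binding_pivot(pk, act)
        assert int(out["counts"].to_numpy().sum()) == 200
        assert (out["by_peak_class"]["denominator"].sum()) == 200

    def test_treatment_unique_peak_enrichment_direction(self):
        """When stimulus-unique peaks sit preferentially at genes activated
        by the same stimulus, the pivot composition reflects it."""
        rows = (["HS"] * 30 + ["none"] * 70)
        act = (["HS"] * 25 + ["none"] * 5 + ["HS"] * 10 + ["none"] * 60)
        genes = [f"g{i}" for i in range(100)]
        out = activation_binding_pivot(pd.Series(rows, index=genes),
                                       pd.Series(act, index=genes))
        by_peak = out["by_peak_class"]
        assert by_peak.loc["HS", "HS"] > by_peak.loc["none", "HS"]

    def test_basal_expression_higher_with_peaks(self):
        rng = np.random.default_rng(22)
        genes = [f"g{i}" for i in range(100)]
        has_peak = pd.Series([i < 40 for i in range(100)], index=genes)
        dens = pd.Series(
            np.where(has_peak, rng.lognormal(1.0, 0.5, 100),
                     rng.lognormal(0.0, 0.5, 100)), index=genes)
        summary, res = basal_expression_comparison(dens, has_peak)
        med = summary.set_index("group")["median_density"]
        assert med["with_peak"] > med["without_peak"]
        assert res.p < 0.01


class TestAtacCategories:
    def _setup(self, genome):
        proms = IntervalSet([GenomicInterval("chr1", 10_000, 12_000)])
        atac_peaks = PeakTable.from_intervals([
            GenomicInterval("chr1", 10_500, 11_000),   # promoter +TF
            GenomicInterval("chr1", 50_000, 50_500),   # intergenic +TF
            GenomicInterval("chr1", 70_000, 70_500),   # intergenic -TF
        ])
        tf = PeakTable.from_intervals([GenomicInterval("chr1", 10_600, 10_900),
                                       GenomicInterval("chr1", 50_100, 50_400)])
        return proms, atac_peaks, tf

    def test_identical_tracks_give_unit_ratios(self, genome):
        proms, atac_peaks, tf = self._setup(genome)
        t = CoverageTrack(genome)
        for c in t.data:
            t.data[c][:] = 2.0
        table, _ = atac_category_analysis(atac_peaks, tf, proms,
                                          {"r1": t}, {"r1": t})
        ok = table.dropna(subset=["ratio_mean"])
        assert np.allclose(ok["ratio_mean"], 1.0)

    def test_category_counts_partition_peaks(self, genome):
        proms, atac_peaks, tf = self._setup(genome)
        t = CoverageTrack(genome)
        table, _ = atac_category_analysis(atac_peaks, tf, proms,
                                          {"r1": t}, {"r1": t})
        assert int(table["n_peaks"].sum()) == 3

    def test_targeted_increase_detected_only_in_tf_category(self, genome):
        proms, atac_peaks, tf = self._setup(genome)
        rng = np.random.default_rng(30)
        nhs, hs = CoverageTrack(genome), CoverageTrack(genome)
        for c in nhs.data:
            nhs.data[c][:] = rng.poisson(2.0, len(nhs.data[c]))
            hs.data[c][:] = rng.poisson(2.0, len(hs.data[c]))
        hs.data["chr1"][50_000:50_500] += 10.0   # +TF intergenic only
        table, _ = atac_category_analysis(atac_peaks, tf, proms,
                                          {"r1": nhs}, {"r1": hs})
        t = table.set_index(["category", "tf"])
        assert t.loc[("intergenic", "+TF"), "ratio_mean"] > 2.0
        assert t.loc[("intergenic", "-TF"), "ratio_mean"] == pytest.approx(1.0, abs=0.2)

    def test_class_tf_fractions(self):
        nhs = PeakTable.from_intervals([GenomicInterval("chr1", 0, 100),
                                        GenomicInterval("chr1", 1_000, 1_100)])
        hs = PeakTable.from_intervals([GenomicInterval("chr1", 0, 100),
                                       GenomicInterval("chr1", 2_000, 2_100)])
        tf = PeakTable.from_intervals([GenomicInterval("chr1", 2_050, 2_060)])
        out = atac_class_tf_fractions(nhs, hs, tf).set_index("class")
        assert out.loc["common", "n"] == 1
        assert out.loc["treated_only", "fraction_with_tf"] == 1.0
        assert out.loc["NHS_only", "fraction_with_tf"] == 0.0
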