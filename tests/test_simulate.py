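import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chipcompare import simulate
from chipcompare.annotate import WINDOW_PRESETS, classify_enhancers, classify_promoter_marks
from chipcompare.core import CapacityError, SimulationConfig
from chipcompare.peaks import collapse_duplicates


def tiny(seed=1, **kw):
    base = dict(genome_length=400_000, n_genes=20, n_true_sites=8, n_reads=5_000)
    base.update(kw)
    return SimulationConfig(seed=seed, **base)


class TestReference:
    def test_gc_content_within_binomial_ci(self):
        cfg = SimulationConfig(
            seed=1, genome_length=200_000, n_genes=0, gc_content=0.5
        )
        genome, _ = simulate.simulate_reference(cfg)
        gc = sum(genome.count(b) for b in "GC")
        n = len(genome)
        sigma = np.sqrt(n * 0.25)
        assert abs(gc - 0.5 * n) < 3 * sigma

    def test_no_genes_still_produces_sequence(self):
        cfg = SimulationConfig(seed=2, genome_length=10_000, n_genes=0, n_true_sites=0)
        genome, genes = simulate.simulate_reference(cfg)
        assert len(genome) == 10_000
        assert genes.empty

    def test_determinism(self):
        g1, t1 = simulate.simulate_reference(tiny())
        g2, t2 = simulate.simulate_reference(tiny())
        assert g1 == g2
        assert t1.equals(t2)

    def test_tss_spacing_and_margins(self):
        _, genes = simulate.simulate_reference(tiny())
        tss = np.sort(genes["tss"].to_numpy())
        assert np.all(np.diff(tss) >= SimulationConfig.MIN_TSS_GAP)
        assert tss[0] >= SimulationConfig.GENE_MARGIN
        assert tss[-1] <= 400_000 - SimulationConfig.GENE_MARGIN

    def test_capacity_error_names_required_length(self):
        cfg = tiny(genome_length=50_000)
        with pytest.raises(CapacityError, match=str(cfg.required_genome_length())):
            simulate.simulate_reference(cfg)

    def test_zero_inflated_expression(self):
        cfg = SimulationConfig(
            seed=3, genome_length=10_000_000, n_genes=1000, zero_expression_fraction=0.2
        )
        _, genes = simulate.simulate_reference(cfg)
        frac0 = (genes["expression"] == 0).mean()
        assert 0.1 < frac0 < 0.3


class TestPlantSites:
    def test_motif_planted_at_site_centers(self):
        cfg = tiny()
        genome, genes = simulate.simulate_reference(cfg)
        genome, truth = simulate.plant_binding_sites(genome, genes, cfg)
        assert truth.n_sites == 8
        for site, flag in zip(truth.sites, truth.has_motif):
            if flag:
                assert genome[site.start : site.end] == simulate.EBOX

    def test_no_sites_leaves_genome_unchanged(self):
        cfg = tiny(n_true_sites=0)
        genome, genes = simulate.simulate_reference(cfg)
        genome2, truth = simulate.plant_binding_sites(genome, genes, cfg)
        assert genome2 == genome
        assert truth.n_sites == 0
        assert truth.bound_genes == set()

    def test_distal_sites_far_from_every_tss(self):
        cfg = tiny(seed=4)
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        tss = genes["tss"].to_numpy()
        for site in truth.distal_sites():
            assert np.abs(tss - site.center).min() >= simulate.DISTAL_MIN_TSS_DIST

    def test_bound_genes_equal_brute_force_intersection(self):
        cfg = tiny(seed=6)
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        win = WINDOW_PRESETS["default"]
        expected = set()
        for g in genes.itertuples(index=False):
            if g.strand == "+":
                lo, hi = g.tss - win.upstream, g.tss + win.downstream
            else:
                lo, hi = g.tss - win.downstream, g.tss + win.upstream
            for s in truth.sites:
                if s.start < hi and lo < s.end:
                    expected.add(g.gene_id)
        assert truth.bound_genes == expected

    def test_zero_coupling_matches_uniform_gene_sampling(self):
        """With coupling 0, bound-gene expression should look like a uniform
        draw of genes (rank-sum test over many seeded replicates)."""
        bound_expr, unbound_expr = [], []
        for seed in range(150):
            cfg = SimulationConfig(
                seed=seed,
                genome_length=500_000,
                n_genes=40,
                n_true_sites=10,
                promoter_site_fraction=1.0,
                binding_expression_coupling=0.0,
                zero_expression_fraction=0.0,
            )
            genome, genes = simulate.simulate_reference(cfg)
            _, truth = simulate.plant_binding_sites(genome, genes, cfg)
            chosen = {g for g in truth.site_gene if g is not None}
            sel = genes["gene_id"].isin(chosen)
            bound_expr.extend(genes.loc[sel, "expression"])
            unbound_expr.extend(genes.loc[~sel, "expression"])
        p = stats.mannwhitneyu(bound_expr, unbound_expr).pvalue
        assert p > 0.01

    def test_positive_coupling_prefers_expressed_genes(self):
        cfg = tiny(seed=8, n_genes=40, n_true_sites=12, promoter_site_fraction=1.0)
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        chosen = {g for g in truth.site_gene if g is not None}
        sel = genes["gene_id"].isin(chosen)
        assert genes.loc[sel, "expression"].median() > genes.loc[~sel, "expression"].median()


class TestReads:
    def test_read_count_conservation(self):
        cfg = tiny()
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        reads = simulate.simulate_chip_reads(truth, cfg, "signal")
        assert len(reads) == cfg.n_reads

    def test_pure_background_uniform_chi_square(self):
        cfg = SimulationConfig(
            seed=9,
            genome_length=1_000_000,
            n_genes=0,
            n_true_sites=0,
            n_reads=50_000,
            background_fraction=1.0,
        )
        reads = simulate.simulate_chip_reads(simulate.TruthSet(), cfg, "signal")
        pos5 = np.where(reads["strand"] == "+", reads["start"], reads["end"] - 1)
        counts, _ = np.histogram(pos5, bins=np.arange(0, 1_000_001, 10_000))
        p = stats.chisquare(counts).pvalue
        assert p > 0.01

    def test_pure_signal_reads_hug_single_site(self):
        cfg = tiny(
            seed=10,
            n_true_sites=1,
            promoter_site_fraction=1.0,
            background_fraction=0.0,
            n_reads=2_000,
        )
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        reads = simulate.simulate_chip_reads(truth, cfg, "signal")
        center = truth.sites[0].center
        pos5 = np.where(reads["strand"] == "+", reads["start"], reads["end"] - 1)
        assert np.all(np.abs(pos5 - center) <= cfg.fragment_length)

    def test_strand_asymmetry_about_fragment_length(self):
        cfg = tiny(
            seed=11,
            n_true_sites=1,
            promoter_site_fraction=1.0,
            background_fraction=0.0,
            n_reads=20_000,
        )
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        reads = simulate.simulate_chip_reads(truth, cfg, "signal")
        plus = reads["strand"] == "+"
        mean_plus = reads.loc[plus, "start"].mean()
        mean_minus = (reads.loc[~plus, "end"] - 1).mean()
        assert mean_minus - mean_plus == pytest.approx(cfg.fragment_length, rel=0.05)

    def test_control_profile_ignores_background_fraction(self):
        cfg = tiny(seed=12, background_fraction=0.0)
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        ctrl = simulate.simulate_chip_reads(truth, cfg, "control")
        # background-only: no clustering at sites -> coarse bins look uniform
        pos5 = np.where(ctrl["strand"] == "+", ctrl["start"], ctrl["end"] - 1)
        counts, _ = np.histogram(pos5, bins=np.arange(0, cfg.genome_length + 1, 40_000))
        assert stats.chisquare(counts).pvalue > 0.001

    def test_reads_deterministic_per_label(self):
        cfg = tiny(seed=13)
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        r1 = simulate.simulate_chip_reads(truth, cfg, "signal", label="a")
        r2 = simulate.simulate_chip_reads(truth, cfg, "signal", label="a")
        r3 = simulate.simulate_chip_reads(truth, cfg, "signal", label="b")
        assert r1.equals(r2)
        assert not r1.equals(r3)


class TestMarks:
    def _bundle(self, seed=14, **mark_params):
        cfg = tiny(seed=seed, n_genes=30, n_true_sites=12, promoter_site_fraction=0.5)
        genome, genes = simulate.simulate_reference(cfg)
        _, truth = simulate.plant_binding_sites(genome, genes, cfg)
        marks, labels = simulate.simulate_marks(genes, truth, cfg, **mark_params)
        return genes, truth, marks, labels

    def test_zero_bivalent_fraction_means_no_k27me3_promoters(self):
        _, _, marks, labels = self._bundle(bivalent_fraction=0.0)
        assert marks["H3K27me3"] == []
        assert "bivalent" not in labels["promoters"].values()

    def test_active_enhancers_subset_of_k4me1(self):
        _, _, marks, _ = self._bundle()
        for ac in marks["H3K27ac"]:
            assert any(ac.overlaps(k4) for k4 in marks["H3K4me1"])

    def test_classification_round_trip_recovers_planted_labels(self):
        genes, _, marks, labels = self._bundle(seed=15)
        classes = classify_promoter_marks(genes, marks["H3K4me3"], marks["H3K27me3"])
        assert classes == labels["promoters"]

    def test_enhancer_round_trip_recovers_planted_labels(self):
        genes, _, marks, labels = self._bundle(seed=16)
        enh = classify_enhancers(marks["H3K4me1"], marks["H3K27ac"], genes)
        # the classifier measures the TSS distance of the whole element, so a
        # planted element whose edge dips below the distal cutoff may be
        # dropped; every classified element must match its planted label, and
        # anything dropped must sit within one half-width of the cutoff
        tss = np.sort(genes["tss"].to_numpy())
        for iv, planted in labels["enhancers"].items():
            if iv in enh:
                assert enh[iv] == planted
            else:
                i = np.searchsorted(tss, iv.start)
                near = tss[max(i - 1, 0) : i + 1]
                assert min(iv.distance_to_point(int(t)) for t in near) >= 4_500
        assert set(enh) <= set(labels["enhancers"])

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError, match="bivalent_fraction"):
            self._bundle(bivalent_fraction=1.5)


class TestFixtureIO:
    def test_round_trip_identity(self, tmp_path):
        cfg = tiny(seed=17)
        bundle = simulate.simulate_experiment(cfg)
        simulate.write_fixture(bundle, tmp_path / "fx")
        back = simulate.read_fixture(tmp_path / "fx")
        assert back.genome == bundle.genome
        assert back.genes[["gene_id", "tss", "strand"]].equals(
            bundle.genes[["gene_id", "tss", "strand"]]
        )
        np.testing.assert_allclose(
            back.genes["expression"], bundle.genes["expression"]
        )
        assert back.truth.bound_genes == bundle.truth.bound_genes
        assert [s.start for s in back.truth.sites] == [s.start for s in bundle.truth.sites]
        for label in bundle.reads:
            a = collapse_duplicates(back.reads[label])
            b = collapse_duplicates(bundle.reads[label])
            assert a[["chrom", "start", "end", "strand"]].equals(
                b[["chrom", "start", "end", "strand"]]
            )
        assert back.marks.keys() == bundle.marks.keys()

    def test_manifest_hash_tracks_config(self):
        h1 = simulate.config_hash(tiny(seed=1))
        h2 = simulate.config_hash(tiny(seed=1))
        h3 = simulate.config_hash(tiny(seed=1, n_reads=5_001))
        assert h1 == h2
        assert h1 != h3

    def test_rewrite_is_byte_identical(self, tmp_path):
        cfg = tiny(seed=18)
        bundle = simulate.simulate_experiment(cfg)
        d = tmp_path / "fx"
        simulate.write_fixture(bundle, d)
        first = {p.name: p.read_bytes() for p in d.iterdir()}
        bundle2 = simulate.simulate_experiment(cfg)
        simulate.write_fixture(bundle2, d)
        second = {p.name: p.read_bytes() for p in d.iterdir()}
        assert first == second
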