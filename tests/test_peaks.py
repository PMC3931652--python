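import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from chipcompare import peaks as pk
from chipcompare.core import SimulationConfig
from chipcompare import simulate


def reads_frame(rows):
    """rows: (start, end, strand) on chrT."""
    return pd.DataFrame(
        {
            "chrom": "chrT",
            "start": [r[0] for r in rows],
            "end": [r[1] for r in rows],
            "name": [f"r{i}" for i in range(len(rows))],
            "score": 0,
            "strand": [r[2] for r in rows],
        }
    )


class TestCollapseDuplicates:
    def test_same_5prime_same_strand_collapsed(self):
        reads = reads_frame([(100, 136, "+"), (100, 136, "+"), (100, 136, "+")])
        assert len(pk.collapse_duplicates(reads)) == 1

    def test_opposite_strands_kept(self):
        # a - strand read whose 5' end (end-1) equals 135, not 100
        reads = reads_frame([(100, 136, "+"), (100, 136, "-")])
        assert len(pk.collapse_duplicates(reads)) == 2

    def test_minus_strand_uses_end_coordinate(self):
        # different starts but identical - strand 5' ends collapse
        reads = reads_frame([(90, 136, "-"), (100, 136, "-")])
        assert len(pk.collapse_duplicates(reads)) == 1

    def test_result_independent_of_input_order(self, rng):
        rows = [
            (int(s), int(s) + 36, str(d))
            for s, d in zip(rng.integers(0, 5_000, 200), rng.choice(["+", "-"], 200))
        ]
        a = pk.collapse_duplicates(reads_frame(rows))
        b = pk.collapse_duplicates(reads_frame(rows[::-1]).reset_index(drop=True))
        assert a[["chrom", "start", "end", "strand"]].equals(
            b[["chrom", "start", "end", "strand"]]
        )

    def test_empty_frame_passthrough(self):
        assert pk.collapse_duplicates(reads_frame([])).empty


class TestCoverage:
    def test_single_plus_read_extends_downstream(self):
        reads = reads_frame([(100, 136, "+")])
        cov = pk.build_coverage(reads, 200, 10, {"chrT": 1_000})
        c = cov.counts["chrT"]
        # fragment [100, 300): bins 10..29 covered
        assert list(np.flatnonzero(c)) == list(range(10, 30))

    def test_single_minus_read_extends_upstream(self):
        reads = reads_frame([(264, 300, "-")])
        cov = pk.build_coverage(reads, 200, 10, {"chrT": 1_000})
        c = cov.counts["chrT"]
        # 5' end at 299, fragment [100, 300)
        assert list(np.flatnonzero(c)) == list(range(10, 30))

    def test_matches_per_base_oracle(self, rng):
        L = 3_000
        rows = []
        for _ in range(60):
            s = int(rng.integers(0, L - 36))
            rows.append((s, s + 36, str(rng.choice(["+", "-"]))))
        reads = reads_frame(rows)
        cov = pk.build_coverage(reads, 200, 10, {"chrT": L})
        dense = np.zeros(L, dtype=int)
        starts, ends = pk.fragment_spans(reads, 200, L)
        for s, e in zip(starts, ends):
            dense[s:e] += 1
        for b, count in enumerate(cov.counts["chrT"]):
            # bin count = number of fragments overlapping the bin
            span = slice(b * 10, min((b + 1) * 10, L))
            overlap = sum(
                1 for s, e in zip(starts, ends) if s < span.stop and span.start < e
            )
            assert count == overlap

    def test_fragment_clipped_at_bounds(self):
        reads = reads_frame([(0, 36, "-"), (990, 1000, "+")])
        starts, ends = pk.fragment_spans(reads, 200, 1_000)
        assert starts.min() >= 0 and ends.max() <= 1_000

    def test_fragment_shorter_than_read_rejected(self):
        reads = reads_frame([(0, 300, "+")])
        with pytest.raises(ValueError, match="fragment_length"):
            pk.build_coverage(reads, 200, 10, {"chrT": 1_000})

    def test_mean_bin_count(self):
        reads = reads_frame([(100, 136, "+")])
        cov = pk.build_coverage(reads, 200, 10, {"chrT": 1_000})
        assert cov.mean_bin_count() == pytest.approx(20 / 100)


class TestPoissonTail:
    def test_against_direct_pmf_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            lam = float(rng.uniform(0.1, 30.0))
            k = int(rng.integers(0, 60))
            direct = sum(stats.poisson.pmf(j, lam) for j in range(k, k + 200))
            assert pk.poisson_tail(k, lam) == pytest.approx(direct, rel=1e-10)

    def test_zero_count_is_certain(self):
        assert pk.poisson_tail(0, 3.0) == pytest.approx(1.0)

    def test_log10_matches_linear_in_safe_range(self):
        p = pk.poisson_tail(12, 2.0)
        lp = pk.poisson_tail(12, 2.0, log10=True)
        assert lp == pytest.approx(math.log10(p), rel=1e-12)

    def test_extreme_tail_does_not_underflow(self):
        nlp = -pk.poisson_tail(5_000, 1.0, log10=True)
        assert np.isfinite(nlp) and nlp > 3_000

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pk.poisson_tail(-1, 1.0)
        with pytest.raises(ValueError):
            pk.poisson_tail(3, 0.0)

    @given(st.integers(0, 100), st.floats(0.01, 50.0))
    def test_monotone_decreasing_in_count(self, k, lam):
        assert pk.poisson_tail(k + 1, lam) <= pk.poisson_tail(k, lam) + 1e-15


class TestCandidateRegions:
    def test_simple_run(self):
        c = np.array([0, 0, 5, 6, 7, 0, 0])
        assert pk._candidate_regions(c, 5, 0) == [(2, 4)]

    def test_gap_merging(self):
        c = np.array([5, 5, 0, 0, 5, 5])
        assert pk._candidate_regions(c, 5, 1) == [(0, 1), (4, 5)]
        assert pk._candidate_regions(c, 5, 2) == [(0, 5)]

    def test_no_regions(self):
        assert pk._candidate_regions(np.array([1, 2, 3]), 5, 0) == []


@pytest.fixture(scope="module")
def single_site():
    cfg = SimulationConfig(
        seed=21,
        genome_length=400_000,
        n_genes=20,
        n_true_sites=1,
        promoter_site_fraction=1.0,
        n_reads=20_000,
        background_fraction=0.10,
    )
    genome, genes = simulate.simulate_reference(cfg)
    _, truth = simulate.plant_binding_sites(genome, genes, cfg)
    treat = pk.collapse_duplicates(simulate.simulate_chip_reads(truth, cfg, "signal"))
    ctrl = pk.collapse_duplicates(
        simulate.simulate_chip_reads(truth, cfg, "control", label="m")
    )
    return cfg, truth, treat, ctrl


class TestCallPeaks:
    def test_single_strong_site_recovered(self, single_site):
        cfg, truth, treat, ctrl = single_site
        peaks = pk.call_peaks(treat, ctrl, {cfg.chrom: cfg.genome_length})
        assert peaks, "no peaks called around a strong planted site"
        top = peaks[0]
        center = truth.sites[0].center
        assert top.start <= center < top.end
        assert abs(top.summit - center) < 150
        assert top.neg_log10_pvalue > 50

    def test_background_only_input_yields_no_confident_peaks(self):
        cfg = SimulationConfig(
            seed=22,
            genome_length=1_000_000,
            n_genes=0,
            n_true_sites=0,
            n_reads=50_000,
        )
        truth = simulate.TruthSet()
        treat = pk.collapse_duplicates(
            simulate.simulate_chip_reads(truth, cfg, "signal", label="t")
        )
        ctrl = pk.collapse_duplicates(
            simulate.simulate_chip_reads(truth, cfg, "control", label="c")
        )
        peaks = pk.call_peaks(
            treat, ctrl, {cfg.chrom: cfg.genome_length}, p_cutoff=1e-8
        )
        assert peaks == []

    def test_peaks_sorted_by_significance(self, small_bundle, small_chrom_lengths):
        treat = pk.collapse_duplicates(small_bundle.reads["tagged"])
        ctrl = pk.collapse_duplicates(small_bundle.reads["mock"])
        peaks = pk.call_peaks(treat, ctrl, small_chrom_lengths)
        nlp = [p.neg_log10_pvalue for p in peaks]
        assert nlp == sorted(nlp, reverse=True)

    def test_empty_treatment_returns_no_peaks(self, single_site):
        cfg, _, _, ctrl = single_site
        assert pk.call_peaks(reads_frame([]), ctrl, {cfg.chrom: cfg.genome_length}) == []

    def test_empty_control_rejected(self, single_site):
        cfg, _, treat, _ = single_site
        with pytest.raises(ValueError, match="control"):
            pk.call_peaks(treat, reads_frame([]), {cfg.chrom: cfg.genome_length})

    def test_peak_invariants(self, single_site):
        cfg, _, treat, ctrl = single_site
        for p in pk.call_peaks(treat, ctrl, {cfg.chrom: cfg.genome_length}):
            assert 0 <= p.start <= p.summit < p.end <= cfg.genome_length
            assert p.tag_count >= 1
            assert p.neg_log10_pvalue >= 0
            assert p.end - p.start >= pk.PeakCallParams().min_width


class TestThresholding:
    def _fake_peaks(self):
        return [
            # neg_log10_pvalue 12, 8, 3
            pk.Peak("chrT", 0, 100, 50, 10, 5.0, 12.0),
            pk.Peak("chrT", 200, 300, 250, 8, 4.0, 8.0),
            pk.Peak("chrT", 400, 500, 450, 4, 2.0, 3.0),
        ]

    def test_threshold_keeps_boundary_peak(self):
        kept = pk.threshold_peaks(self._fake_peaks(), 1e-8)
        assert [p.start for p in kept] == [0, 200]

    def test_invalid_cutoff(self):
        with pytest.raises(ValueError):
            pk.threshold_peaks([], 0.0)

    def test_counts_monotone_in_cutoff(self):
        grid = [1e-2, 1e-4, 1e-8, 1e-12]
        table = pk.peak_counts_by_cutoff(self._fake_peaks(), grid)
        counts = table["n_peaks"].to_list()
        assert counts == sorted(counts, reverse=True)
        assert counts[0] == 3 and counts[-1] == 1
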