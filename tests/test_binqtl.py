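"""Binmap construction and QTL scanning: filters, windows, distances, LOD."""

import numpy as np
import pytest

from wildsoy import binqtl as bq, synthdata as sd


class TestFilterSNPs:
    def _table(self, pos, geno, qual=None, chrom=None):
        n_loci = len(pos)
        return bq.SNPCallTable(chrom or ["c1"] * n_loci, pos, geno,
                               None if qual is None else np.asarray(qual))

    def test_quality_strictly_above_threshold(self):
        geno = np.full((25, 2), "A", dtype="<U1")
        t = self._table([100, 200], geno, qual=[30.0, 30.5])
        out = bq.filter_snps(t)
        assert out.pos == [200]

    def test_dense_window_dropped_entirely(self):
        geno = np.full((25, 4), "A", dtype="<U1")
        t = self._table([100, 105, 109, 500], geno, qual=[40] * 4)
        out = bq.filter_snps(t)
        assert out.pos == [500]

    def test_min_line_count(self):
        geno = np.full((25, 2), "A", dtype="<U1")
        geno[:6, 0] = "-"      # locus 0 typed in 19 lines
        t = self._table([100, 500], geno, qual=[40, 40])
        out = bq.filter_snps(t)
        assert out.pos == [500]

    def test_heterozygous_calls_become_missing(self):
        geno = np.full((25, 1), "A", dtype="<U1")
        geno[0, 0] = "H"
        t = self._table([100], geno, qual=[40])
        out = bq.filter_snps(t)
        assert out.genotypes[0, 0] == "-"


class TestSlidingWindow:
    def test_uniform_window_called(self):
        calls = np.array(["A"] * 15)
        assert bq.sliding_window_genotypes(calls).tolist() == ["A"]

    def test_majority_eleven_of_fifteen(self):
        calls = np.array(["A"] * 11 + ["B"] * 4)
        assert bq.sliding_window_genotypes(calls)[0] == "A"

    def test_below_majority_is_heterozygous_call(self):
        calls = np.array(["A"] * 8 + ["B"] * 7)
        assert bq.sliding_window_genotypes(calls)[0] == "H"

    def test_sparse_window_missing(self):
        calls = np.array(["A"] * 4 + ["-"] * 11)
        assert bq.sliding_window_genotypes(calls)[0] == "-"

    def test_short_chromosome_single_window(self):
        calls = np.array(["A"] * 7)
        out = bq.sliding_window_genotypes(calls)
        assert out.size == 1 and out[0] == "A"


class TestBreakpoints:
    def test_clean_transition_interval_contains_midpoint(self):
        calls = np.array(["A"] * 15 + ["B"] * 15)
        pos = np.arange(1, 31) * 1000
        wc = bq.sliding_window_genotypes(calls)
        (bp,) = bq.detect_breakpoints(wc, pos)
        assert bp.start <= 15_500 <= bp.end
        assert (bp.from_state, bp.to_state) == ("A", "B")

    def test_uniform_chromosome_no_breakpoints(self):
        calls = np.array(["A"] * 40)
        wc = bq.sliding_window_genotypes(calls)
        assert bq.detect_breakpoints(wc, np.arange(40) * 1000) == []

    def test_isolated_heterozygous_run_not_a_breakpoint(self):
        calls = np.array(["A"] * 20 + ["H"] * 6 + ["A"] * 20)
        wc = bq.sliding_window_genotypes(calls)
        assert bq.detect_breakpoints(wc, np.arange(46) * 1000) == []


class TestBinMap:
    def test_no_breakpoints_single_bin(self):
        bm = bq.build_binmap([{"c1": []}], [{"c1": "A"}], {"c1": 1_000_000})
        assert bm.n_bins == 1
        assert (bm.start[0], bm.end[0]) == (1, 1_000_000)
        assert bm.genotypes[0, 0] == "A"

    def test_single_breakpoint_boundary_in_containing_cell(self):
        bp = bq.Breakpoint(1_225_000, 1_235_000, "A", "B")
        bm = bq.build_binmap([{"c1": [bp]}], [{"c1": "A"}], {"c1": 2_000_000})
        boundaries = [e for e in bm.end[:-1]]
        assert len(boundaries) == 1
        assert 1_200_000 <= boundaries[0] <= 1_250_000
        assert bm.genotypes[0].tolist() == ["A", "B"]

    def test_saturated_breakpoints_keep_grid(self):
        bps = [bq.Breakpoint(s, s + 49_000, "A", "B")
               for s in range(1000, 500_000, 50_000)]
        bm = bq.build_binmap([{"c1": bps}], [{"c1": "A"}], {"c1": 500_000})
        assert bm.n_bins == 10

    def test_bins_contiguous_and_ordered(self):
        pop = sd.simulate_ril_population(30, {"chr1": 80.0}, 400, seed=21)
        bm, _ = bq.binmap_from_population(pop)
        for i in range(1, bm.n_bins):
            if bm.chrom[i] == bm.chrom[i - 1]:
                assert bm.start[i] == bm.end[i - 1] + 1
        assert bm.cM is not None
        for i in range(1, bm.n_bins):
            if bm.chrom[i] == bm.chrom[i - 1]:
                assert bm.cM[i] >= bm.cM[i - 1]


class TestMappingFunctions:
    def test_kosambi_closed_form(self):
        assert bq.kosambi(0.1) == pytest.approx(25 * np.log(1.2 / 0.8))
        assert bq.kosambi(0.1) == pytest.approx(10.14, abs=0.01)

    def test_haldane_closed_form(self):
        assert bq.haldane(0.1) == pytest.approx(-50 * np.log(0.8))
        assert bq.haldane(0.1) == pytest.approx(11.16, abs=0.01)

    def test_first_order_agreement_as_r_vanishes(self):
        r = 1e-4
        assert bq.kosambi(r) == pytest.approx(100 * r, rel=1e-4)
        assert bq.haldane(r) == pytest.approx(100 * r, rel=1e-2)

    def test_inverses_round_trip(self):
        for r in (0.01, 0.1, 0.3):
            assert bq.kosambi_inv(bq.kosambi(r)) == pytest.approx(r)
            assert bq.haldane_inv(bq.haldane(r)) == pytest.approx(r)

    def test_identical_columns_zero_distance(self):
        g = np.array([["A", "A"], ["B", "B"], ["A", "A"]])
        bm = bq.BinMap(["c1", "c1"], [1, 50_001], [50_000, 100_000], g)
        bm = bq.genetic_distances(bm)
        assert bm.cM[1] == 0.0


class TestLODScan:
    def _binmap_with_signal(self, n=100, r2=0.5, seed=0):
        rng = np.random.default_rng(seed)
        g = rng.choice(["A", "B"], size=(n, 3))
        bm = bq.BinMap(["c1"] * 3, [1, 50_001, 100_001],
                       [50_000, 100_000, 150_000], g)
        bm.cM = np.array([0.0, 10.0, 20.0])
        x = np.where(g[:, 1] == "A", 1.0, -1.0)
        xc = x - x.mean()
        noise = rng.normal(size=n)
        noise -= noise.mean()
        noise -= xc * (xc @ noise) / (xc @ xc)     # orthogonal to the signal
        noise *= np.sqrt((xc @ xc) * (1 - r2) / r2 / (noise @ noise))
        y = x + noise                               # R^2 at the bin is exactly r2
        return bm, y

    def test_closed_form_lod_at_known_r2(self):
        bm, y = self._binmap_with_signal(n=100, r2=0.5)
        scan = bq.lod_scan(bm, y)
        at_bin = scan.lod[np.argmin(np.abs(scan.pos_cM - 10.0))]
        assert at_bin == pytest.approx(50 * np.log10(2), rel=1e-6)

    def test_affine_phenotype_invariance(self):
        bm, y = self._binmap_with_signal()
        l1 = bq.lod_scan(bm, y).lod
        l2 = bq.lod_scan(bm, 3.7 * y - 11.0).lod
        assert np.allclose(l1, l2)

    def test_constant_phenotype_all_zero(self):
        bm, y = self._binmap_with_signal()
        scan = bq.lod_scan(bm, np.ones_like(y))
        assert np.allclose(scan.lod, 0.0)

    def test_lod_nonnegative(self):
        bm, y = self._binmap_with_signal(seed=3)
        assert np.all(bq.lod_scan(bm, y).lod >= 0)


class TestPermutationThreshold:
    def test_deterministic_given_seed(self):
        bm, y = TestLODScan()._binmap_with_signal(seed=5)
        t1 = bq.permutation_threshold(bm, y, n_perm=100, seed=3)
        t2 = bq.permutation_threshold(bm, y, n_perm=100, seed=3)
        assert t1 == t2

    def test_alpha_one_gives_null_minimum(self):
        bm, y = TestLODScan()._binmap_with_signal(seed=6)
        t = bq.permutation_threshold(bm, y, n_perm=100, alpha=1.0, seed=3)
        t05 = bq.permutation_threshold(bm, y, n_perm=100, alpha=0.05, seed=3)
        assert t <= t05

    def test_too_few_permutations_rejected(self):
        bm, y = TestLODScan()._binmap_with_signal()
        with pytest.raises(ValueError):
            bq.permutation_threshold(bm, y, n_perm=10)


class TestCallQTL:
    def test_no_signal_no_qtl(self):
        bm, y = TestLODScan()._binmap_with_signal(r2=0.5)
        rng = np.random.default_rng(0)
        scan = bq.lod_scan(bm, rng.normal(size=y.size))
        scan.threshold = 3.0
        assert bq.call_qtl(scan) == []

    def test_planted_qtl_support_contains_truth(self):
        pop = sd.simulate_ril_population(
            96, {"chr1": 100.0}, 800, qtls=[sd.QTLSpec("chr1", 10_000_000)],
            heritability=0.5, seed=31)
        bm, _ = bq.binmap_from_population(pop)
        scan = bq.lod_scan(bm, pop.phenotypes)
        scan.threshold = bq.permutation_threshold(bm, pop.phenotypes,
                                                  n_perm=100, seed=1)
        qtls = bq.call_qtl(scan)
        assert len(qtls) >= 1
        truth_idx = next(i for i in range(bm.n_bins)
                         if bm.start[i] <= 10_000_000 <= bm.end[i])
        truth_cM = bm.cM[truth_idx]
        best = max(qtls, key=lambda q: q.peak_lod)
        assert best.support_start_cM - 5 <= truth_cM <= best.support_end_cM + 5

    def test_unlinked_qtls_on_two_chromosomes(self):
        pop = sd.simulate_ril_population(
            96, {"chr1": 60.0, "chr2": 60.0}, 600,
            qtls=[sd.QTLSpec("chr1", 6_000_000), sd.QTLSpec("chr2", 6_000_000)],
            heritability=0.6, seed=32)
        bm, _ = bq.binmap_from_population(pop)
        scan = bq.lod_scan(bm, pop.phenotypes)
        scan.threshold = bq.permutation_threshold(bm, pop.phenotypes,
                                                  n_perm=100, seed=2)
        qtls = bq.call_qtl(scan)
        assert {q.chrom for q in qtls} == {"chr1", "chr2"}
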