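"""Generator correctness: determinism, conservation laws, planted truth."""

import numpy as np
import pytest

from wildsoy import synthdata as sd
from wildsoy.util import revcomp


class TestGenerateReference:
    def test_deterministic_given_seed(self):
        a = sd.generate_reference(1, [150_000], gc=0.35, seed=1)
        b = sd.generate_reference(1, [150_000], gc=0.35, seed=1)
        assert a.genome == b.genome
        assert a.te_library == b.te_library
        assert a.te_intervals == b.te_intervals
        assert a.gene_intervals == b.gene_intervals

    def test_chromosome_count_and_lengths(self):
        ref = sd.generate_reference(2, [1_000_000, 2_000_000], seed=3)
        assert {c: len(s) for c, s in ref.genome.items()} == {
            "chr1": 1_000_000, "chr2": 2_000_000}

    def test_gc_content_converges(self):
        ref = sd.generate_reference(1, [10_000_000], gc=0.35, te_library_size=0,
                                    n_genes=0, n_te_copies=0, seed=2)
        s = ref.genome["chr1"]
        gc = (s.count("G") + s.count("C")) / len(s)
        assert abs(gc - 0.35) < 0.01

    @pytest.mark.parametrize("kwargs", [
        dict(n_chrom=1, lengths=[50_000]),          # too short
        dict(n_chrom=1, lengths=[150_000], gc=0.0),
        dict(n_chrom=1, lengths=[150_000], gc=1.5),
        dict(n_chrom=2, lengths=[150_000]),         # count mismatch
    ])
    def test_rejects_invalid_input(self, kwargs):
        with pytest.raises(ValueError):
            sd.generate_reference(**{"gc": 0.4, "seed": 0, **kwargs})

    def test_te_library_element_sizes(self, small_reference):
        assert all(500 <= len(e) <= 10_000 for e in small_reference.te_library)

    def test_gene_intervals_non_overlapping(self, small_reference):
        for ivs in small_reference.gene_intervals.values():
            for (s1, e1, _), (s2, e2, _) in zip(ivs, ivs[1:]):
                assert e1 < s2


class TestDeriveVariantGenome:
    def test_empty_plan_identity(self, small_reference):
        qry, truth = sd.derive_variant_genome(small_reference, sd.SVPlan(), snp_rate=0.0)
        assert qry == small_reference.genome
        assert truth.n_snps == 0

    def test_insertion_length_conservation(self, small_reference):
        plan = sd.SVPlan([sd.PlannedEvent("novel_insertion", "chr1", 100_000, length=2000)])
        qry, _ = sd.derive_variant_genome(small_reference, plan)
        assert len(qry["chr1"]) == 300_000 + 2000

    def test_inversion_is_reverse_complement(self):
        ref = sd.generate_reference(1, [500_000], gc=0.4, seed=7)
        plan = sd.SVPlan([sd.PlannedEvent("inversion", "chr1", 100_000, length=150_000)])
        qry, truth = sd.derive_variant_genome(ref, plan)
        ev = truth.events[0]
        got = qry[ev.qry_chrom][ev.qry_start - 1:ev.qry_end]
        want = revcomp(ref.genome["chr1"][100_000 - 1:100_000 + 150_000 - 1])
        assert got == want
        assert len(qry["chr1"]) == 500_000  # inversions length-preserving

    def test_reciprocal_translocation_conserves_length(self, two_chrom_reference):
        ref = two_chrom_reference
        plan = sd.SVPlan([sd.PlannedEvent("inter_translocation", "chr1", 800_000,
                                          chrom2="chr2", pos2=600_000)])
        qry, _ = sd.derive_variant_genome(ref, plan)
        assert sum(map(len, qry.values())) == sum(map(len, ref.genome.values()))
        # the tails actually swapped
        assert qry["chr1"][800_000 - 1:] == ref.genome["chr2"][600_000 - 1:]

    def test_overlapping_events_rejected_with_names(self, small_reference):
        plan = sd.SVPlan([
            sd.PlannedEvent("inversion", "chr1", 100_000, length=50_000),
            sd.PlannedEvent("novel_insertion", "chr1", 120_000, length=1000),
        ])
        with pytest.raises(ValueError, match="overlapping planted events"):
            sd.derive_variant_genome(small_reference, plan)

    def test_liftover_round_trip_near_events(self, small_reference):
        plan = sd.SVPlan([
            sd.PlannedEvent("novel_insertion", "chr1", 50_000, length=1500),
            sd.PlannedEvent("inversion", "chr1", 150_000, length=20_000),
        ])
        qry, truth = sd.derive_variant_genome(small_reference, plan, snp_rate=0.0)
        for pos in (10, 49_999, 50_010, 149_999, 160_000, 299_000):
            img = truth.lift("chr1", pos)
            assert img is not None
            qc, qp = img
            rbase = small_reference.genome["chr1"][pos - 1]
            qbase = qry[qc][qp - 1]
            # inside the inversion the lifted base is the complement
            if 150_000 <= pos < 170_000:
                assert qbase == revcomp(rbase)
            else:
                assert qbase == rbase

    def test_snps_respect_breakpoint_clearance(self, small_reference):
        plan = sd.SVPlan([sd.PlannedEvent("novel_insertion", "chr1", 150_000, length=2000)])
        qry, truth = sd.derive_variant_genome(small_reference, plan, snp_rate=0.01, seed=4)
        ev = truth.events[0]
        window = qry["chr1"][ev.qry_start - 201:ev.qry_start - 1]
        ref_window = small_reference.genome["chr1"][150_000 - 200:150_000]
        assert window == ref_window  # no SNPs within 200 bp upstream of the junction


class TestSimulateRILs:
    def test_zero_cM_chromosome_never_recombines(self):
        pop = sd.simulate_ril_population(10, {"chr1": 0.0}, 20, seed=1)
        assert all(pop.truth.crossovers[i]["chr1"] == [] for i in range(10))

    def test_deterministic_given_seed(self):
        a = sd.simulate_ril_population(12, {"chr1": 80.0}, 100, seed=9)
        b = sd.simulate_ril_population(12, {"chr1": 80.0}, 100, seed=9)
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.allclose(a.phenotypes, b.phenotypes)

    def test_heritability_moment_check(self):
        ratios = []
        for rep in range(100):
            pop = sd.simulate_ril_population(
                96, {"chr1": 100.0}, 50,
                qtls=[sd.QTLSpec("chr1", 10_000_000)], heritability=0.3, seed=1000 + rep)
            t = pop.truth
            g = np.array([1.0 if t.genotype_at(i, "chr1", 10_000_000) == "A" else -1.0
                          for i in range(96)])
            ratios.append(np.var(g) / np.var(pop.phenotypes))
        assert abs(np.mean(ratios) - 0.3) < 0.1

    def test_rejects_bad_heritability(self):
        with pytest.raises(ValueError):
            sd.simulate_ril_population(10, {"chr1": 50.0}, 10,
                                       qtls=[sd.QTLSpec("chr1", 1000)],
                                       heritability=1.5, seed=0)

    def test_genotypes_piecewise_constant_between_crossovers(self):
        pop = sd.simulate_ril_population(20, {"chr1": 100.0}, 200, seed=3)
        t = pop.truth
        for i in range(20):
            xs = t.crossovers[i]["chr1"]
            states = t.states[i]["chr1"]
            assert len(states) == len(xs) + 1
            for a, b in zip(states, states[1:]):
                assert a != b

    def test_residual_heterozygosity_bounded(self):
        pop = sd.simulate_ril_population(50, {"chr1": 100.0}, 500, seed=5)
        frac_h = np.mean(pop.genotypes == "H")
        assert frac_h <= 0.01


class TestSimulateOpticalMolecules:
    def _map(self):
        from wildsoy.omap import OpticalMap
        return OpticalMap("src", 10_000_000, list(range(1000, 10_000_000, 1000)))

    def test_noise_free_molecules_are_exact_windows(self):
        m = self._map()
        mols, truth = sd.simulate_optical_molecules(m, 5, (200_000, 200_000), seed=1)
        src_labels = np.asarray(m.labels)
        for mol in mols:
            _, start, end = truth[mol.id]["source"]
            expect = src_labels[(src_labels >= start) & (src_labels <= end)] - start + 1
            assert mol.labels == expect.tolist()

    def test_label_dropout_rate(self):
        m = self._map()
        mols, truth = sd.simulate_optical_molecules(
            m, 60, (180_000, 220_000), label_fn_rate=0.1, seed=2)
        n_true = sum(len(t["true_label_idx"]) for t in truth.values())
        n_kept = sum(len(t["kept_label_idx"]) for t in truth.values())
        assert n_true >= 10_000
        dropped = 1 - n_kept / n_true
        assert abs(dropped - 0.1) < 0.02

    def test_fixed_intensity_passes_qc_intensity_rule(self):
        from wildsoy.omap import qc_filter_molecules
        m = self._map()
        mols, _ = sd.simulate_optical_molecules(m, 20, (200_000, 300_000),
                                                intensity_dist=0.5, seed=3)
        _, removed = qc_filter_molecules(mols)
        assert not any("intensity" in reasons for _, reasons in removed)

    def test_zero_molecules_is_empty_not_error(self):
        mols, truth = sd.simulate_optical_molecules(self._map(), 0, seed=1)
        assert mols == [] and truth == {}
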