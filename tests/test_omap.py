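"""Optical-map operations: digestion, merging, QC, alignment, coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from wildsoy import omap, synthdata as sd
from wildsoy.omap import OpticalMap, OpticalMolecule
from wildsoy.util import random_seq, revcomp


class TestDigest:
    def test_planted_motifs_labelled_at_forward_start(self, rng):
        base = random_seq(rng, 10_000, 0.3).replace("GCTCTTC", "GCTCTTG")
        base = base.replace("GAAGAGC", "GAAGAGA")
        seq = base[:99] + "GCTCTTC" + base[106:4999] + "GCTCTTC" + base[5006:]
        m = omap.digest(seq, "GCTCTTC")
        assert m.labels == [100, 5000]

    def test_absent_motif_no_labels(self):
        assert omap.digest("ACAC" * 1000, "GCTCTTC").labels == []

    def test_reverse_strand_occurrence_labelled(self, rng):
        base = random_seq(rng, 10_000, 0.3).replace("GCTCTTC", "GCTCTTG")
        base = base.replace("GAAGAGC", "GAAGAGA")
        seq = base[:199] + revcomp("GCTCTTC") + base[206:]
        m = omap.digest(seq, "GCTCTTC")
        assert m.labels == [200]

    def test_strand_symmetry(self, rng):
        seq = random_seq(rng, 50_000, 0.4)
        f = omap.digest(seq, "GCTCTTC").labels
        r = omap.digest(revcomp(seq), "GCTCTTC").labels
        mirrored = sorted(len(seq) - p - 5 for p in r)  # motif span maps end-to-start
        assert f == mirrored


class TestMergeLabels:
    @pytest.mark.parametrize("labels,expect", [
        ([5000, 5600], [5300]),
        ([5000, 6500], [5000, 6500]),
        ([1000, 1500, 2000], [1500]),
    ])
    def test_merge_rules(self, labels, expect):
        m = OpticalMap("m", 100_000, labels)
        assert omap.merge_labels(m).labels == expect

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.sets(st.integers(min_value=1, max_value=400_000),
                   min_size=1, max_size=50))
    def test_merge_idempotent_for_arbitrary_label_sets(self, labels):
        m = OpticalMap("m", 400_000, sorted(labels))
        once = omap.merge_labels(m)
        assert omap.merge_labels(once).labels == once.labels
        if len(once.labels) > 1:
            assert int(np.min(np.diff(once.labels))) >= 1000

    def test_idempotent_and_spaced_on_random_maps(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 60))
            labels = sorted(set(rng.integers(1, 500_000, size=n).tolist()))
            m = OpticalMap("m", 500_000, labels)
            once = omap.merge_labels(m)
            twice = omap.merge_labels(once)
            assert once.labels == twice.labels
            if len(once.labels) > 1:
                assert min(np.diff(once.labels)) >= 1000


class TestQCFilter:
    def test_constructed_set_partitions_exactly(self):
        def mol(i, length, intensity, n_labels):
            labels = list(range(5000, 5000 + 5000 * n_labels, 5000))
            return OpticalMolecule(f"m{i}", length, labels, "1", intensity)

        good = [mol(i, 200_000, 0.5, 12) for i in range(3)]
        short = [mol(10 + i, 140_000, 0.5, 12) for i in range(3)]
        bright = [mol(20 + i, 200_000, 0.7, 12) for i in range(3)]
        sparse = [mol(30 + i, 200_000, 0.5, 8) for i in range(3)]
        retained, removed = omap.qc_filter_molecules(good + short + bright + sparse)
        assert [m.id for m in retained] == [m.id for m in good]
        reasons = {m.id: r for m, r in removed}
        assert all(reasons[m.id] == ["length"] for m in short)
        assert all(reasons[m.id] == ["intensity"] for m in bright)
        assert all(reasons[m.id] == ["labels"] for m in sparse)

    def test_boundary_values_retained(self):
        m = OpticalMolecule("b", 150_000, list(range(1000, 10_000, 1000)), "1", 0.6)
        retained, removed = omap.qc_filter_molecules([m])
        assert retained == [m]   # length == 150 Kb, intensity == 0.6, 9 labels

    def test_partition_is_exact(self, rng):
        mols = [OpticalMolecule(f"m{i}", int(rng.integers(100_000, 300_000)),
                                sorted(set(rng.integers(1, 90_000, size=int(rng.integers(2, 20))).tolist())),
                                "1", float(rng.random()))
                for i in range(50)]
        retained, removed = omap.qc_filter_molecules(mols)
        assert len(retained) + len(removed) == 50
        assert {m.id for m in retained}.isdisjoint({m.id for m, _ in removed})


class TestRepetitiveFilter:
    def test_uniform_spacing_removed(self):
        m = OpticalMap("rep", 160_000, list(range(3000, 156_000, 3000)))
        retained, removed = omap.filter_repetitive_maps([m])
        assert removed == [m]

    def test_random_spacing_retained(self, rng):
        gaps = rng.integers(2000, 50_000, size=30)
        labels = np.cumsum(gaps).tolist()
        m = OpticalMap("rand", int(labels[-1] + 1000), labels)
        retained, removed = omap.filter_repetitive_maps([m])
        assert retained == [m]

    def test_two_label_map_never_removed(self):
        m = OpticalMap("tiny", 10_000, [2000, 5000])
        retained, _ = omap.filter_repetitive_maps([m])
        assert retained == [m]


class TestAlignMaps:
    def _map(self, rng, n=12, length=400_000):
        labels = sorted(set(rng.integers(2000, length - 2000, size=n).tolist()))
        m = OpticalMap("a", length, labels)
        return omap.merge_labels(m, 2000)

    def test_self_alignment_matches_everything(self, rng):
        m = self._map(rng)
        al = omap.align_maps(m, m, sizing_tolerance=500)
        assert al.orientation == "forward"
        assert len(al.pairs) == m.n_labels
        assert al.ref_skips == 0 and al.qry_skips == 0

    def test_mirror_alignment_is_reverse(self, rng):
        m = self._map(rng)
        mirror = OpticalMap("b", m.length, sorted(m.length - p + 1 for p in m.labels))
        al = omap.align_maps(m, mirror, sizing_tolerance=500)
        assert al.orientation == "reverse"
        assert len(al.pairs) == m.n_labels

    def test_deleted_label_costs_one_skip(self, rng):
        m = self._map(rng, n=14)
        drop = m.n_labels // 2
        b = OpticalMap("b", m.length, [p for i, p in enumerate(m.labels) if i != drop])
        al = omap.align_maps(m, b, sizing_tolerance=500)
        assert len(al.pairs) == m.n_labels - 1
        assert al.ref_skips == 1 and al.qry_skips == 0

    def test_match_count_equals_exhaustive_oracle(self, rng):
        for _ in range(5):
            a = sorted(set(rng.integers(1, 120_000, size=8).tolist()))
            b = sorted(set(rng.integers(1, 120_000, size=8).tolist()))
            ma = OpticalMap("a", 130_000, a)
            mb = OpticalMap("b", 130_000, b)
            al = omap.align_maps(ma, mb, sizing_tolerance=2000,
                                 miss_penalty=0.0, fp_penalty=0.0, max_skip=7,
                                 match_score=1.0)
            fwd = oracles.exhaustive_map_alignment(a, b, 2000)
            rev = oracles.exhaustive_map_alignment(
                a, sorted(130_000 - p + 1 for p in b), 2000)
            assert al.score == pytest.approx(max(fwd, rev))

    def test_molecules_realign_to_source_without_skips(self, rng):
        seq = random_seq(rng, 2_000_000, 0.38)
        src = omap.merge_labels(omap.digest(seq, omap.NICKING_MOTIFS["Nt.BspQI"], "src"))
        mols, _ = sd.simulate_optical_molecules(src, 6, (200_000, 350_000), seed=4)
        for mol in mols:
            if mol.n_labels < 2:
                continue
            al = omap.align_maps(src, mol, sizing_tolerance=800)
            assert al.orientation == "forward"
            assert len(al.pairs) == mol.n_labels
            assert al.ref_skips == 0 and al.qry_skips == 0

    def test_matched_fraction_degrades_with_sizing_error(self, rng):
        seq = random_seq(rng, 1_500_000, 0.38)
        src = omap.merge_labels(omap.digest(seq, omap.NICKING_MOTIFS["Nt.BspQI"], "src"))
        fracs = []
        for sd_bp in (0, 600, 2000):
            matched = total = 0
            mols, _ = sd.simulate_optical_molecules(
                src, 8, (250_000, 350_000), sizing_sd=sd_bp, seed=9)
            for mol in mols:
                if mol.n_labels < 2:
                    continue
                al = omap.align_maps(src, mol, sizing_tolerance=700)
                matched += len(al.pairs)
                total += mol.n_labels
            fracs.append(matched / total)
        assert fracs[0] >= fracs[1] >= fracs[2]


class TestRegionCoverage:
    def _alignments(self, n):
        return [omap.OMAlignment("ref", f"m{i}", "forward", [], 0, 0, 1.0,
                                 (100_000, 300_000)) for i in range(n)]

    def test_thirty_molecules_retained(self):
        depth, ok = omap.region_coverage(self._alignments(30), "ref", (150_000, 250_000))
        assert (depth, ok) == (30, True)

    def test_twentynine_molecules_excluded(self):
        depth, ok = omap.region_coverage(self._alignments(29), "ref", (150_000, 250_000))
        assert (depth, ok) == (29, False)

    def test_empty_alignments_excluded_depth_zero(self):
        assert omap.region_coverage([], "ref", (1, 100)) == (0, False)

    def test_partial_span_does_not_count(self):
        als = self._alignments(35)
        depth, ok = omap.region_coverage(als, "ref", (50_000, 250_000))
        assert depth == 0 and not ok


class TestIO:
    def test_cmap_round_trip(self, tmp_path, rng):
        maps = [OpticalMap("12", 500_000, sorted(set(rng.integers(1, 499_000, 20).tolist())))]
        path = tmp_path / "maps.cmap"
        omap.write_cmap(maps, path)
        (back,) = omap.read_cmap(path)
        assert back.length == maps[0].length
        assert back.labels == maps[0].labels

    def test_molecule_tsv_round_trip(self, tmp_path):
        mols = [OpticalMolecule("m1", 180_000, [1000, 5000, 9000], "1", 0.45),
                OpticalMolecule("m2", 220_000, [], "1", 0.2)]
        path = tmp_path / "mols.tsv"
        omap.write_molecules_tsv(mols, path)
        back = omap.read_molecules_tsv(path)
        assert [(m.id, m.length, m.labels) for m in back] == \
               [(m.id, m.length, m.labels) for m in mols]
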