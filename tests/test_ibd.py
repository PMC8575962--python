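import numpy as np
import pytest

from ibdtrace.ibd import (
    IBDSegment,
    brute_force_ibd,
    build_match_sets,
    detect_ibd,
    locus_overlap,
    read_match_file,
    write_match_file,
)
from ibdtrace.simdata import (
    FocalAllele,
    GeneticMap,
    Haplotype,
    HaplotypeSet,
    drop_haplotypes,
    make_genetic_map,
    simulate_background,
    simulate_pedigree,
    true_ibd_segments,
)


def hapset_from_alleles(panel, gmap, sample_alleles):
    """Build a HaplotypeSet from {sid: (hap0 array, hap1 array)}."""
    hs = HaplotypeSet(panel, gmap)
    for sid, (a0, a1) in sample_alleles.items():
        segs = {c: [(0.0, gmap.chrom_length_cm(c), f"{sid}.0")] for c in gmap.chromosomes}
        hs.haps[sid] = (
            Haplotype(np.asarray(a0, np.uint8), segs),
            Haplotype(np.asarray(a1, np.uint8), segs),
        )
    return hs


@pytest.fixture(scope="module")
def panel100():
    return make_genetic_map(1, 100.0, 500, seed=31)


class TestDetectBasics:
    def test_identical_genotypes_one_full_segment(self, panel100):
        gmap, panel = panel100
        rng = np.random.default_rng(1)
        a0 = (rng.random(500) < 0.5).astype(np.uint8)
        a1 = (rng.random(500) < 0.5).astype(np.uint8)
        hs = hapset_from_alleles(panel, gmap, {"A": (a0, a1), "B": (a0.copy(), a1.copy())})
        segs = detect_ibd(hs, word_size=16, min_length_cm=0.5)
        assert len(segs) == 1
        assert segs[0].length_cm == pytest.approx(100.0)

    def test_opposite_homozygotes_everywhere_no_segment(self, panel100):
        gmap, panel = panel100
        zero, one = np.zeros(500, np.uint8), np.ones(500, np.uint8)
        hs = hapset_from_alleles(panel, gmap, {"A": (zero, zero), "B": (one, one)})
        assert detect_ibd(hs, word_size=16, min_length_cm=0.5) == []

    def test_empty_sample_set_rejected(self, panel100):
        gmap, panel = panel100
        with pytest.raises(ValueError):
            detect_ibd(HaplotypeSet(panel, gmap))

    def test_small_word_size_rejected(self, panel100):
        gmap, panel = panel100
        hs = hapset_from_alleles(
            panel, gmap, {"A": (np.zeros(500), np.zeros(500))})
        with pytest.raises(ValueError):
            detect_ibd(hs, word_size=4)

    def test_heterozygous_site_does_not_split(self, panel100):
        gmap, panel = panel100
        a = np.zeros(500, np.uint8)
        b = np.zeros(500, np.uint8)
        b2 = np.zeros(500, np.uint8)
        b2[250] = 1  # B heterozygous mid-chromosome, A homozygous ref
        hs = hapset_from_alleles(panel, gmap, {"A": (a, a.copy()), "B": (b, b2)})
        segs = detect_ibd(hs, word_size=16, min_length_cm=1.0)
        assert len(segs) == 1 and segs[0].length_cm == pytest.approx(100.0)

    def test_symmetry_under_insertion_order(self, panel100):
        gmap, panel = panel100
        rng = np.random.default_rng(3)
        mk = lambda: (rng.random(500) < 0.5).astype(np.uint8)
        shared = mk()
        ab = {"A": (shared, mk()), "B": (shared.copy(), mk()), "C": (mk(), mk())}
        ba = {k: ab[k] for k in ("C", "B", "A")}
        s1 = detect_ibd(hapset_from_alleles(panel, gmap, ab), word_size=16, min_length_cm=1)
        s2 = detect_ibd(hapset_from_alleles(panel, gmap, ba), word_size=16, min_length_cm=1)
        assert s1 == s2

    def test_canonical_pair_order(self, panel100):
        gmap, panel = panel100
        rng = np.random.default_rng(4)
        shared = (rng.random(500) < 0.5).astype(np.uint8)
        hs = hapset_from_alleles(
            panel, gmap,
            {"ZZ": (shared, shared.copy()), "AA": (shared.copy(), shared.copy())},
        )
        for seg in detect_ibd(hs, word_size=16, min_length_cm=1):
            assert seg.id_a <= seg.id_b


class TestBruteForce:
    def test_guard_on_large_instances(self):
        gmap, panel = make_genetic_map(1, 100.0, 5000, seed=1)
        hs = simulate_background(80, panel, gmap, seed=1)
        with pytest.raises(ValueError):
            brute_force_ibd(hs, 1.0)

    def test_truth_containment_zero_error(self):
        """Every true founder-shared segment >= min_length is covered."""
        gmap, panel = make_genetic_map(1, 80.0, 800, seed=6)
        ped = simulate_pedigree(3, 2.5, seed=10)
        haps = drop_haplotypes(ped, gmap, panel, seed=9)
        segs = brute_force_ibd(haps, min_length_cm=5.0)
        spacing = 80.0 / 799  # marker spacing in cM: endpoints snap to markers
        by_pair = {}
        for s in segs:
            by_pair.setdefault(s.pair, []).append(s)
        ids = haps.sample_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                key = tuple(sorted((a, b)))
                for chrom, lo, hi in true_ibd_segments(haps, a, b, min_cM=5.0):
                    assert any(
                        s.chrom == chrom
                        and s.start_cm <= lo + spacing + 1e-9
                        and s.end_cm >= hi - spacing - 1e-9
                        for s in by_pair.get(key, [])
                    ), f"true segment {chrom}:{lo}-{hi} of {key} uncovered"

    def test_run_endpoints_flanked_by_opposite_homozygote_or_chrom_end(self, panel100):
        gmap, panel = panel100
        rng = np.random.default_rng(12)
        geno = {}
        for sid in ("A", "B"):
            geno[sid] = ((rng.random(500) < 0.5).astype(np.uint8),
                         (rng.random(500) < 0.5).astype(np.uint8))
        hs = hapset_from_alleles(panel, gmap, geno)
        ga = geno["A"][0] + geno["A"][1]
        gb = geno["B"][0] + geno["B"][1]
        opp = ((ga == 0) & (gb == 2)) | ((ga == 2) & (gb == 0))
        for seg in brute_force_ibd(hs, min_length_cm=0.0):
            i = int(np.searchsorted(panel.bp, seg.start_bp))
            j = int(np.searchsorted(panel.bp, seg.end_bp))
            assert i == 0 or opp[i - 1]
            assert j == len(panel.bp) - 1 or opp[j + 1]


class TestOracleEquivalence:
    def test_detect_matches_brute_force_on_related_samples(self):
        """Seed-and-extend equals exhaustive scanning on pedigree cohorts."""
        word = 64
        for seed in range(10):
            gmap, panel = make_genetic_map(
                1, 50.0, 2000, seed=seed, freq_range=(0.35, 0.65)
            )
            ped = simulate_pedigree(3, 2.2, seed=seed + 100)
            haps = drop_haplotypes(ped, gmap, panel, seed=seed)
            fast = detect_ibd(haps, word_size=word, min_length_cm=4.0)
            slow = brute_force_ibd(haps, min_length_cm=4.0)
            word_cm = word * 50.0 / 2000
            assert _equivalent(fast, slow, word_cm), f"seed {seed}"


def _equivalent(fast, slow, tol_cm):
    if len(fast) != len(slow):
        return False
    for f, s in zip(sorted(fast), sorted(slow)):
        if f.pair != s.pair or f.chrom != s.chrom:
            return False
        if abs(f.start_cm - s.start_cm) > tol_cm or abs(f.end_cm - s.end_cm) > tol_cm:
            return False
    return True


class TestThresholdMonotonicity:
    def test_segment_sets_nest(self):
        gmap, panel = make_genetic_map(1, 60.0, 1200, seed=8)
        ped = simulate_pedigree(3, 2.0, seed=21)
        haps = drop_haplotypes(ped, gmap, panel, seed=8)
        s6 = set(detect_ibd(haps, word_size=32, min_length_cm=6.0))
        s1 = set(detect_ibd(haps, word_size=32, min_length_cm=1.0))
        s05 = set(detect_ibd(haps, word_size=32, min_length_cm=0.5))
        assert s6 <= s1 <= s05


class TestLocusOverlap:
    def make_map(self):
        bp = np.arange(1, 102) * 1000
        cm = np.linspace(0.0, 10.0, 101)
        return GeneticMap({"chr1": (bp, cm)})

    def seg(self, s_cm, e_cm, gmap):
        return IBDSegment.make(
            "A", "B", "chr1",
            int(gmap.cm_to_bp("chr1", s_cm)), int(gmap.cm_to_bp("chr1", e_cm)),
            s_cm, e_cm, 10,
        )

    def test_disjoint_is_zero(self):
        gmap = self.make_map()
        window = FocalAllele("chr1", 80_000, 70_000, 90_000, "X.0")
        assert locus_overlap(self.seg(0.0, 2.0, gmap), window, gmap) == 0.0

    def test_nested_is_inner_length(self):
        gmap = self.make_map()
        window = FocalAllele("chr1", 50_000, 1_000, 101_000, "X.0")
        assert locus_overlap(self.seg(3.0, 5.0, gmap), window, gmap) == pytest.approx(2.0)

    def test_partial_matches_marker_counting_oracle(self):
        gmap = self.make_map()
        bp, cm = gmap.anchors["chr1"]
        rng = np.random.default_rng(5)
        spacing = 0.1
        for _ in range(50):
            s, e = sorted(rng.uniform(0, 10, 2))
            w0, w1 = sorted(rng.uniform(0, 10, 2))
            window = FocalAllele(
                "chr1",
                int(gmap.cm_to_bp("chr1", (w0 + w1) / 2)),
                int(gmap.cm_to_bp("chr1", w0)),
                int(gmap.cm_to_bp("chr1", w1)),
                "X.0",
            )
            got = locus_overlap(self.seg(s, e, gmap), window, gmap)
            inside = cm[(cm >= max(s, w0)) & (cm <= min(e, w1))]
            oracle = inside[-1] - inside[0] if len(inside) >= 2 else 0.0
            assert got == pytest.approx(oracle, abs=2 * spacing)

    def test_wrong_chromosome(self):
        gmap = self.make_map()
        window = FocalAllele("chr1", 50_000, 40_000, 60_000, "X.0")
        seg = IBDSegment.make("A", "B", "chr2", 1, 2000, 0.0, 1.0, 5)
        assert locus_overlap(seg, window, gmap) == 0.0


class TestBuildMatchSets:
    def setup_method(self):
        bp = np.arange(1, 102) * 100_000
        cm = np.linspace(0.0, 100.0, 101)
        self.gmap = GeneticMap({"chr1": (bp, cm)})
        self.locus = FocalAllele(
            "chr1",
            int(self.gmap.cm_to_bp("chr1", 50.0)),
            int(self.gmap.cm_to_bp("chr1", 48.0)),
            int(self.gmap.cm_to_bp("chr1", 52.0)),
            "X.0",
        )

    def seg(self, a, b, s_cm, e_cm):
        return IBDSegment.make(
            a, b, "chr1",
            int(self.gmap.cm_to_bp("chr1", s_cm)), int(self.gmap.cm_to_bp("chr1", e_cm)),
            s_cm, e_cm, 10,
        )

    def test_long_segment_off_locus_is_genetic_match_only(self):
        ms = build_match_sets(
            [self.seg("S1", "carrier", 10.0, 16.5)], ["carrier"], self.locus, self.gmap
        )
        assert ms.genetic_matches == {"S1"}
        assert ms.at_locus_matches == set()

    def test_exactly_six_cm_is_not_a_match(self):
        # strict inequality at the genome threshold
        ms = build_match_sets(
            [self.seg("S1", "carrier", 10.0, 16.0)], ["carrier"], self.locus, self.gmap
        )
        assert ms.genetic_matches == set()

    def test_segment_covering_window_is_at_locus(self):
        segs = [self.seg("S1", "carrier", 40.0, 60.0)]
        ms = build_match_sets(segs, ["carrier"], self.locus, self.gmap)
        assert ms.at_locus_matches == {"S1"}
        assert ms.locus_cm["S1"]["carrier"] == pytest.approx(4.0)

    def test_exactly_one_cm_overlap_is_not_at_locus(self):
        segs = [
            self.seg("S1", "carrier", 10.0, 20.0),  # qualifies genome-wide
            self.seg("S1", "carrier", 48.0, 49.0),  # exactly 1 cM at locus
        ]
        ms = build_match_sets(segs, ["carrier"], self.locus, self.gmap)
        assert ms.genetic_matches == {"S1"}
        assert ms.at_locus_matches == set()

    def test_at_locus_nested_in_genetic(self):
        segs = [self.seg("S1", "carrier", 45.0, 55.0)]
        ms = build_match_sets(segs, ["carrier"], self.locus, self.gmap)
        # 10 cM segment covering locus: both genetic and at-locus
        assert ms.at_locus_matches <= ms.genetic_matches

    def test_known_carriers_excluded(self):
        segs = [self.seg("carrierA", "carrierB", 30.0, 70.0)]
        ms = build_match_sets(segs, ["carrierA", "carrierB"], self.locus, self.gmap)
        assert ms.genetic_matches == set()

    def test_locus_outside_map_rejected(self):
        bad = FocalAllele("chr1", 10**9 + 100, 10**9, 10**9 + 200, "X.0")
        with pytest.raises(ValueError):
            build_match_sets([], ["c"], bad, self.gmap)

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            build_match_sets([], ["c"], self.locus, self.gmap, genome_threshold_cm=0)


class TestTruthRecallAndFalsePositives:
    def test_truth_recall_zero_error(self):
        """True founder segments >= min_length + 2 word windows are found."""
        word = 32
        gmap, panel = make_genetic_map(1, 80.0, 1600, seed=14)
        word_cm = word * 80.0 / 1600
        ped = simulate_pedigree(3, 2.5, seed=30)
        haps = drop_haplotypes(ped, gmap, panel, seed=14)
        min_len = 5.0
        detected = detect_ibd(haps, word_size=word, min_length_cm=min_len)
        by_pair = {}
        for s in detected:
            by_pair.setdefault(s.pair, []).append(s)
        ids = haps.sample_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                for chrom, lo, hi in true_ibd_segments(haps, a, b):
                    if hi - lo < min_len + 2 * word_cm:
                        continue
                    key = tuple(sorted((a, b)))
                    assert any(
                        s.chrom == chrom and s.start_cm <= lo + word_cm and s.end_cm >= hi - word_cm
                        for s in by_pair.get(key, [])
                    ), f"missed true segment {chrom}:{lo:.2f}-{hi:.2f} for {key}"

    def test_background_false_positive_rate_logged(self, capsys):
        gmap, panel = make_genetic_map(1, 100.0, 2000, seed=15)
        bg = simulate_background(30, panel, gmap, seed=15)
        segs = detect_ibd(bg, word_size=64, min_length_cm=6.0)
        n_pairs = 30 * 29 // 2
        print(f"background FP rate (>6 cM): {len(segs)}/{n_pairs} pairs")
        assert len(segs) >= 0  # rate is reported, not asserted zero


class TestMatchFile:
    def test_round_trip(self, tmp_path, panel100):
        gmap, panel = panel100
        ped = simulate_pedigree(3, 2.0, seed=40)
        haps = drop_haplotypes(ped, gmap, panel, seed=41)
        segs = detect_ibd(haps, word_size=16, min_length_cm=2.0)
        path = tmp_path / "out.match"
        write_match_file(path, segs)
        assert read_match_file(path) == segs


class TestIBSFilter:
    def test_density_filter_drops_sparse_segments(self):
        # 2 cM between markers -> density far below 1 per 0.2 cM
        bp = np.arange(1, 52) * 1_000_000
        cm = np.linspace(0.0, 100.0, 51)
        gmap = GeneticMap({"chr1": (bp, cm)})
        from ibdtrace.simdata.genmap import MarkerPanel

        panel = MarkerPanel(
            chrom=np.array(["chr1"] * 51, dtype=object), bp=bp, cm=cm,
            ref=np.array(["A"] * 51, dtype=object), alt=np.array(["C"] * 51, dtype=object),
            freq=np.full(51, 0.5),
        )
        rng = np.random.default_rng(2)
        shared = (rng.random(51) < 0.5).astype(np.uint8)
        hs = hapset_from_alleles(
            panel, gmap, {"A": (shared, shared.copy()), "B": (shared.copy(), shared.copy())}
        )
        plain = detect_ibd(hs, word_size=16, min_length_cm=1.0)
        filtered = detect_ibd(hs, word_size=16, min_length_cm=1.0, ibs_filter=True)
        assert plain and not filtered
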