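"""Mutation-pair barcode sharing, pattern encoding and SV haplotype mapping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import linkedhap as lh
from linkedhap.pairs import (
    CNVSegment,
    PairAnalysisConfig,
    PairPattern,
    PairPatternCounts,
    SVCall,
    classify_pair,
    encode_pattern,
    filter_pairs,
    map_sv_haplotype,
    pair_distance_profile,
    shared_barcode_table,
)
from linkedhap.somatic import H1, H2, PhasingCall, SomaticMutation
from tests.conftest import make_obs


def mut(pos, chrom="chr1"):
    return SomaticMutation(chrom, pos, "A", "T")


def call(verdict, site):
    return PhasingCall(site=site, verdict=verdict, method="combined")


def site_rows(bc, pos, allele, n=1, hap=1, chrom="chr1"):
    return [(f"{bc}", chrom, pos, allele, hap)] * n


class TestFilterPairs:
    def neutral(self, chrom="chr1"):
        return [CNVSegment(chrom, 1, 10_000_000, 0.0)]

    def covered(self, positions, n_barcodes=12):
        rows = []
        for pos in positions:
            for i in range(n_barcodes):
                rows += site_rows(f"bx{pos}_{i}", pos, 1 if i == 0 else 0)
        return make_obs(rows)

    def test_distance_cutoff_inclusive_at_62kb(self):
        near = [mut(100_000), mut(162_000)]  # exactly 62 kb
        far = [mut(100_000), mut(170_001)]  # 70 kb
        obs = self.covered([100_000, 162_000, 170_001])
        assert len(filter_pairs(near, self.neutral(), obs)) == 1
        assert len(filter_pairs(far, self.neutral(), obs)) == 0

    def test_non_neutral_site_excluded(self):
        cnv = [
            CNVSegment("chr1", 1, 150_000, 0.0),
            CNVSegment("chr1", 150_001, 300_000, 0.3),
        ]
        muts = [mut(100_000), mut(160_000)]
        obs = self.covered([100_000, 160_000])
        assert filter_pairs(muts, cnv, obs) == []

    def test_site_outside_all_segments_excluded(self):
        muts = [mut(100_000), mut(110_000)]
        obs = self.covered([100_000, 110_000])
        assert filter_pairs(muts, [CNVSegment("chr1", 1, 50_000, 0.0)], obs) == []

    def test_coverage_band_and_alt_requirement(self):
        """Four crafted sites: brute-force application of the filters keeps 2 pairs."""
        rows = []
        # site 1: 12 barcodes, 1 ALT -> eligible
        for i in range(12):
            rows += site_rows(f"a{i}", 10_000, 1 if i == 0 else 0)
        # site 2: 12 barcodes, 1 ALT -> eligible
        for i in range(12):
            rows += site_rows(f"b{i}", 20_000, 1 if i == 0 else 0)
        # site 3: only 5 barcodes -> coverage below 10
        for i in range(5):
            rows += site_rows(f"c{i}", 30_000, 1 if i == 0 else 0)
        # site 4: 12 barcodes but no ALT
        for i in range(12):
            rows += site_rows(f"d{i}", 40_000, 0)
        # site 5: eligible, completes the second pair
        for i in range(15):
            rows += site_rows(f"e{i}", 50_000, 1 if i < 2 else 0)
        obs = make_obs(rows)
        muts = [mut(p) for p in (10_000, 20_000, 30_000, 40_000, 50_000)]
        pairs = filter_pairs(muts, self.neutral(), obs)
        kept = {(a.pos, b.pos) for a, b in pairs}
        assert kept == {(10_000, 20_000), (10_000, 50_000), (20_000, 50_000)}

    def test_untagged_barcodes_do_not_count_as_phased_coverage(self):
        rows = []
        for i in range(12):
            rows += site_rows(f"a{i}", 10_000, 1 if i == 0 else 0, hap=0)
        obs = make_obs(rows)
        assert filter_pairs([mut(10_000), mut(11_000)], self.neutral(), obs) == []


class TestSharedBarcodeTable:
    def test_nras_fixture_counts(self, nras_bundle):
        pair = tuple(nras_bundle.somatic_sites)
        counts = shared_barcode_table(pair, nras_bundle.observations)
        assert counts.counts == {
            "REF-REF": 2,
            "REF-ALT": 1,
            "ALT-REF": 1,
            "ALT-ALT": 0,
        }
        assert counts.n_shared_barcodes == 4

    def test_actg_fixture_counts(self, actg_bundle):
        pair = tuple(actg_bundle.somatic_sites)
        counts = shared_barcode_table(pair, actg_bundle.observations)
        assert counts.counts["ALT-REF"] == 6
        assert counts.counts["ALT-ALT"] == 24

    def test_disjoint_barcode_sets(self):
        obs = make_obs(
            site_rows("bx1", 1000, 1) + site_rows("bx2", 2000, 1)
        )
        counts = shared_barcode_table((mut(1000), mut(2000)), obs)
        assert counts.n_shared_barcodes == 0
        assert all(v == 0 for v in counts.counts.values())

    def test_conflicting_barcode_dropped_and_counted(self):
        obs = make_obs(
            [
                ("bx1", "chr1", 1000, 0, 1),
                ("bx1", "chr1", 1000, 1, 1),  # conflict at site a
                ("bx1", "chr1", 2000, 1, 1),
            ]
        )
        counts = shared_barcode_table((mut(1000), mut(2000)), obs)
        assert counts.n_shared_barcodes == 1
        assert counts.n_conflicting_barcodes == 1
        assert sum(counts.counts.values()) == 0

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_set_intersection_oracle(self, data):
        """Random fixtures against a brute-force set-intersection oracle."""
        n_bc = data.draw(st.integers(2, 12))
        alleles_a = data.draw(
            st.lists(st.sampled_from([0, 1, None]), min_size=n_bc, max_size=n_bc)
        )
        alleles_b = data.draw(
            st.lists(st.sampled_from([0, 1, None]), min_size=n_bc, max_size=n_bc)
        )
        rows = []
        for i, (a, b) in enumerate(zip(alleles_a, alleles_b)):
            if a is not None:
                rows += site_rows(f"bx{i}", 1000, a)
            if b is not None:
                rows += site_rows(f"bx{i}", 2000, b)
        obs = make_obs(rows)
        counts = shared_barcode_table((mut(1000), mut(2000)), obs)
        expected = {"REF-REF": 0, "REF-ALT": 0, "ALT-REF": 0, "ALT-ALT": 0}
        n_shared = 0
        for a, b in zip(alleles_a, alleles_b):
            if a is None or b is None:
                continue
            n_shared += 1
            name = f"{'ALT' if a else 'REF'}-{'ALT' if b else 'REF'}"
            expected[name] += 1
        assert counts.n_shared_barcodes == n_shared
        assert counts.counts == expected

    def test_swap_symmetry(self, actg_bundle):
        pair = tuple(actg_bundle.somatic_sites)
        counts = shared_barcode_table(pair, actg_bundle.observations)
        swapped = shared_barcode_table(pair[::-1], actg_bundle.observations)
        assert swapped.counts["REF-ALT"] == counts.counts["ALT-REF"]
        assert swapped.counts["ALT-REF"] == counts.counts["REF-ALT"]
        assert swapped.counts["REF-REF"] == counts.counts["REF-REF"]
        # sequential ordering swaps accordingly
        assert classify_pair(encode_pattern(counts)) == "sequential_a_first"
        assert classify_pair(encode_pattern(swapped)) == "sequential_b_first"


class TestEncodeAndClassify:
    @pytest.mark.parametrize(
        "counts,bits",
        [((2, 1, 1, 0), "1110"), ((10, 0, 6, 24), "1011"), ((5, 0, 0, 0), "1000")],
    )
    def test_encode(self, counts, bits):
        pc = PairPatternCounts(site_a=mut(1), site_b=mut(2))
        pc.counts = dict(zip(("REF-REF", "REF-ALT", "ALT-REF", "ALT-ALT"), counts))
        assert encode_pattern(pc).bits == bits

    def test_nras_case(self):
        interp = classify_pair(
            PairPattern("1110"),
            (call(H2, mut(1)), call(H2, mut(2))),
            cn_neutral=True,
        )
        assert interp == "independent_subclones"

    def test_independent_requires_same_haplotype_and_neutral(self):
        assert (
            classify_pair(PairPattern("1110"), (call(H1, mut(1)), call(H2, mut(2))), True)
            == "uninformative"
        )
        assert (
            classify_pair(PairPattern("1110"), (call(H2, mut(1)), call(H2, mut(2))), False)
            == "uninformative"
        )

    @pytest.mark.parametrize(
        "bits,expected",
        [
            ("1011", "sequential_a_first"),
            ("0011", "sequential_a_first"),
            ("1101", "sequential_b_first"),
            ("1001", "co_occurring_only"),
            ("0001", "co_occurring_only"),
            ("1100", "single_mutant_only"),
            ("1010", "single_mutant_only"),
            ("1000", "uninformative"),
            ("0000", "uninformative"),
            ("1111", "mixed"),
            ("0111", "mixed"),
        ],
    )
    def test_pattern_map(self, bits, expected):
        assert classify_pair(PairPattern(bits)) == expected


class TestPairDistanceProfile:
    def test_same_site_pair_is_error(self):
        with pytest.raises(ValueError):
            pair_distance_profile([(mut(1000), mut(1000))], make_obs([]))

    def test_sharing_decays_with_distance(self):
        """Exponential molecules make co-barcoding decay on the molecule scale."""
        rng = np.random.default_rng(17)
        params = lh.SimulationParams(
            region_length=600_000,
            molecule_length_mean=20_000.0,
            mean_depth=40.0,
            het_snp_density=0.0,
        )
        germ = lh.simulate_germline(params, rng)
        sites = [(300_000 - d, 300_000) for d in (500, 20_000, 200_000)]
        tree = lh.CloneTree(
            [lh.Clone("c", 1.0, mutations=[(p, 1) for p in
                       {p for pair in sites for p in pair}])],
            purity=1.0,
        )
        tumor = lh.simulate_tumor(germ, tree, rng)
        obs = lh.simulate_barcodes(germ, tumor, params, rng)
        prof = pair_distance_profile(
            [(mut(a, "chr1"), mut(b, "chr1")) for a, b in sites], obs
        )
        shared = prof.sort_values("distance")["n_shared_barcodes"].tolist()
        # 200 kb apart (10 mean lengths) shares essentially nothing
        assert shared[0] > shared[-1]
        assert shared[-1] <= 1

    def test_near_pairs_always_share_a_barcode(self):
        """Sites < 100 bp apart sit on the same reads, hence the same barcode."""
        rng = np.random.default_rng(23)
        params = lh.SimulationParams(
            region_length=200_000, mean_depth=40.0, het_snp_density=0.0
        )
        germ = lh.simulate_germline(params, rng)
        pairs_pos = [(50_000, 50_050), (100_000, 100_090)]
        tree = lh.CloneTree(
            [lh.Clone("c", 1.0, mutations=[(p, 1) for pair in pairs_pos for p in pair])],
            purity=1.0,
        )
        tumor = lh.simulate_tumor(germ, tree, rng)
        obs = lh.simulate_barcodes(germ, tumor, params, rng)
        prof = pair_distance_profile(
            [(mut(a, "chr1"), mut(b, "chr1")) for a, b in pairs_pos], obs
        )
        assert (prof["n_shared_barcodes"] >= 1).all()


class TestMapSVHaplotype:
    def sv(self):
        return SVCall("chr4", 1_871_962, "chr14", 105_700_000, "TRA")

    def obs(self, tags=(2, 2, 2), n_barcodes=3):
        rows = []
        for i in range(n_barcodes):
            rows += [
                (f"bx{i}", "chr4", 1_871_962 + 50, 0, tags[i % len(tags)]),
                (f"bx{i}", "chr14", 105_700_000 - 50, 0, tags[i % len(tags)]),
            ]
        return make_obs(rows)

    def test_consistent_h2(self):
        res = map_sv_haplotype(self.sv(), self.obs())
        assert res.verdict == H2 and res.n_supporting_barcodes == 3

    def test_single_barcode_unsupported(self):
        res = map_sv_haplotype(self.sv(), self.obs(n_barcodes=1))
        assert res.verdict == "unsupported"

    def test_mixed_tags_inconsistent(self):
        res = map_sv_haplotype(self.sv(), self.obs(tags=(1, 2)))
        assert res.verdict == "inconsistent"

    def test_overlapping_windows_error(self):
        sv = SVCall("chr1", 1_000_000, "chr1", 1_050_000, "DEL")
        with pytest.raises(ValueError):
            map_sv_haplotype(sv, make_obs([]))
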