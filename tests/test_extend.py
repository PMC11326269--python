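"""Phase-block extension: switch votes, binomial guard, parity propagation."""

import itertools

import numpy as np
import pytest

from linkedhap.core import PhasedVariant, build_phase_blocks
from linkedhap.extend import (
    NO_SWITCH,
    SWITCH,
    UNDETERMINED,
    BlockOverlap,
    ExtendConfig,
    SwitchRecommendation,
    build_graph,
    extension_stats,
    find_overlaps,
    propagate_orientation,
    recommend_switch,
)
from linkedhap.simulate import scenario


def variant(pos, ps, hap1, chrom="chr1"):
    return PhasedVariant(
        chrom, pos, "A", "G", (0, 1),
        phased=True, phase_set=ps, hap1_allele=hap1, hap2_allele=1 - hap1,
    )


def flipped(v):
    return PhasedVariant(
        v.chrom, v.pos, v.ref_allele, v.alt_allele, v.genotype,
        phased=True, phase_set=v.phase_set,
        hap1_allele=v.hap2_allele, hap2_allele=v.hap1_allele,
    )


def rec(t, r, n, k, verdict=None):
    overlap = BlockOverlap(t, r, n_shared=n, n_switch_votes=k)
    if verdict is None:
        return recommend_switch(overlap)
    return SwitchRecommendation(overlap, verdict, overlap.switch_fraction)


class TestFindOverlaps:
    def sample(self, hap1s):
        return [variant(100 * (i + 1), 1, h) for i, h in enumerate(hap1s)]

    def test_identical_samples_zero_switch_fraction(self):
        target = self.sample([0, 1, 0, 1])
        overlaps = find_overlaps(target, list(target))
        assert len(overlaps) == 1
        assert overlaps[0].switch_fraction == 0.0

    def test_globally_flipped_reference(self):
        target = self.sample([0, 1, 0, 1])
        overlaps = find_overlaps(target, [flipped(v) for v in target])
        assert overlaps[0].switch_fraction == 1.0

    def test_votes_split_at_planted_switch_error(self):
        target = self.sample([0, 1, 0, 1, 0, 1])
        reference = [v if i < 3 else flipped(v) for i, v in enumerate(target)]
        (overlap,) = find_overlaps(target, reference)
        assert (overlap.n_shared, overlap.n_switch_votes) == (6, 3)

    def test_duplicate_positions_error(self):
        target = self.sample([0, 1]) + [variant(100, 1, 0)]
        with pytest.raises(ValueError, match="duplicated"):
            find_overlaps(target, self.sample([0, 1]))

    def test_variants_matched_on_full_key(self):
        target = self.sample([0, 1])
        reference = [
            PhasedVariant(
                "chr1", v.pos, "A", "C", (0, 1),  # different alt allele
                phased=True, phase_set=1, hap1_allele=0, hap2_allele=1,
            )
            for v in target
        ]
        assert find_overlaps(target, reference) == []


class TestRecommendSwitch:
    def test_unanimous_switch(self):
        assert rec("T", "R", 20, 20).verdict == SWITCH

    def test_below_min_overlap_undetermined(self):
        assert rec("T", "R", 5, 5).verdict == UNDETERMINED

    def test_hard_cutoff_strict(self):
        # 19/20 = 0.95 is not > 0.95
        assert rec("T", "R", 20, 19).verdict == UNDETERMINED
        assert rec("T", "R", 20, 1).verdict == UNDETERMINED  # 0.05 not < 0.05
        assert rec("T", "R", 40, 1).verdict == NO_SWITCH  # 0.025 < 0.05

    def test_balanced_votes_undetermined(self):
        assert rec("T", "R", 50, 25).verdict == UNDETERMINED

    def test_binomial_guard_uses_configured_alpha(self):
        # 10/10 switch votes: p = 2 * 0.5^10 ~ 0.002
        strict = ExtendConfig(alpha=1e-4)
        overlap = BlockOverlap("T", "R", n_shared=10, n_switch_votes=10)
        assert recommend_switch(overlap, strict).verdict == UNDETERMINED
        assert recommend_switch(overlap).verdict == SWITCH

    def test_label_swap_flips_verdicts(self):
        """Swapping one sample's H1/H2 labels maps SWITCH <-> NO_SWITCH."""
        for n, k in [(30, 30), (30, 0), (50, 48), (12, 6)]:
            a = rec("T", "R", n, k).verdict
            b = rec("T", "R", n, n - k).verdict
            mapping = {SWITCH: NO_SWITCH, NO_SWITCH: SWITCH, UNDETERMINED: UNDETERMINED}
            assert b == mapping[a]


def brute_force_orientations(targets, refs, edges):
    """Enumerate all target-orientation assignments consistent with the edges.

    An edge (t, r, w) forces orient(t) XOR orient(r) = (w == 1).  For each
    candidate target assignment, check a consistent reference assignment
    exists.
    """
    targets, refs = sorted(targets, key=repr), sorted(refs, key=repr)
    valid = []
    for bits in itertools.product((0, 1), repeat=len(targets)):
        orient = dict(zip(targets, bits))
        ok = True
        for r in refs:
            required = None
            for t, rr, w in edges:
                if rr != r:
                    continue
                val = orient[t] ^ (w % 2)
                if required is None:
                    required = val
                elif required != val:
                    ok = False
                    break
            if not ok:
                break
        if ok:
            valid.append(orient)
    return valid


class TestParityGraph:
    def fig4b_graph(self):
        recs = [
            rec("T4", "R1", 20, 20, SWITCH),
            rec("T7", "R1", 20, 20, SWITCH),
            rec("T6", "R1", 20, 0, NO_SWITCH),
        ]
        return build_graph(recs)

    def test_same_orientation_through_shared_reference(self):
        graph = self.fig4b_graph()
        groups = propagate_orientation(graph)
        (group,) = groups
        # T4 and T7 both switch relative to R1 -> same orientation;
        # T6 does not switch -> opposite to T4/T7
        assert group.orientations["T4"] == group.orientations["T7"]
        assert group.orientations["T6"] == 1 - group.orientations["T4"]
        assert group.orientations["T4"] == 0  # anchored at T4

    def test_odd_cycle_flagged_inconsistent(self):
        recs = [
            rec("T1", "R1", 20, 20, SWITCH),
            rec("T1", "R2", 20, 0, NO_SWITCH),
            rec("T2", "R1", 20, 0, NO_SWITCH),
            rec("T2", "R2", 20, 0, NO_SWITCH),
        ]
        graph = build_graph(recs)
        assert graph.inconsistent == [True]
        (group,) = propagate_orientation(graph)
        assert not group.consistent and group.orientations is None

    def test_undetermined_recommendations_excluded(self):
        recs = [
            rec("T1", "R1", 20, 20, SWITCH),
            rec("T2", "R1", 5, 5),  # UNDETERMINED via thresholds
        ]
        graph = build_graph(recs)
        assert ("T", "T2") not in graph.graph

    def test_chain_parity(self):
        """Chain T1-R1-T2-R2-T3 with weights 1,2,1,1."""
        recs = [
            rec("T1", "R1", 20, 20, SWITCH),
            rec("T2", "R1", 20, 0, NO_SWITCH),
            rec("T2", "R2", 20, 20, SWITCH),
            rec("T3", "R2", 20, 20, SWITCH),
        ]
        (group,) = propagate_orientation(build_graph(recs))
        assert group.orientations["T2"] == (group.orientations["T1"] + 1) % 2
        assert group.orientations["T3"] == (group.orientations["T1"] + 1) % 2

    def test_matches_brute_force_on_random_components(self):
        """Parity propagation vs exhaustive enumeration on random bipartite graphs."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n_t = int(rng.integers(1, 8))
            n_r = int(rng.integers(1, 5))
            targets = [f"T{i}" for i in range(n_t)]
            refs = [f"R{i}" for i in range(n_r)]
            edges = []
            for t in targets:
                for r in refs:
                    if rng.random() < 0.5:
                        edges.append((t, r, int(rng.integers(1, 3))))
            recs = [
                rec(t, r, 20, 20 if w == 1 else 0, SWITCH if w == 1 else NO_SWITCH)
                for t, r, w in edges
            ]
            graph = build_graph(recs)
            groups = propagate_orientation(graph)
            valid = brute_force_orientations(targets, refs, edges)
            connected_targets = {
                t for g in groups for t in g.target_blocks
            }
            for group in groups:
                if not group.consistent:
                    # no assignment satisfies the component's constraints
                    comp_edges = [
                        e for e in edges if e[0] in group.target_blocks
                    ]
                    assert not brute_force_orientations(
                        group.target_blocks,
                        {r for _, r, _ in comp_edges},
                        comp_edges,
                    )
                    continue
                # group orientations (up to a global flip) appear in the
                # brute-force solution set restricted to this component
                restricted = {
                    tuple(sorted((t, o[t]) for t in group.target_blocks))
                    for o in valid
                } if valid else set()
                ours = tuple(sorted(group.orientations.items()))
                flipped_ours = tuple(
                    sorted((t, 1 - b) for t, b in group.orientations.items())
                )
                if restricted:
                    assert ours in restricted or flipped_ours in restricted
            assert connected_targets <= set(targets)

    def test_extra_parity_edges_connect_targets_directly(self):
        graph = build_graph([], extra_edges=[("T1", "T2", 1), ("T2", "T3", 2)])
        (group,) = propagate_orientation(graph)
        assert group.orientations["T2"] == 1 - group.orientations["T1"]
        assert group.orientations["T3"] == group.orientations["T2"]


class TestMatchedPairRecovery:
    def test_noiseless_verdicts_and_orientations_match_truth(self):
        bundle = scenario("matched_pair", seed=9)
        overlaps = find_overlaps(bundle.target_variants, bundle.reference_variants)
        recs = [recommend_switch(o) for o in overlaps]
        t_flips = {int(k): v for k, v in bundle.truth["target_block_flips"].items()}
        r_flips = {int(k): v for k, v in bundle.truth["reference_block_flips"].items()}
        determined = [r for r in recs if r.verdict != UNDETERMINED]
        assert determined, "expected at least one determined overlap"
        for r in determined:
            truth_switch = (
                t_flips[r.overlap.target_block[1]]
                != r_flips[r.overlap.reference_block[1]]
            )
            assert r.verdict == (SWITCH if truth_switch else NO_SWITCH)
        # all overlaps with enough shared variants are determined (no noise)
        for r in recs:
            if r.overlap.n_shared >= 10:
                assert r.verdict != UNDETERMINED
        groups = propagate_orientation(
            build_graph(recs), {b.key: b for b in bundle.blocks}
        )
        for group in groups:
            assert group.consistent
            anchor_flip = t_flips[group.anchor[1]]
            for t, bit in group.orientations.items():
                assert bit == (t_flips[t[1]] ^ anchor_flip)


class TestExtensionStats:
    def blocks(self):
        variants = (
            [variant(1, 10, 0), variant(1_000_000, 10, 1)]
            + [variant(2_000_000, 20, 0), variant(3_000_000, 20, 1)]
        )
        return {b.key: b for b in build_phase_blocks(variants)}

    def test_joined_blocks_span(self):
        blocks = self.blocks()
        graph = build_graph(
            [rec(("chr1", 10), "R1", 20, 0, NO_SWITCH),
             rec(("chr1", 20), "R1", 20, 20, SWITCH)]
        )
        groups = propagate_orientation(graph, blocks)
        stats = extension_stats(blocks, groups)
        assert set(stats["after_bp"]) == {3_000_000}
        assert stats.attrs["median_after_bp"] >= stats.attrs["median_before_bp"]

    def test_no_extendable_groups_after_equals_before(self):
        blocks = self.blocks()
        graph = build_graph([rec(("chr1", 10), "R1", 20, 0, NO_SWITCH)])
        groups = propagate_orientation(graph, blocks)
        stats = extension_stats(blocks, groups)
        assert (stats["after_bp"] == stats["before_bp"]).all()

    def test_matched_pair_extension_increases_median(self):
        bundle = scenario("matched_pair", seed=4)
        overlaps = find_overlaps(bundle.target_variants, bundle.reference_variants)
        recs = [recommend_switch(o) for o in overlaps]
        blocks = {b.key: b for b in bundle.blocks}
        groups = propagate_orientation(build_graph(recs), blocks)
        stats = extension_stats(blocks, groups)
        assert stats.attrs["fold_change"] >= 1.0
        assert stats["extended"].any()
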