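"""Bridge phase blocks with identity-by-descent (IBD) segments.

An IBD segment is a genomic interval over which two individuals share a
haplotype from a common ancestor.  Within the segment the donor's shared
haplotype carries a definite allele at every position, so wherever the segment
overlaps a phase block of the focal sample those donor alleles should match one
of the block's two haplotypes almost everywhere.  A segment spanning two phase
blocks therefore reveals their relative orientation: if the donor alleles match
H2 in one block and H1 in the other, the blocks are oppositely oriented.

Input IBD segments follow the Refined IBD output dialect (tab-separated:
sample1, hap1, sample2, hap2, chrom, start, end, LOD, cM).  Bridge
recommendations are emitted as parity edges (SAME -> weight 2, OPPOSITE ->
weight 1) compatible with :func:`linkedhap.extend.build_graph`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Optional, Sequence

import pandas as pd

from linkedhap.core import PhaseBlock, PhasedVariant

logger = logging.getLogger(__name__)

SAME = "SAME"
OPPOSITE = "OPPOSITE"


@dataclass(frozen=True)
class IBDSegment:
    """One Refined-IBD segment between two samples' haplotypes."""

    sample1: str
    hap_index1: int
    sample2: str
    hap_index2: int
    chrom: str
    start: int
    end: int
    lod: float = 0.0
    cm_length: float = 0.0

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("IBD segment must have start < end")
        if self.lod < 0 or self.cm_length < 0:
            raise ValueError("LOD and cM length must be >= 0")


@dataclass
class IBDBlockMatch:
    """Haplotype match proportions of one segment x phase-block intersection."""

    segment: IBDSegment
    block: PhaseBlock
    n_informative: int
    n_match_h1: int
    n_match_h2: int
    annotations: dict = None

    @property
    def h1_fraction(self) -> Optional[float]:
        return self.n_match_h1 / self.n_informative if self.n_informative else None

    @property
    def h2_fraction(self) -> Optional[float]:
        return self.n_match_h2 / self.n_informative if self.n_informative else None


def overlap_ibd(
    segments: Sequence[IBDSegment],
    blocks: Sequence[PhaseBlock],
    sample_variants: Sequence[PhasedVariant],
    donor_alleles: Mapping[tuple[str, int], tuple[int, int]],
) -> list[IBDBlockMatch]:
    """Tally donor-allele vs H1/H2 matches per (segment, block) intersection.

    ``donor_alleles`` maps (chrom, pos) to the donor's phased allele pair; the
    allele on the donor's IBD haplotype (``hap_index2``) is compared with the
    sample's H1 and H2 alleles at every phased heterozygous position inside
    the intersection.  Positions where the donor allele matches neither sample
    allele (e.g. a third allele) are not informative.  Segment metadata is
    passed through as annotation of the intersected interval.
    """
    by_block: dict[tuple, list[PhasedVariant]] = {}
    for v in sample_variants:
        if v.phased and v.is_het:
            by_block.setdefault((v.chrom, v.phase_set), []).append(v)

    matches = []
    for seg in segments:
        for block in blocks:
            if block.chrom != seg.chrom:
                continue
            lo = max(block.start, seg.start)
            hi = min(block.end, seg.end)
            if lo > hi:
                continue
            n_h1 = n_h2 = n_inf = 0
            for v in by_block.get((block.chrom, block.phase_set), ()):
                if not (lo <= v.pos <= hi):
                    continue
                pair = donor_alleles.get((v.chrom, v.pos))
                if pair is None:
                    continue
                donor = pair[seg.hap_index2 - 1]
                if donor == v.hap1_allele:
                    n_h1 += 1
                elif donor == v.hap2_allele:
                    n_h2 += 1
                else:
                    continue
                n_inf += 1
            matches.append(
                IBDBlockMatch(
                    segment=seg,
                    block=block,
                    n_informative=n_inf,
                    n_match_h1=n_h1,
                    n_match_h2=n_h2,
                    annotations={
                        "interval": (lo, hi),
                        "donor": seg.sample2,
                        "lod": seg.lod,
                        "cM": seg.cm_length,
                    },
                )
            )
    return matches


@dataclass
class BridgeRecommendation:
    """Relative orientation of two phase blocks inferred through one segment."""

    block_a: PhaseBlock
    block_b: PhaseBlock
    orientation: str  # SAME | OPPOSITE
    segment: IBDSegment

    @property
    def parity_weight(self) -> int:
        """Edge weight for the extend parity graph (1 = switch, 2 = no switch)."""
        return 2 if self.orientation == SAME else 1


def bridge_by_ibd(
    matches: Sequence[IBDBlockMatch],
    min_informative: int = 10,
    majority: float = 0.95,
) -> list[BridgeRecommendation]:
    """Orientation recommendations between block pairs sharing an IBD segment.

    A block qualifies on a segment when one haplotype matches the donor allele
    in at least ``majority`` of at least ``min_informative`` informative
    positions.  Two qualifying blocks on the same segment are SAME-oriented
    when the majorities point to the same haplotype label, OPPOSITE otherwise.
    """
    by_segment: dict[IBDSegment, list[IBDBlockMatch]] = {}
    for m in matches:
        by_segment.setdefault(m.segment, []).append(m)

    def majority_hap(m: IBDBlockMatch) -> Optional[int]:
        if m.n_informative < min_informative:
            return None
        if m.h1_fraction >= majority:
            return 1
        if m.h2_fraction >= majority:
            return 2
        return None

    recs = []
    for seg, seg_matches in by_segment.items():
        qualified = [(m, majority_hap(m)) for m in seg_matches]
        qualified = [(m, h) for m, h in qualified if h is not None]
        for (ma, ha), (mb, hb) in combinations(qualified, 2):
            recs.append(
                BridgeRecommendation(
                    block_a=ma.block,
                    block_b=mb.block,
                    orientation=SAME if ha == hb else OPPOSITE,
                    segment=seg,
                )
            )
    return recs


def matches_table(matches: Sequence[IBDBlockMatch]) -> pd.DataFrame:
    """TSV-ready table of IBD/block match rows."""
    return pd.DataFrame(
        [
            {
                "chrom": m.block.chrom,
                "phase_set": m.block.phase_set,
                "segment_start": m.segment.start,
                "segment_end": m.segment.end,
                "donor": m.segment.sample2,
                "donor_hap": m.segment.hap_index2,
                "lod": m.segment.lod,
                "cM": m.segment.cm_length,
                "n_informative": m.n_informative,
                "h1_fraction": m.h1_fraction,
                "h2_fraction": m.h2_fraction,
            }
            for m in matches
        ],
        columns=[
            "chrom",
            "phase_set",
            "segment_start",
            "segment_end",
            "donor",
            "donor_hap",
            "lod",
            "cM",
            "n_informative",
            "h1_fraction",
            "h2_fraction",
        ],
    )


def bridges_table(recs: Sequence[BridgeRecommendation]) -> pd.DataFrame:
    """TSV-ready bridge table, consumable as extend parity edges."""
    return pd.DataFrame(
        [
            {
                "chrom": r.block_a.chrom,
                "block_a": r.block_a.phase_set,
                "block_b": r.block_b.phase_set,
                "orientation": r.orientation,
                "parity_weight": r.parity_weight,
                "segment_start": r.segment.start,
                "segment_end": r.segment.end,
            }
            for r in recs
        ],
        columns=[
            "chrom",
            "block_a",
            "block_b",
            "orientation",
            "parity_weight",
            "segment_start",
            "segment_end",
        ],
    )
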