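"""Phase-block extension across matched samples via germline-overlap voting.

Samples from the same individual share germline variants, and those variants
must be phased consistently in both samples even when the samples' phase-block
boundaries differ.  For each overlapping (target, reference) block pair the
shared phased heterozygous variants vote "switch" (the target's haplotype
labels must flip to match the reference) or "no switch".  A verdict requires at
least ``min_overlap`` shared variants, a significant two-sided binomial test
against a null switch proportion of 0.5, and a hard cutoff: strictly more than
95% switch votes (SWITCH) or strictly fewer than 5% (NO_SWITCH).

Determined verdicts become edges of a bipartite parity graph (weight 1 =
switch, 2 = no switch).  Two target blocks connected through reference blocks
have the same haplotype orientation iff the sum of edge weights along any
connecting path is even; components where two paths disagree are flagged
inconsistent and produce no orientations (a switch error would propagate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Iterable, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import binomtest

from linkedhap.core import PhaseBlock, PhasedVariant

logger = logging.getLogger(__name__)

SWITCH = "SWITCH"
NO_SWITCH = "NO_SWITCH"
UNDETERMINED = "UNDETERMINED"

BlockId = Hashable  # (chrom, phase_set) in practice


@dataclass
class ExtendConfig:
    """Decision thresholds for switch recommendations.

    The hard cutoffs are strict ("more than 95%", "less than 5%"); the
    binomial test (null proportion ``null_p``, level ``alpha``) guards against
    low-information overlaps.
    """

    min_overlap: int = 10
    hard_cutoff_high: float = 0.95
    hard_cutoff_low: float = 0.05
    null_p: float = 0.5
    alpha: float = 0.05


@dataclass
class BlockOverlap:
    """Shared-variant tally between one target and one reference block."""

    target_block: BlockId
    reference_block: BlockId
    n_shared: int
    n_switch_votes: int

    def __post_init__(self) -> None:
        if not (0 <= self.n_switch_votes <= self.n_shared):
            raise ValueError("switch votes must be between 0 and n_shared")

    @property
    def switch_fraction(self) -> float:
        return self.n_switch_votes / self.n_shared if self.n_shared else float("nan")


@dataclass
class SwitchRecommendation:
    overlap: BlockOverlap
    verdict: str  # SWITCH | NO_SWITCH | UNDETERMINED
    switch_fraction: float
    p_value: Optional[float] = None


@dataclass
class ExtensionGraph:
    """Parity graph over target ("T") and reference ("R") phase-block nodes."""

    graph: nx.Graph
    components: list[set] = field(default_factory=list)
    inconsistent: list[bool] = field(default_factory=list)


def _index_het_phased(variants: Iterable[PhasedVariant]) -> dict:
    index = {}
    seen_pos = set()
    for v in variants:
        if not (v.phased and v.is_het):
            continue
        if (v.chrom, v.pos) in seen_pos and v.key not in index:
            # same position, different alleles: decomposed multiallelic, skip
            continue
        if v.key in index:
            raise ValueError(
                f"duplicated variant {v.key} within one sample (malformed input)"
            )
        index[v.key] = v
        seen_pos.add((v.chrom, v.pos))
    return index


def find_overlaps(
    target_variants: Sequence[PhasedVariant],
    reference_variants: Sequence[PhasedVariant],
) -> list[BlockOverlap]:
    """Shared-variant switch votes for every overlapping block pair.

    Variants are matched across samples on (chrom, pos, ref, alt) and must be
    heterozygous and phased in both.  A shared variant votes "switch" when its
    target hap1 allele differs from its reference hap1 allele.  Duplicated
    variant keys within a sample raise.
    """
    t_index = _index_het_phased(target_variants)
    r_index = _index_het_phased(reference_variants)
    tallies: dict[tuple, list[int]] = {}
    for key, tv in t_index.items():
        rv = r_index.get(key)
        if rv is None:
            continue
        pair = ((tv.chrom, tv.phase_set), (rv.chrom, rv.phase_set))
        tally = tallies.setdefault(pair, [0, 0])
        tally[0] += 1
        if tv.hap1_allele != rv.hap1_allele:
            tally[1] += 1
    return [
        BlockOverlap(
            target_block=t, reference_block=r, n_shared=n, n_switch_votes=k
        )
        for (t, r), (n, k) in sorted(tallies.items(), key=lambda kv: repr(kv[0]))
    ]


def recommend_switch(
    overlap: BlockOverlap, config: Optional[ExtendConfig] = None
) -> SwitchRecommendation:
    """Switch / no-switch / undetermined verdict for one block overlap."""
    config = config or ExtendConfig()
    if overlap.n_shared < config.min_overlap:
        return SwitchRecommendation(
            overlap=overlap,
            verdict=UNDETERMINED,
            switch_fraction=overlap.switch_fraction,
        )
    test = binomtest(
        overlap.n_switch_votes, overlap.n_shared, config.null_p, alternative="two-sided"
    )
    frac = overlap.switch_fraction
    verdict = UNDETERMINED
    if test.pvalue < config.alpha:
        if frac > config.hard_cutoff_high:
            verdict = SWITCH
        elif frac < config.hard_cutoff_low:
            verdict = NO_SWITCH
    return SwitchRecommendation(
        overlap=overlap, verdict=verdict, switch_fraction=frac, p_value=test.pvalue
    )


def build_graph(
    recommendations: Sequence[SwitchRecommendation],
    extra_edges: Sequence[tuple[BlockId, BlockId, int]] = (),
) -> ExtensionGraph:
    """Parity graph from determined recommendations.

    Nodes are ("T", block) and ("R", block); edge weight 1 means switch,
    2 means no switch.  ``extra_edges`` add direct target-target parity edges
    (e.g. from IBD bridging) as (block_a, block_b, weight) triples.
    UNDETERMINED recommendations are ignored.  Per-component parity
    consistency is checked over all cycles.
    """
    g = nx.Graph()
    for rec in recommendations:
        if rec.verdict == UNDETERMINED:
            continue
        weight = 1 if rec.verdict == SWITCH else 2
        g.add_edge(
            ("T", rec.overlap.target_block),
            ("R", rec.overlap.reference_block),
            weight=weight,
        )
    for a, b, w in extra_edges:
        if w not in (1, 2):
            raise ValueError("parity edge weight must be 1 or 2")
        g.add_edge(("T", a), ("T", b), weight=w)

    components = [set(c) for c in nx.connected_components(g)]
    inconsistent = []
    for comp in components:
        parity = _component_parity(g, comp)
        inconsistent.append(parity is None)
    return ExtensionGraph(graph=g, components=components, inconsistent=inconsistent)


def _component_parity(g: nx.Graph, comp: set) -> Optional[dict]:
    """BFS parity labelling of one component; None if a cycle contradicts."""
    start = next(iter(sorted(comp, key=repr)))
    parity = {start: 0}
    queue = [start]
    while queue:
        node = queue.pop()
        for nbr in g.neighbors(node):
            p = (parity[node] + g.edges[node, nbr]["weight"]) % 2
            if nbr in parity:
                if parity[nbr] != p:
                    return None
            else:
                parity[nbr] = p
                queue.append(nbr)
    return parity


@dataclass
class OrientationGroup:
    """Connected target blocks with orientation bits relative to an anchor."""

    group_id: int
    target_blocks: list[BlockId]
    orientations: Optional[dict[BlockId, int]]  # None when inconsistent
    consistent: bool
    anchor: Optional[BlockId] = None


def propagate_orientation(
    graph: ExtensionGraph,
    target_blocks: Optional[Mapping[BlockId, PhaseBlock]] = None,
) -> list[OrientationGroup]:
    """Relative orientations of target blocks per connected component.

    The orientation bit of a target block is the parity of any path to the
    component's anchor (0 = same orientation, 1 = must be switched).  The
    anchor is the member target block with the lowest genomic coordinate when
    block objects are supplied, otherwise the lowest block id.  Inconsistent
    components are reported with ``orientations=None``.
    """
    groups = []
    for gid, (comp, bad) in enumerate(zip(graph.components, graph.inconsistent)):
        targets = sorted((n[1] for n in comp if n[0] == "T"), key=repr)
        if not targets:
            continue
        if bad:
            groups.append(
                OrientationGroup(
                    group_id=gid,
                    target_blocks=targets,
                    orientations=None,
                    consistent=False,
                )
            )
            continue
        if target_blocks:
            def coord(t):
                b = target_blocks.get(t)
                return (b.chrom, b.start) if b is not None else (repr(t), 0)
            anchor = min(targets, key=coord)
        else:
            anchor = min(targets, key=repr)
        parity = _component_parity(graph.graph, comp)
        base = parity[("T", anchor)]
        orientations = {t: (parity[("T", t)] - base) % 2 for t in targets}
        groups.append(
            OrientationGroup(
                group_id=gid,
                target_blocks=targets,
                orientations=orientations,
                consistent=True,
                anchor=anchor,
            )
        )
    return groups


def extension_stats(
    blocks: Mapping[BlockId, PhaseBlock],
    groups: Sequence[OrientationGroup],
) -> pd.DataFrame:
    """Before/after length table for extendable groups.

    The "after" length of a consistent group is the span from the minimum
    start to the maximum end of its member target blocks; each member's
    "before" length is its own span.  Singleton or inconsistent groups leave
    lengths unchanged.  The returned frame has one row per target block with
    group id, before/after lengths; medians and fold change are in ``attrs``.
    """
    rows = []
    for grp in groups:
        members = [blocks[t] for t in grp.target_blocks if t in blocks]
        if not members:
            continue
        if grp.consistent and len(members) > 1:
            span = max(b.end for b in members) - min(b.start for b in members) + 1
        else:
            span = None
        for b in members:
            rows.append(
                {
                    "group_id": grp.group_id,
                    "chrom": b.chrom,
                    "phase_set": b.phase_set,
                    "before_bp": b.length,
                    "after_bp": span if span is not None else b.length,
                    "extended": span is not None,
                }
            )
    df = pd.DataFrame(
        rows,
        columns=["group_id", "chrom", "phase_set", "before_bp", "after_bp", "extended"],
    )
    if len(df):
        before_med = float(np.median(df["before_bp"]))
        after_med = float(np.median(df["after_bp"]))
        df.attrs["median_before_bp"] = before_med
        df.attrs["median_after_bp"] = after_med
        df.attrs["fold_change"] = after_med / before_med if before_med else float("nan")
    return df


def recommendations_table(recs: Sequence[SwitchRecommendation]) -> pd.DataFrame:
    """TSV-ready table of switch recommendations."""
    return pd.DataFrame(
        [
            {
                "target_block": repr(r.overlap.target_block),
                "reference_block": repr(r.overlap.reference_block),
                "n_shared": r.overlap.n_shared,
                "n_switch_votes": r.overlap.n_switch_votes,
                "switch_fraction": r.switch_fraction,
                "p_value": r.p_value,
                "verdict": r.verdict,
            }
            for r in recs
        ],
        columns=[
            "target_block",
            "reference_block",
            "n_shared",
            "n_switch_votes",
            "switch_fraction",
            "p_value",
            "verdict",
        ],
    )
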