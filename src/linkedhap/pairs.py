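"""Clonal-evolution patterns from pairs of somatic mutations sharing barcodes.

Two somatic mutations closer together than a typical HMW molecule (~62 kb) can
appear on the same barcode, so the joint alleles observed per shared barcode —
the allele-pair classes REF-REF, REF-ALT, ALT-REF and ALT-ALT — carry
single-molecule (hence single-cell, single-haplotype) information.  The
presence pattern of the four classes, written as a 4-bit string in that order,
is interpreted under a parsimony model (a given mutation arises only once):

* ALT-REF together with ALT-ALT but no REF-ALT (``1011``/``0011``) means the
  first mutation preceded the second (a nested subclone);
* REF-ALT and ALT-REF without ALT-ALT (``1110``/``0110``), when both mutations
  are phased to the same haplotype in a copy-number-neutral region, means the
  mutations arose independently in sibling subclones;
* only REF-REF and/or ALT-ALT (``1001``/``0001``) shows co-occurrence without
  ordering information.

The module also maps structural variants to haplotypes from barcodes whose
reads flank both breakpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from linkedhap.somatic import (
    H1,
    H2,
    PhasingCall,
    SomaticMutation,
    barcode_consensus_alleles,
    _site_rows,
)

logger = logging.getLogger(__name__)

PATTERN_CLASSES = ("REF-REF", "REF-ALT", "ALT-REF", "ALT-ALT")

UNINFORMATIVE = "uninformative"
SINGLE_MUTANT_ONLY = "single_mutant_only"
INDEPENDENT_SUBCLONES = "independent_subclones"
SEQUENTIAL_A_FIRST = "sequential_a_first"
SEQUENTIAL_B_FIRST = "sequential_b_first"
CO_OCCURRING_ONLY = "co_occurring_only"
MIXED = "mixed"


@dataclass(frozen=True)
class CNVSegment:
    """Copy-number segment, 1-based inclusive, with a read-depth log2 ratio."""

    chrom: str
    start: int
    end: int
    log2_ratio: float

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("CNV segment start > end")

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end


@dataclass
class PairAnalysisConfig:
    """Eligibility filters for the pairwise barcode-sharing analysis.

    Pairs are kept when both sites lie in a copy-number-neutral segment
    (log2 ratio inside ``cn_neutral_interval``, inclusive at both ends), each
    site has between ``min_phased_barcodes`` and ``max_phased_barcodes``
    haplotype-informative barcodes plus at least ``min_alt_barcodes`` ALT
    barcode, and the sites are at most ``max_pair_distance`` apart
    (inclusive); ``near_pair_distance`` marks the "read-pair scale" bound
    (strictly less than).
    """

    max_pair_distance: int = 62_000
    near_pair_distance: int = 100
    min_phased_barcodes: int = 10
    max_phased_barcodes: int = 100
    min_alt_barcodes: int = 1
    cn_neutral_interval: tuple[float, float] = (-0.25, 0.2)


@dataclass
class PairPatternCounts:
    """Shared-barcode allele-pair tally for one mutation pair."""

    site_a: SomaticMutation
    site_b: SomaticMutation
    n_shared_barcodes: int = 0
    n_conflicting_barcodes: int = 0
    counts: dict[str, int] = field(
        default_factory=lambda: {c: 0 for c in PATTERN_CLASSES}
    )
    call_a: Optional[PhasingCall] = None
    call_b: Optional[PhasingCall] = None

    @property
    def distance(self) -> int:
        return abs(self.site_b.pos - self.site_a.pos)

    def swapped(self) -> "PairPatternCounts":
        """The same tally with site_a and site_b exchanged."""
        return PairPatternCounts(
            site_a=self.site_b,
            site_b=self.site_a,
            n_shared_barcodes=self.n_shared_barcodes,
            n_conflicting_barcodes=self.n_conflicting_barcodes,
            counts={
                "REF-REF": self.counts["REF-REF"],
                "REF-ALT": self.counts["ALT-REF"],
                "ALT-REF": self.counts["REF-ALT"],
                "ALT-ALT": self.counts["ALT-ALT"],
            },
            call_a=self.call_b,
            call_b=self.call_a,
        )


@dataclass
class PairPattern:
    """4-bit presence string over (REF-REF, REF-ALT, ALT-REF, ALT-ALT)."""

    bits: str
    interpretation: Optional[str] = None

    def __post_init__(self) -> None:
        if len(self.bits) != 4 or set(self.bits) - {"0", "1"}:
            raise ValueError("pattern must be a 4-character bit string")


@dataclass(frozen=True)
class SVCall:
    """A structural variant given by its two breakpoints."""

    chrom1: str
    pos1: int
    chrom2: str
    pos2: int
    sv_type: str = "BND"


@dataclass
class SVHaplotypeResult:
    sv: SVCall
    verdict: str  # H1 | H2 | unsupported | inconsistent | untagged
    n_supporting_barcodes: int
    n_reads_h1: int = 0
    n_reads_h2: int = 0


# ---------------------------------------------------------------------------
# site-level coverage


def site_barcode_stats(
    observations: pd.DataFrame, chrom: str, pos: int
) -> tuple[int, int]:
    """(phased-barcode coverage, ALT barcode count) at one position.

    A phased barcode has at least one haplotype-tagged read at the position;
    an ALT barcode has consensus allele 1 there.
    """
    rows = _site_rows(observations, chrom, pos)
    if rows.empty:
        return 0, 0
    tagged = rows[rows["hap"].isin((1, 2))]
    n_phased = tagged["barcode"].nunique()
    consensus = barcode_consensus_alleles(rows)
    n_alt = int((consensus == 1).sum())
    return n_phased, n_alt


def filter_pairs(
    mutations: Sequence[SomaticMutation],
    cnv: Sequence[CNVSegment],
    observations: pd.DataFrame,
    config: Optional[PairAnalysisConfig] = None,
) -> list[tuple[SomaticMutation, SomaticMutation]]:
    """Same-chromosome mutation pairs eligible for barcode-sharing analysis.

    Both sites must lie in a copy-number-neutral segment, have phased-barcode
    coverage within the configured band and at least one ALT barcode, and be
    within ``max_pair_distance`` of each other.  A site covered by no CNV
    segment is excluded (logged).
    """
    config = config or PairAnalysisConfig()
    lo, hi = config.cn_neutral_interval

    def neutral(m: SomaticMutation) -> bool:
        seg = next((s for s in cnv if s.contains(m.chrom, m.pos)), None)
        if seg is None:
            logger.info("%s:%d not covered by any CNV segment; excluded", m.chrom, m.pos)
            return False
        return lo <= seg.log2_ratio <= hi

    eligible_sites = []
    for m in mutations:
        if not neutral(m):
            continue
        n_phased, n_alt = site_barcode_stats(observations, m.chrom, m.pos)
        if not (config.min_phased_barcodes <= n_phased <= config.max_phased_barcodes):
            continue
        if n_alt < config.min_alt_barcodes:
            continue
        eligible_sites.append(m)

    pairs = []
    for a, b in combinations(eligible_sites, 2):
        if a.chrom != b.chrom:
            continue
        if abs(b.pos - a.pos) > config.max_pair_distance:
            continue
        pairs.append((a, b) if a.pos <= b.pos else (b, a))
    return pairs


def shared_barcode_table(
    pair: tuple[SomaticMutation, SomaticMutation],
    observations: pd.DataFrame,
) -> PairPatternCounts:
    """Allele-pair class counts over barcodes with reads at both sites.

    Each shared barcode contributes one class from its consensus allele at
    each site; a barcode with internally conflicting reads at either site is
    dropped from the table and counted separately.
    """
    a, b = pair
    rows_a = _site_rows(observations, a.chrom, a.pos)
    rows_b = _site_rows(observations, b.chrom, b.pos)
    bcs_a = set(rows_a["barcode"])
    bcs_b = set(rows_b["barcode"])
    shared = bcs_a & bcs_b
    out = PairPatternCounts(site_a=a, site_b=b, n_shared_barcodes=len(shared))
    if not shared:
        return out
    cons_a = barcode_consensus_alleles(rows_a[rows_a["barcode"].isin(shared)])
    cons_b = barcode_consensus_alleles(rows_b[rows_b["barcode"].isin(shared)])
    for bc in sorted(shared):
        if bc not in cons_a.index or bc not in cons_b.index:
            out.n_conflicting_barcodes += 1
            continue
        cls = PATTERN_CLASSES[2 * int(cons_a[bc]) + int(cons_b[bc])]
        out.counts[cls] += 1
    return out


def encode_pattern(counts: PairPatternCounts) -> PairPattern:
    """Presence string: bit i is 1 iff class i was observed on >= 1 barcode."""
    bits = "".join("1" if counts.counts[c] > 0 else "0" for c in PATTERN_CLASSES)
    return PairPattern(bits=bits)


def classify_pair(
    pattern: PairPattern,
    calls: tuple[Optional[PhasingCall], Optional[PhasingCall]] = (None, None),
    cn_neutral: bool = True,
) -> str:
    """Interpret a presence pattern as a clonal-evolution model.

    Under parsimony (each mutation arises once): ALT-REF with ALT-ALT and no
    REF-ALT means site A mutated first; the mirror image means B first;
    REF-ALT and ALT-REF without ALT-ALT, with both ALTs phased to the same
    haplotype in a copy-number-neutral context, means independent sibling
    subclones (otherwise the pattern is uninformative about the model); both
    single-ALT classes together with ALT-ALT is a mixed signal.
    """
    rr, ra, ar, aa = (bit == "1" for bit in pattern.bits)
    if ra and ar and aa:
        interp = MIXED
    elif ar and aa:
        interp = SEQUENTIAL_A_FIRST
    elif ra and aa:
        interp = SEQUENTIAL_B_FIRST
    elif ra and ar:
        call_a, call_b = calls
        same_hap = (
            call_a is not None
            and call_b is not None
            and call_a.verdict in (H1, H2)
            and call_a.verdict == call_b.verdict
        )
        interp = INDEPENDENT_SUBCLONES if (same_hap and cn_neutral) else UNINFORMATIVE
    elif aa:
        interp = CO_OCCURRING_ONLY
    elif ra or ar:
        interp = SINGLE_MUTANT_ONLY
    else:
        interp = UNINFORMATIVE
    pattern.interpretation = interp
    return interp


def pair_distance_profile(
    pairs: Sequence[tuple[SomaticMutation, SomaticMutation]],
    observations: pd.DataFrame,
    bin_edges: Sequence[int] = (0, 100, 62_000, 124_000, 248_000),
) -> pd.DataFrame:
    """Distance vs shared-barcode count per pair, with a binned summary.

    Returns one row per pair (distance, n_shared_barcodes, distance_bin); the
    probability of sharing decays with distance on the scale of the molecule
    length.  A pair at distance 0 (the same site twice) is an error.
    """
    rows = []
    for a, b in pairs:
        if a.chrom == b.chrom and a.pos == b.pos:
            raise ValueError("pair at distance 0: a pair must be two distinct sites")
        counts = shared_barcode_table((a, b), observations)
        rows.append(
            {
                "chrom": a.chrom,
                "pos_a": a.pos,
                "pos_b": b.pos,
                "distance": counts.distance,
                "n_shared_barcodes": counts.n_shared_barcodes,
            }
        )
    df = pd.DataFrame(
        rows, columns=["chrom", "pos_a", "pos_b", "distance", "n_shared_barcodes"]
    )
    if len(df):
        df["distance_bin"] = pd.cut(
            df["distance"], bins=list(bin_edges) + [np.inf], right=True
        )
    return df


# ---------------------------------------------------------------------------
# SV haplotype mapping


def map_sv_haplotype(
    sv: SVCall,
    observations: pd.DataFrame,
    min_support: int = 2,
    window: int = 100_000,
) -> SVHaplotypeResult:
    """Map a structural variant to a haplotype from flanking barcode evidence.

    Supporting barcodes have reads within ``window`` bp of both breakpoints.
    Fewer than ``min_support`` supporting barcodes is ``unsupported``; when
    all haplotype tags on supporting barcodes' flanking reads agree the common
    haplotype is returned; disagreement is flagged ``inconsistent``; tags
    absent entirely gives ``untagged``.  Intrachromosomal breakpoints closer
    than the window size raise (the windows would overlap).
    """
    if sv.chrom1 == sv.chrom2 and abs(sv.pos2 - sv.pos1) < window:
        raise ValueError("breakpoint windows overlap; reduce window or check SV")

    def window_rows(chrom: str, pos: int) -> pd.DataFrame:
        mask = (
            (observations["chrom"] == chrom)
            & (observations["pos"] >= pos - window)
            & (observations["pos"] <= pos + window)
        )
        return observations.loc[mask]

    rows1 = window_rows(sv.chrom1, sv.pos1)
    rows2 = window_rows(sv.chrom2, sv.pos2)
    supporting = set(rows1["barcode"]) & set(rows2["barcode"])
    if len(supporting) < min_support:
        return SVHaplotypeResult(
            sv=sv, verdict="unsupported", n_supporting_barcodes=len(supporting)
        )
    flank = pd.concat([rows1, rows2])
    flank = flank[flank["barcode"].isin(supporting)]
    n_h1 = int((flank["hap"] == 1).sum())
    n_h2 = int((flank["hap"] == 2).sum())
    if n_h1 and n_h2:
        verdict = "inconsistent"
    elif n_h1 or n_h2:
        verdict = H1 if n_h1 else H2
    else:
        verdict = "untagged"
    return SVHaplotypeResult(
        sv=sv,
        verdict=verdict,
        n_supporting_barcodes=len(supporting),
        n_reads_h1=n_h1,
        n_reads_h2=n_h2,
    )


def pair_report(
    pairs: Sequence[tuple[SomaticMutation, SomaticMutation]],
    observations: pd.DataFrame,
    calls_by_site: Optional[dict[tuple[str, int], PhasingCall]] = None,
    cnv: Sequence[CNVSegment] = (),
    config: Optional[PairAnalysisConfig] = None,
) -> pd.DataFrame:
    """Full per-pair report: counts, pattern, interpretation, per-site verdicts."""
    config = config or PairAnalysisConfig()
    lo, hi = config.cn_neutral_interval
    calls_by_site = calls_by_site or {}
    rows = []
    for a, b in pairs:
        counts = shared_barcode_table((a, b), observations)
        counts.call_a = calls_by_site.get(a.key)
        counts.call_b = calls_by_site.get(b.key)
        pattern = encode_pattern(counts)
        neutral = all(
            any(s.contains(m.chrom, m.pos) and lo <= s.log2_ratio <= hi for s in cnv)
            for m in (a, b)
        ) if cnv else True
        interp = classify_pair(pattern, (counts.call_a, counts.call_b), neutral)
        rows.append(
            {
                "chrom": a.chrom,
                "pos_a": a.pos,
                "pos_b": b.pos,
                "distance": counts.distance,
                "n_shared_barcodes": counts.n_shared_barcodes,
                "n_conflicting_barcodes": counts.n_conflicting_barcodes,
                "ref_ref": counts.counts["REF-REF"],
                "ref_alt": counts.counts["REF-ALT"],
                "alt_ref": counts.counts["ALT-REF"],
                "alt_alt": counts.counts["ALT-ALT"],
                "pattern": pattern.bits,
                "interpretation": interp,
                "verdict_a": counts.call_a.verdict if counts.call_a else "NA",
                "verdict_b": counts.call_b.verdict if counts.call_b else "NA",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos_a",
            "pos_b",
            "distance",
            "n_shared_barcodes",
            "n_conflicting_barcodes",
            "ref_ref",
            "ref_alt",
            "alt_ref",
            "alt_alt",
            "pattern",
            "interpretation",
            "verdict_a",
            "verdict_b",
        ],
    )
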