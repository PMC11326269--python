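"""Assign somatic mutations to haplotypes from linked-read barcode evidence.

Two complementary rules are implemented:

* **linked alleles** — every phased heterozygous germline allele observed on a
  barcode that supports the mutant (ALT) allele at the somatic site votes for
  the haplotype carrying that allele; the site is assigned to a haplotype when
  at least ``min_linked_alleles_alt`` votes exist and at least
  ``linked_allele_threshold`` (default 91%) of them agree.
* **barcodes** — the haplotype tags of reads supporting the ALT allele must be
  in *complete* agreement; a single discordant tagged read leaves the site
  unphased.

Verdicts are ``H1``/``H2`` (assigned), ``NP`` (covered but not phased) and
``NC`` (not enough coverage).  Combining the two rules increases power when one
lacks coverage; a conflict between them yields ``NP`` with a discordant flag.

Barcode evidence is a table with one row per (read, site) observation, columns
``barcode, chrom, pos, allele, hap, phase_set`` where ``allele`` is 0 (ref) or
1 (alt), ``hap`` is 1, 2 or 0 (read not haplotype-tagged) and ``phase_set`` may
be -1 when unknown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Optional, Sequence

import pandas as pd

from linkedhap.core import PhaseBlock, PhasedVariant

logger = logging.getLogger(__name__)

#: canonical column order of the barcode-evidence table
OBS_COLUMNS = ["barcode", "chrom", "pos", "allele", "hap", "phase_set"]

H1 = "H1"
H2 = "H2"
NP = "NP"  # not phased
NC = "NC"  # not enough coverage


@dataclass(frozen=True)
class SomaticMutation:
    """A somatic SNV given by chrom, 1-based position, ref and alt base."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    gene: Optional[str] = None

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass
class SomaticPhasingConfig:
    """Thresholds of the two phasing rules.

    ``linked_allele_threshold`` is inclusive ("at least 91%"); the coverage
    minimum requires at least ``min_linked_alleles_alt`` phased linked-allele
    votes on ALT-supporting barcodes, or for the barcodes rule at least
    ``min_phased_alt_reads`` haplotype-tagged ALT reads.
    """

    linked_allele_threshold: float = 0.91
    min_linked_alleles_alt: int = 10
    min_phased_alt_reads: int = 1

    def __post_init__(self) -> None:
        if not (0.5 < self.linked_allele_threshold <= 1.0):
            raise ValueError("linked_allele_threshold must be in (0.5, 1]")
        if self.min_linked_alleles_alt < 0 or self.min_phased_alt_reads < 0:
            raise ValueError("coverage minima must be >= 0")


@dataclass
class LinkedAlleleProfile:
    """Tally of phased linked-allele votes around one somatic site.

    Votes are counted once per (barcode, germline site) on the ALT-supporting
    and REF-supporting barcode sides separately; the REF side is recorded for
    QC only and does not drive the verdict.
    """

    site: SomaticMutation
    alt_votes_h1: int = 0
    alt_votes_h2: int = 0
    ref_votes_h1: int = 0
    ref_votes_h2: int = 0
    n_alt_barcodes: int = 0
    n_ref_barcodes: int = 0
    alt_reads_h1: int = 0
    alt_reads_h2: int = 0
    alt_reads_untagged: int = 0
    phase_set: Optional[int] = None
    covered: bool = True

    @property
    def n_linked_alleles_alt(self) -> int:
        return self.alt_votes_h1 + self.alt_votes_h2

    @property
    def h1_fraction(self) -> Optional[float]:
        tot = self.n_linked_alleles_alt
        return self.alt_votes_h1 / tot if tot else None


@dataclass
class PhasingCall:
    """Haplotype decision for one somatic mutation."""

    site: SomaticMutation
    verdict: str  # H1 | H2 | NP | NC
    method: str  # linked_alleles | barcodes | combined
    h1_fraction: Optional[float] = None
    alt_votes_h1: int = 0
    alt_votes_h2: int = 0
    alt_reads_h1: int = 0
    alt_reads_h2: int = 0
    phase_set: Optional[int] = None
    discordant: bool = False

    @property
    def is_phased(self) -> bool:
        return self.verdict in (H1, H2)


# ---------------------------------------------------------------------------
# helpers on the observation table

_VOTE_EPS = 1e-9  # guards float comparison at the inclusive threshold


def _site_rows(observations: pd.DataFrame, chrom: str, pos: int) -> pd.DataFrame:
    mask = (observations["chrom"].to_numpy() == chrom) & (
        observations["pos"].to_numpy() == pos
    )
    return observations.loc[mask]


def barcode_consensus_alleles(rows: pd.DataFrame) -> pd.Series:
    """Majority allele per barcode at one site; tied barcodes are dropped.

    A barcode whose reads disagree evenly on the allele is most likely chimeric
    and contributes no evidence.
    """
    if rows.empty:
        return pd.Series(dtype=int)
    means = rows.groupby("barcode", sort=True)["allele"].mean()
    consensus = means[(means > 0.5) | (means < 0.5)]
    return (consensus > 0.5).astype(int)


def collect_linked_alleles(
    site: SomaticMutation,
    observations: pd.DataFrame,
    variants: Iterable[PhasedVariant],
    config: Optional[SomaticPhasingConfig] = None,
) -> LinkedAlleleProfile:
    """Tabulate phased linked-allele votes for one somatic site.

    For every barcode carrying the ALT (resp. REF) consensus allele at the
    site, every phased heterozygous germline allele observed on that barcode
    contributes one H1 or H2 vote, according to which haplotype carries the
    observed allele.  Each (barcode, germline site) pair votes at most once;
    reads of a barcode over the same germline site are collapsed to their
    consensus allele first.  A site with no observations returns an
    NC-flagged empty profile (``covered=False``).
    """
    hap_alleles: dict[tuple[str, int], tuple[int, int]] = {}
    for v in variants:
        if v.phased and v.is_het:
            hap_alleles[(v.chrom, v.pos)] = (v.hap1_allele, v.hap2_allele)

    site_rows = _site_rows(observations, site.chrom, site.pos)
    if site_rows.empty:
        return LinkedAlleleProfile(site=site, covered=False)

    consensus = barcode_consensus_alleles(site_rows)
    alt_barcodes = set(consensus[consensus == 1].index)
    ref_barcodes = set(consensus[consensus == 0].index)

    ps_vals = site_rows["phase_set"].to_numpy()
    ps_vals = ps_vals[ps_vals >= 0]
    phase_set = int(ps_vals[0]) if ps_vals.size else None

    tagged = site_rows[site_rows["allele"] == 1]
    alt_reads_h1 = int((tagged["hap"] == 1).sum())
    alt_reads_h2 = int((tagged["hap"] == 2).sum())
    alt_reads_untagged = int((tagged["hap"] == 0).sum())

    profile = LinkedAlleleProfile(
        site=site,
        n_alt_barcodes=len(alt_barcodes),
        n_ref_barcodes=len(ref_barcodes),
        alt_reads_h1=alt_reads_h1,
        alt_reads_h2=alt_reads_h2,
        alt_reads_untagged=alt_reads_untagged,
        phase_set=phase_set,
    )

    barcodes_of_interest = alt_barcodes | ref_barcodes
    if not barcodes_of_interest:
        return profile

    germ = observations[
        observations["barcode"].isin(barcodes_of_interest)
        & ~(
            (observations["chrom"] == site.chrom)
            & (observations["pos"] == site.pos)
        )
    ]
    if germ.empty:
        return profile

    # one consensus allele per (barcode, germline site)
    grouped = germ.groupby(["barcode", "chrom", "pos"], sort=False)["allele"].mean()
    for (bc, chrom, pos), mean_allele in grouped.items():
        haps = hap_alleles.get((chrom, pos))
        if haps is None or mean_allele == 0.5:
            continue
        allele = int(mean_allele > 0.5)
        if allele == haps[0]:
            vote = 1
        elif allele == haps[1]:
            vote = 2
        else:
            continue
        if bc in alt_barcodes:
            if vote == 1:
                profile.alt_votes_h1 += 1
            else:
                profile.alt_votes_h2 += 1
        else:
            if vote == 1:
                profile.ref_votes_h1 += 1
            else:
                profile.ref_votes_h2 += 1
    return profile


def phase_by_linked_alleles(
    profile: LinkedAlleleProfile,
    config: Optional[SomaticPhasingConfig] = None,
) -> PhasingCall:
    """Linked-allele majority rule.

    NC when fewer than ``min_linked_alleles_alt`` phased linked-allele votes
    exist on the ALT side; a haplotype when the majority fraction is at least
    ``linked_allele_threshold``; NP otherwise.
    """
    config = config or SomaticPhasingConfig()
    total = profile.n_linked_alleles_alt
    call = PhasingCall(
        site=profile.site,
        verdict=NC,
        method="linked_alleles",
        alt_votes_h1=profile.alt_votes_h1,
        alt_votes_h2=profile.alt_votes_h2,
        alt_reads_h1=profile.alt_reads_h1,
        alt_reads_h2=profile.alt_reads_h2,
        phase_set=profile.phase_set,
    )
    if not profile.covered or total < config.min_linked_alleles_alt:
        return call
    frac_h1 = profile.alt_votes_h1 / total
    call.h1_fraction = frac_h1
    majority = max(frac_h1, 1.0 - frac_h1)
    if majority + _VOTE_EPS >= config.linked_allele_threshold:
        call.verdict = H1 if frac_h1 >= 0.5 else H2
    else:
        call.verdict = NP
    return call


def phase_by_barcodes(
    site: SomaticMutation,
    observations: pd.DataFrame,
    config: Optional[SomaticPhasingConfig] = None,
) -> PhasingCall:
    """Complete-agreement rule over haplotype tags of ALT-supporting reads.

    NC when no ALT read carries a haplotype tag (or fewer than
    ``min_phased_alt_reads``); the common haplotype when all tagged ALT reads
    agree; NP when they disagree.
    """
    config = config or SomaticPhasingConfig()
    rows = _site_rows(observations, site.chrom, site.pos)
    alt = rows[rows["allele"] == 1]
    n_h1 = int((alt["hap"] == 1).sum())
    n_h2 = int((alt["hap"] == 2).sum())
    ps_vals = rows["phase_set"].to_numpy()
    ps_vals = ps_vals[ps_vals >= 0]
    call = PhasingCall(
        site=site,
        verdict=NC,
        method="barcodes",
        alt_reads_h1=n_h1,
        alt_reads_h2=n_h2,
        phase_set=int(ps_vals[0]) if ps_vals.size else None,
    )
    if n_h1 + n_h2 < max(config.min_phased_alt_reads, 1):
        return call
    if n_h1 and n_h2:
        call.verdict = NP
    else:
        call.verdict = H1 if n_h1 else H2
    return call


def combine_calls(la: PhasingCall, bc: PhasingCall) -> PhasingCall:
    """Merge the two rules' verdicts for one site.

    Exactly one phased verdict is adopted; two equal phased verdicts agree;
    two unequal phased verdicts give NP with the discordant flag set (the
    conservative conflict rule); otherwise the less-null of {NP, NC}.
    """
    if la.site != bc.site:
        raise ValueError("calls refer to different sites")
    combined = PhasingCall(
        site=la.site,
        verdict=NC,
        method="combined",
        h1_fraction=la.h1_fraction,
        alt_votes_h1=la.alt_votes_h1,
        alt_votes_h2=la.alt_votes_h2,
        alt_reads_h1=bc.alt_reads_h1,
        alt_reads_h2=bc.alt_reads_h2,
        phase_set=la.phase_set if la.phase_set is not None else bc.phase_set,
    )
    if la.is_phased and bc.is_phased:
        if la.verdict == bc.verdict:
            combined.verdict = la.verdict
        else:
            combined.verdict = NP
            combined.discordant = True
    elif la.is_phased:
        combined.verdict = la.verdict
    elif bc.is_phased:
        combined.verdict = bc.verdict
    else:
        combined.verdict = NP if NP in (la.verdict, bc.verdict) else NC
    return combined


def phase_somatic_mutations(
    mutations: Sequence[SomaticMutation],
    observations: pd.DataFrame,
    variants: Sequence[PhasedVariant],
    config: Optional[SomaticPhasingConfig] = None,
) -> list[PhasingCall]:
    """Run both rules on every mutation and combine them."""
    config = config or SomaticPhasingConfig()
    calls = []
    for site in mutations:
        profile = collect_linked_alleles(site, observations, variants, config)
        la = phase_by_linked_alleles(profile, config)
        bc = phase_by_barcodes(site, observations, config)
        calls.append(combine_calls(la, bc))
    return calls


def summarize_somatic_by_phase_block(
    calls: Sequence[PhasingCall],
    blocks: Sequence[PhaseBlock],
) -> pd.DataFrame:
    """Per-block mutation counts, phased density per Mb and pair counts.

    A call is assigned to a block by matching phase set when the call carries
    one, otherwise by position within the block range.  Mutations falling
    outside every block are counted in an ``unassigned`` row.  The number of
    mutation pairs per block is C(n_phased, 2).
    """
    by_key = {b.key: b for b in blocks}
    assigned: dict[tuple[str, object], list[PhasingCall]] = {b.key: [] for b in blocks}
    unassigned: list[PhasingCall] = []
    for call in calls:
        key = None
        if call.phase_set is not None and (call.site.chrom, call.phase_set) in by_key:
            key = (call.site.chrom, call.phase_set)
        else:
            for b in blocks:
                if b.chrom == call.site.chrom and b.start <= call.site.pos <= b.end:
                    key = b.key
                    break
        if key is None:
            unassigned.append(call)
        else:
            assigned[key].append(call)

    rows = []
    for b in blocks:
        members = assigned[b.key]
        n_phased = sum(c.is_phased for c in members)
        rows.append(
            {
                "chrom": b.chrom,
                "phase_set": b.phase_set,
                "length_bp": b.length,
                "n_mutations": len(members),
                "n_phased": n_phased,
                "phased_per_mb": n_phased / (b.length / 1e6),
                "n_mutation_pairs": comb(n_phased, 2),
            }
        )
    if unassigned:
        n_phased = sum(c.is_phased for c in unassigned)
        rows.append(
            {
                "chrom": "unassigned",
                "phase_set": -1,
                "length_bp": 0,
                "n_mutations": len(unassigned),
                "n_phased": n_phased,
                "phased_per_mb": float("nan"),
                "n_mutation_pairs": comb(n_phased, 2),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "phase_set",
            "length_bp",
            "n_mutations",
            "n_phased",
            "phased_per_mb",
            "n_mutation_pairs",
        ],
    )
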