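"""Phase-block data model, phased-VCF reading, and summary statistics.

A *phase block* is a genomic range within which the haplotype assignments of
phased variants are mutually consistent; the H1/H2 labels are arbitrary per
block and cannot be compared between blocks.  Blocks are identified in a phased
VCF by the per-variant phase-set (``PS``) annotation.  The Long Ranger
convention (PS = position of the block's first variant) is accepted but not
required: any consistent per-sample identifier defines a block.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Phase-set value meaning "not phased".
UNPHASED = None


@dataclass(frozen=True)
class PhasedVariant:
    """A small variant with genotype, phase-set membership and per-haplotype alleles.

    Coordinates are 1-based inclusive (VCF convention).  ``hap1_allele`` /
    ``hap2_allele`` are allele indices (0 = ref, >=1 = alt) and are defined only
    when ``phased`` is True.  For phased heterozygous variants
    ``{hap1_allele, hap2_allele}`` is a permutation of the genotype.
    """

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    genotype: tuple[int, int]
    phased: bool = False
    phase_set: Optional[int] = None
    hap1_allele: Optional[int] = None
    hap2_allele: Optional[int] = None

    def __post_init__(self) -> None:
        if self.phased:
            if self.phase_set is None:
                raise ValueError("phased variant must carry a phase_set")
            if {self.hap1_allele, self.hap2_allele} != set(self.genotype):
                raise ValueError(
                    "haplotype alleles must be a permutation of the genotype"
                )
        elif self.phase_set is not None:
            raise ValueError("phase_set present on unphased variant")

    @property
    def is_het(self) -> bool:
        return self.genotype[0] != self.genotype[1]

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity used to match variants across samples."""
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class PhaseBlock:
    """Contiguous set of phased variants sharing one phase set.

    The genomic range spans the outermost *heterozygous* phased member
    variants; homozygous phased records are retained as members but carry no
    phasing information and are ignored for the range.
    """

    chrom: str
    phase_set: int
    variants: list[PhasedVariant] = field(default_factory=list)

    @property
    def het_variants(self) -> list[PhasedVariant]:
        return [v for v in self.variants if v.is_het]

    @property
    def start(self) -> int:
        vs = self.het_variants or self.variants
        return min(v.pos for v in vs)

    @property
    def end(self) -> int:
        vs = self.het_variants or self.variants
        return max(v.pos for v in vs)

    @property
    def length(self) -> int:
        """Span in bp, 1-based inclusive: end - start + 1."""
        return self.end - self.start + 1

    @property
    def key(self) -> tuple[str, int]:
        return (self.chrom, self.phase_set)

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class PhaseBlockSummary:
    """Per-block table plus global phase-block length statistics."""

    per_block: pd.DataFrame
    n_blocks: int
    total_bp: int
    n50_bp: Optional[int]
    per_chrom_n50: dict[str, int]
    length_bins: dict[str, int]

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_blocks": self.n_blocks,
                "total_bp": int(self.total_bp),
                "n50_bp": None if self.n50_bp is None else int(self.n50_bp),
                "per_chrom_n50": {k: int(v) for k, v in self.per_chrom_n50.items()},
                "length_bins": self.length_bins,
            },
            indent=2,
        )


# ---------------------------------------------------------------------------
# VCF reading


def _parse_region(region: Optional[str]) -> tuple[Optional[str], Optional[int], Optional[int]]:
    if region is None:
        return None, None, None
    if ":" not in region:
        return region, None, None
    chrom, _, span = region.partition(":")
    start_s, _, end_s = span.partition("-")
    return chrom, int(start_s.replace(",", "")), int(end_s.replace(",", ""))


def read_phased_vcf(
    path: str,
    region: Optional[str] = None,
    sample: Optional[str] = None,
) -> list[PhasedVariant]:
    """Read one sample's variants from a phased VCF.

    Parameters
    ----------
    path
        VCF (v4.x) with ``GT`` and, for phased records, ``PS`` annotations.
    region
        Optional ``chrom`` or ``chrom:start-end`` restriction (1-based
        inclusive).
    sample
        Sample name to read; defaults to the first (and typically only) sample.

    Multiallelic records are decomposed into biallelic variants that keep the
    original phase set.  Records whose PS annotation is malformed are skipped
    with a warning.  A VCF without any sample column raises ``ValueError``.
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = vcf.samples
    if not samples:
        raise ValueError(f"{path}: VCF has no sample columns; genotypes required")
    if sample is None:
        sidx = 0
    else:
        try:
            sidx = samples.index(sample)
        except ValueError:
            raise ValueError(f"{path}: sample {sample!r} not found") from None

    want_chrom, want_start, want_end = _parse_region(region)
    out: list[PhasedVariant] = []
    for rec in vcf:
        if want_chrom is not None and rec.CHROM != want_chrom:
            continue
        if want_start is not None and not (want_start <= rec.POS <= want_end):
            continue
        gt = rec.genotypes[sidx]  # [allele_a, allele_b, phased]
        a, b, phased_flag = gt[0], gt[1], bool(gt[-1])
        if a < 0 or b < 0:  # missing genotype
            continue
        phase_set: Optional[int] = None
        if phased_flag:
            ps = rec.format("PS")
            if ps is None:
                # phased genotype without PS: treat the chromosome as one block
                phase_set = 0
            else:
                try:
                    val = ps[sidx]
                    phase_set = int(np.asarray(val).ravel()[0])
                    if phase_set < 0:  # cyvcf2 missing sentinel
                        raise ValueError
                except (TypeError, ValueError):
                    logger.warning(
                        "%s:%s malformed PS annotation; record skipped",
                        rec.CHROM,
                        rec.POS,
                    )
                    continue
        alts = rec.ALT or []
        for alt_idx, alt in enumerate(alts, start=1):
            # decomposition projects every other alt allele to REF
            ga = 1 if a == alt_idx else 0
            gb = 1 if b == alt_idx else 0
            if phased_flag:
                out.append(
                    PhasedVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref_allele=rec.REF,
                        alt_allele=alt,
                        genotype=(ga, gb),
                        phased=True,
                        phase_set=phase_set,
                        hap1_allele=ga,
                        hap2_allele=gb,
                    )
                )
            else:
                out.append(
                    PhasedVariant(
                        chrom=rec.CHROM,
                        pos=rec.POS,
                        ref_allele=rec.REF,
                        alt_allele=alt,
                        genotype=tuple(sorted((ga, gb))),
                    )
                )
    return out


# ---------------------------------------------------------------------------
# Phase blocks


def build_phase_blocks(variants: Iterable[PhasedVariant]) -> list[PhaseBlock]:
    """Group phased variants into one PhaseBlock per (chrom, phase set).

    Unphased variants are excluded.  Member variants are sorted by position.
    Blocks are returned sorted by (chrom, start).
    """
    groups: dict[tuple[str, int], list[PhasedVariant]] = {}
    for v in variants:
        if not v.phased:
            continue
        groups.setdefault((v.chrom, v.phase_set), []).append(v)
    blocks = []
    for (chrom, ps), members in groups.items():
        members.sort(key=lambda v: v.pos)
        blocks.append(PhaseBlock(chrom=chrom, phase_set=ps, variants=members))
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def n50(lengths: Sequence[int]) -> int:
    """N50 of a multiset of lengths.

    The largest L in the multiset such that elements of length >= L account
    for at least half the total length.
    """
    arr = np.asarray(list(lengths))
    if arr.size == 0:
        raise ValueError("n50 of an empty multiset is undefined")
    if (arr <= 0).any():
        raise ValueError("lengths must be positive")
    arr = np.sort(arr)[::-1]
    half = arr.sum() / 2.0
    csum = np.cumsum(arr)
    idx = int(np.searchsorted(csum, half))
    return int(arr[idx])


_LENGTH_BINS_BP = [
    (0, 1_000_000, "0-1Mb"),
    (1_000_000, 2_000_000, "1-2Mb"),
    (2_000_000, 5_000_000, "2-5Mb"),
    (5_000_000, 10_000_000, "5-10Mb"),
    (10_000_000, 30_000_000, "10-30Mb"),
    (30_000_000, math.inf, ">30Mb"),
]


def summarize_phase_blocks(
    blocks: Sequence[PhaseBlock],
    region: Optional[str] = None,
) -> PhaseBlockSummary:
    """Per-block rows plus global N50 / coverage / per-chromosome N50.

    ``region`` restricts the summary to blocks overlapping ``chrom`` or
    ``chrom:start-end`` (useful e.g. for an HLA-interval report).  An empty
    block set yields a summary with ``n50_bp=None``.
    """
    want_chrom, want_start, want_end = _parse_region(region)
    kept = []
    for b in blocks:
        if want_chrom is not None and b.chrom != want_chrom:
            continue
        if want_start is not None and (b.end < want_start or b.start > want_end):
            continue
        kept.append(b)

    rows = [
        {
            "chrom": b.chrom,
            "phase_set": b.phase_set,
            "start": b.start,
            "end": b.end,
            "length_bp": b.length,
            "n_variants": len(b.variants),
            "n_het_phased": len(b.het_variants),
        }
        for b in kept
    ]
    per_block = pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "phase_set",
            "start",
            "end",
            "length_bp",
            "n_variants",
            "n_het_phased",
        ],
    )
    lengths = per_block["length_bp"].to_numpy() if len(per_block) else np.array([], int)
    total = int(lengths.sum())
    global_n50 = n50(lengths) if lengths.size else None
    per_chrom = {}
    if len(per_block):
        for chrom, sub in per_block.groupby("chrom", sort=True):
            per_chrom[str(chrom)] = n50(sub["length_bp"].to_numpy())
    bins = {
        label: int(((lengths > lo) & (lengths <= hi)).sum()) if lengths.size else 0
        for lo, hi, label in _LENGTH_BINS_BP
    }
    return PhaseBlockSummary(
        per_block=per_block,
        n_blocks=len(kept),
        total_bp=total,
        n50_bp=global_n50,
        per_chrom_n50=per_chrom,
        length_bins=bins,
    )
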