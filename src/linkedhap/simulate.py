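"""Synthetic linked-read evidence with known truth.

The generator emulates the artifacts an upstream linked-read pipeline would
produce — a phased VCF, a barcode-evidence table, a somatic mutation list and
copy-number segments — from an explicit stated world:

* a diploid region with heterozygous SNPs placed by a Poisson process
  (default 1 per kb),
* HMW molecules with exponential lengths (default mean 62 kb, the cohort
  median of mean molecule lengths), each carrying one barcode and sampled by
  150 bp reads (default 62 linked-reads per mean-length molecule; read pairs
  are not modeled, each read is a single 150 bp segment),
* phase blocks obtained by fragmenting the truth haplotypes at a per-variant
  break probability (default 1.75e-4, giving ~5.7 Mb expected spans at 1
  SNP/kb) with an arbitrary label flip per block and optional switch errors,
* tumor subclones with declared mutations, haplotypes of origin and cell
  fractions; expected VAF = purity x carrier fraction / 2 in copy-number-
  neutral regions,
* haplotype tags on a configurable fraction of reads (default 0.716, the
  cohort's observed tagged-read share).

Cells are implicit: molecules are drawn per clone with probability
proportional to clone fraction.  Named scenarios reproduce the worked
examples (``nras_like``, ``actg1_like``) as deterministic hand-specified
fixtures, and provide matched-sample (``matched_pair``) and IBD donor
(``ibd_trio``) bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from linkedhap.ancestry import IBDSegment
from linkedhap.core import PhaseBlock, PhasedVariant, build_phase_blocks
from linkedhap.pairs import CNVSegment
from linkedhap.somatic import OBS_COLUMNS, SomaticMutation

_BASES = np.array(list("ACGT"))

SCENARIOS = ("basic", "nras_like", "actg1_like", "matched_pair", "ibd_trio")


def _rng(seed: Union[int, np.random.Generator]) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class SimulationParams:
    """Stated world of the generator; defaults follow the cohort's QC medians."""

    chrom: str = "chr1"
    region_start: int = 1
    region_length: int = 2_000_000
    het_snp_density: float = 1e-3  # per bp
    molecule_length_mean: float = 62_000.0
    molecule_length_distribution: str = "exponential"  # or "lognormal"
    reads_per_molecule: float = 62.0  # expected reads on a mean-length molecule
    read_length: int = 150
    molecules_per_barcode: int = 1
    mean_depth: float = 60.0  # target read depth
    fragmentation_rate: float = 1.75e-4  # per-variant block-break probability
    switch_error_rate: float = 0.0  # per-variant label-flip probability
    fraction_tagged: float = 0.716  # share of reads with a haplotype tag

    def __post_init__(self) -> None:
        for name in (
            "het_snp_density",
            "molecule_length_mean",
            "reads_per_molecule",
            "mean_depth",
            "fragmentation_rate",
            "switch_error_rate",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.fraction_tagged <= 1.0):
            raise ValueError("fraction_tagged must be in [0, 1]")

    @property
    def region_end(self) -> int:
        return self.region_start + self.region_length - 1


@dataclass
class GermlineTruth:
    """Truth haplotypes plus the emitted (fragmented, possibly flipped) phase."""

    params: SimulationParams
    positions: np.ndarray  # sorted 1-based het SNP positions
    ref: np.ndarray
    alt: np.ndarray
    h1: np.ndarray  # truth haplotype-1 allele (0/1); truth H2 = 1 - h1
    block_index: np.ndarray  # per-variant block ordinal
    block_ids: np.ndarray  # phase-set id per block (first member position)
    flip: np.ndarray  # per-variant: emitted labels are truth labels flipped

    @property
    def n_variants(self) -> int:
        return len(self.positions)

    @property
    def emitted_h1(self) -> np.ndarray:
        """Allele on emitted haplotype 1 at each variant."""
        return np.where(self.flip, 1 - self.h1, self.h1)

    def block_flips(self) -> np.ndarray:
        """Per-block flip of the first member variant (the whole block when
        switch errors are off)."""
        first = np.searchsorted(self.block_index, np.arange(len(self.block_ids)))
        return self.flip[first]

    def _variant_index_at(self, pos: np.ndarray) -> np.ndarray:
        """Index of the variant at or immediately before each position."""
        idx = np.searchsorted(self.positions, pos, side="right") - 1
        return np.clip(idx, 0, max(self.n_variants - 1, 0))

    def flip_at(self, pos: np.ndarray) -> np.ndarray:
        if self.n_variants == 0:
            return np.zeros(len(pos), dtype=bool)
        return self.flip[self._variant_index_at(pos)]

    def phase_set_at(self, pos: np.ndarray) -> np.ndarray:
        if self.n_variants == 0:
            return np.full(len(pos), -1)
        return self.block_ids[self.block_index[self._variant_index_at(pos)]]

    def variants(self) -> list[PhasedVariant]:
        """Emitted phased variants, as an upstream phasing pipeline reports them."""
        out = []
        e1 = self.emitted_h1
        for i in range(self.n_variants):
            a1 = int(e1[i])
            out.append(
                PhasedVariant(
                    chrom=self.params.chrom,
                    pos=int(self.positions[i]),
                    ref_allele=str(self.ref[i]),
                    alt_allele=str(self.alt[i]),
                    genotype=(a1, 1 - a1),
                    phased=True,
                    phase_set=int(self.block_ids[self.block_index[i]]),
                    hap1_allele=a1,
                    hap2_allele=1 - a1,
                )
            )
        return out


def _fragment(
    positions: np.ndarray,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Break a variant series into phase blocks with flips and switch errors."""
    n = len(positions)
    if n == 0:
        return np.zeros(0, int), np.zeros(0, int), np.zeros(0, bool)
    breaks = rng.random(n) < params.fragmentation_rate
    breaks[0] = True
    block_index = np.cumsum(breaks) - 1
    n_blocks = int(block_index[-1]) + 1
    block_flip = rng.integers(0, 2, n_blocks).astype(bool)
    toggles = rng.random(n) < params.switch_error_rate
    toggles[breaks] = False  # a flip at the first variant is just a block flip
    csum = np.cumsum(toggles)
    first_idx = np.searchsorted(block_index, np.arange(n_blocks))
    base = csum[first_idx] - toggles[first_idx]
    within = csum - base[block_index]
    flip = block_flip[block_index] ^ (within % 2).astype(bool)
    block_ids = positions[first_idx]
    return block_index, block_ids, flip


def simulate_germline(
    params: SimulationParams,
    seed: Union[int, np.random.Generator] = 0,
) -> GermlineTruth:
    """Place het SNPs by a Poisson process and fragment truth phase into blocks.

    Density 0 yields a truth with no variants (a valid, empty VCF).
    """
    rng = _rng(seed)
    n = int(rng.poisson(params.region_length * params.het_snp_density))
    n = min(n, params.region_length)
    offsets = rng.choice(params.region_length, size=n, replace=False)
    positions = np.sort(offsets) + params.region_start
    ref_idx = rng.integers(0, 4, n)
    alt_idx = (ref_idx + rng.integers(1, 4, n)) % 4
    h1 = rng.integers(0, 2, n)
    block_index, block_ids, flip = _fragment(positions, params, rng)
    return GermlineTruth(
        params=params,
        positions=positions,
        ref=_BASES[ref_idx],
        alt=_BASES[alt_idx],
        h1=h1,
        block_index=block_index,
        block_ids=block_ids,
        flip=flip,
    )


# ---------------------------------------------------------------------------
# tumor clones


@dataclass
class Clone:
    """One tumor subclone.

    ``mutations`` is either an int (that many mutations will be planted at
    random positions/haplotypes) or an explicit list of (pos, truth_hap)
    pairs.  ``fraction`` is the clone's exclusive share of tumor cells; a
    clone carries its own mutations plus all of its ancestors'.
    """

    name: str
    fraction: float
    parent: Optional[str] = None
    mutations: Union[int, list[tuple[int, int]]] = 0


@dataclass
class CloneTree:
    clones: list[Clone]
    purity: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.purity <= 1.0):
            raise ValueError("purity must be in [0, 1]")
        total = sum(c.fraction for c in self.clones)
        if total > 1.0 + 1e-9:
            raise ValueError("clone fractions must sum to <= 1")
        names = [c.name for c in self.clones]
        if len(set(names)) != len(names):
            raise ValueError("clone names must be unique")
        for c in self.clones:
            if c.parent is not None and c.parent not in names:
                raise ValueError(f"unknown parent {c.parent!r}")

    def carriers(self, clone_name: str) -> set[str]:
        """The clone plus all of its descendants."""
        children: dict[Optional[str], list[str]] = {}
        for c in self.clones:
            children.setdefault(c.parent, []).append(c.name)
        out, stack = set(), [clone_name]
        while stack:
            cur = stack.pop()
            out.add(cur)
            stack.extend(children.get(cur, ()))
        return out

    @classmethod
    def single(cls, n_mutations: int = 10, purity: float = 1.0) -> "CloneTree":
        return cls([Clone("founder", 1.0, mutations=n_mutations)], purity=purity)

    @classmethod
    def siblings(
        cls,
        fraction_a: float = 0.4,
        fraction_b: float = 0.2,
        purity: float = 1.0,
        n_mutations_each: int = 1,
    ) -> "CloneTree":
        rest = 1.0 - fraction_a - fraction_b
        clones = [
            Clone("founder", rest),
            Clone("sib_a", fraction_a, parent="founder", mutations=n_mutations_each),
            Clone("sib_b", fraction_b, parent="founder", mutations=n_mutations_each),
        ]
        return cls(clones, purity=purity)

    @classmethod
    def nested(
        cls,
        fraction_parent_only: float = 0.3,
        fraction_child: float = 0.5,
        purity: float = 1.0,
    ) -> "CloneTree":
        rest = 1.0 - fraction_parent_only - fraction_child
        clones = [
            Clone("founder", rest),
            Clone("parent", fraction_parent_only, parent="founder", mutations=1),
            Clone("child", fraction_child, parent="parent", mutations=1),
        ]
        return cls(clones, purity=purity)


@dataclass
class PlantedMutation:
    site: SomaticMutation
    clone: str
    truth_hap: int  # 1 | 2, in truth labels
    emitted_hap: int  # label after the local block flip (what a caller should find)
    expected_vaf: float


@dataclass
class TumorTruth:
    clone_tree: CloneTree
    mutations: list[PlantedMutation]
    cnv: list[CNVSegment]


def simulate_tumor(
    truth: GermlineTruth,
    clone_tree: CloneTree,
    seed: Union[int, np.random.Generator] = 0,
    cnv: Optional[Sequence[CNVSegment]] = None,
) -> TumorTruth:
    """Plant declared somatic SNVs on haplotypes and derive expected VAFs.

    Mutations declared as an int count are drawn uniformly over the region,
    re-drawn on collision with a germline SNP or another mutation; haplotypes
    of origin are drawn uniformly.  A mutation is never placed on both
    haplotypes of one clone.  Default CNV output is one neutral segment
    (log2 ratio 0) spanning the region.
    """
    rng = _rng(seed)
    params = truth.params
    taken = set(int(p) for p in truth.positions)
    planted: list[PlantedMutation] = []
    frac_by_name = {c.name: c.fraction for c in clone_tree.clones}
    for clone in clone_tree.clones:
        if isinstance(clone.mutations, int):
            muts = []
            for _ in range(clone.mutations):
                while True:
                    pos = int(rng.integers(params.region_start, params.region_end + 1))
                    if pos not in taken:
                        break
                taken.add(pos)
                muts.append((pos, int(rng.integers(1, 3))))
        else:
            muts = [(int(p), int(h)) for p, h in clone.mutations]
            for pos, _ in muts:
                if pos in taken:
                    raise ValueError(f"mutation position {pos} collides")
                taken.add(pos)
        carrier_frac = sum(
            frac_by_name[name] for name in clone_tree.carriers(clone.name)
        )
        for pos, hap in muts:
            ref = str(_BASES[int(rng.integers(0, 4))])
            alt = str(_BASES[(list(_BASES).index(ref) + int(rng.integers(1, 4))) % 4])
            flip = bool(truth.flip_at(np.array([pos]))[0]) if truth.n_variants else False
            planted.append(
                PlantedMutation(
                    site=SomaticMutation(params.chrom, pos, ref, alt),
                    clone=clone.name,
                    truth_hap=hap,
                    emitted_hap=(3 - hap) if flip else hap,
                    expected_vaf=clone_tree.purity * carrier_frac / 2.0,
                )
            )
    planted.sort(key=lambda m: m.site.pos)
    if cnv is None:
        cnv = [
            CNVSegment(params.chrom, params.region_start, params.region_end, 0.0)
        ]
    return TumorTruth(clone_tree=clone_tree, mutations=planted, cnv=list(cnv))


# ---------------------------------------------------------------------------
# molecules / barcodes / reads


def simulate_barcodes(
    truth: GermlineTruth,
    tumor: Optional[TumorTruth],
    params: Optional[SimulationParams] = None,
    seed: Union[int, np.random.Generator] = 0,
) -> pd.DataFrame:
    """Barcode-evidence table: one row per (read, covered site) observation.

    Molecules are drawn with exponential (or lognormal) lengths and uniform
    starts, assigned a truth haplotype (50/50) and a cell population (normal
    with probability 1 - purity, otherwise a clone by fraction); reads are
    Poisson-sampled along each molecule and report the molecule's haplotype
    allele at covered germline SNPs and the clone's somatic allele at covered
    mutation sites.  A configurable fraction of reads carries a haplotype tag
    holding the *emitted* (phase-block-local) label of the molecule's
    haplotype.
    """
    params = params or truth.params
    rng = _rng(seed)
    region = params.region_length
    n_mol = max(
        1,
        int(round(params.mean_depth * region / (params.reads_per_molecule * params.read_length))),
    )

    if params.molecule_length_distribution == "exponential":
        lengths = rng.exponential(params.molecule_length_mean, n_mol)
    elif params.molecule_length_distribution == "lognormal":
        sigma = 0.5
        mu = np.log(params.molecule_length_mean) - sigma**2 / 2
        lengths = rng.lognormal(mu, sigma, n_mol)
    else:
        raise ValueError("molecule_length_distribution must be exponential|lognormal")
    lengths = np.maximum(lengths, params.read_length).astype(np.int64)
    starts = (
        params.region_start
        - lengths
        + 1
        + (rng.random(n_mol) * (region + lengths - 1)).astype(np.int64)
    )
    hap = rng.integers(1, 3, n_mol)

    # cell population per molecule
    if tumor is not None:
        tree = tumor.clone_tree
        probs = [1.0 - tree.purity] + [tree.purity * c.fraction for c in tree.clones]
        residual = 1.0 - sum(probs)
        probs.append(max(residual, 0.0))
        probs = np.array(probs) / np.sum(probs)
        # 0 = normal, 1..k = clones, k+1 = tumor residual (no private mutations)
        population = rng.choice(len(probs), size=n_mol, p=probs)
        clone_names = [c.name for c in tree.clones]
        carrier_matrix = np.zeros((len(tumor.mutations), len(probs)), dtype=bool)
        for mi, m in enumerate(tumor.mutations):
            carriers = tree.carriers(m.clone)
            for ci, name in enumerate(clone_names, start=1):
                carrier_matrix[mi, ci] = name in carriers
        mut_pos = np.array([m.site.pos for m in tumor.mutations], dtype=np.int64)
        mut_hap = np.array([m.truth_hap for m in tumor.mutations])
        order = np.argsort(mut_pos)
        mut_pos, mut_hap = mut_pos[order], mut_hap[order]
        carrier_matrix = carrier_matrix[order]
    else:
        population = np.zeros(n_mol, dtype=int)
        mut_pos = np.zeros(0, dtype=np.int64)

    # reads
    lam = params.reads_per_molecule * lengths / params.molecule_length_mean
    reads_per_mol = rng.poisson(lam)
    n_reads = int(reads_per_mol.sum())
    mol_of_read = np.repeat(np.arange(n_mol), reads_per_mol)
    span = np.maximum(lengths - params.read_length, 1)
    read_start = starts[mol_of_read] + (
        rng.random(n_reads) * span[mol_of_read]
    ).astype(np.int64)
    tagged = rng.random(n_reads) < params.fraction_tagged

    def site_observations(site_pos: np.ndarray):
        lo = np.searchsorted(site_pos, read_start)
        hi = np.searchsorted(site_pos, read_start + params.read_length)
        counts = hi - lo
        read_of_obs = np.repeat(np.arange(n_reads), counts)
        offs = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
        site_idx = np.repeat(lo, counts) + offs
        return read_of_obs, site_idx

    frames = []

    if truth.n_variants:
        read_of_obs, snp_idx = site_observations(truth.positions)
        mol_idx = mol_of_read[read_of_obs]
        allele = np.where(hap[mol_idx] == 1, truth.h1[snp_idx], 1 - truth.h1[snp_idx])
        flip = truth.flip[snp_idx]
        tag_label = np.where(flip, 3 - hap[mol_idx], hap[mol_idx])
        tag = np.where(tagged[read_of_obs], tag_label, 0)
        ps = truth.block_ids[truth.block_index[snp_idx]]
        frames.append(
            pd.DataFrame(
                {
                    "_mol": mol_idx,
                    "chrom": params.chrom,
                    "pos": truth.positions[snp_idx],
                    "allele": allele.astype(np.int8),
                    "hap": tag.astype(np.int8),
                    "phase_set": ps.astype(np.int64),
                }
            )
        )

    if mut_pos.size:
        read_of_obs, mut_idx = site_observations(mut_pos)
        mol_idx = mol_of_read[read_of_obs]
        carries = carrier_matrix[mut_idx, population[mol_idx]] & (
            hap[mol_idx] == mut_hap[mut_idx]
        )
        flip = truth.flip_at(mut_pos[mut_idx]) if truth.n_variants else np.zeros(
            len(mut_idx), bool
        )
        tag_label = np.where(flip, 3 - hap[mol_idx], hap[mol_idx])
        tag = np.where(tagged[read_of_obs], tag_label, 0)
        ps = truth.phase_set_at(mut_pos[mut_idx])
        frames.append(
            pd.DataFrame(
                {
                    "_mol": mol_idx,
                    "chrom": params.chrom,
                    "pos": mut_pos[mut_idx],
                    "allele": carries.astype(np.int8),
                    "hap": tag.astype(np.int8),
                    "phase_set": np.asarray(ps, dtype=np.int64),
                }
            )
        )

    if not frames:
        return pd.DataFrame(columns=OBS_COLUMNS)

    obs = pd.concat(frames, ignore_index=True)
    # barcode assignment: molecules_per_barcode molecules share one barcode
    perm = rng.permutation(n_mol)
    barcode_of_mol = perm // max(params.molecules_per_barcode, 1)
    obs["barcode"] = np.char.add(
        "BX", np.char.zfill(barcode_of_mol[obs["_mol"]].astype(str), 8)
    )
    obs = obs.drop(columns="_mol")
    obs = obs[OBS_COLUMNS].sort_values(["chrom", "pos", "barcode"], kind="mergesort")
    return obs.reset_index(drop=True)


# ---------------------------------------------------------------------------
# deterministic worked-example fixtures


def _fixture_molecule_rows(
    barcode: str,
    hap_label: int,
    start: int,
    end: int,
    snp_positions: Sequence[int],
    somatic_sites: Sequence[int],
    carries: set[int],
    phase_set: int,
    chrom: str,
) -> list[dict]:
    """Rows emitted by one fully-tagged fixture molecule.

    Germline SNPs carry ref on H1 and alt on H2, so a molecule on emitted
    haplotype ``hap_label`` reports allele ``hap_label - 1`` at every covered
    SNP.
    """
    rows = []
    for pos in snp_positions:
        if start <= pos <= end:
            rows.append(
                {
                    "barcode": barcode,
                    "chrom": chrom,
                    "pos": pos,
                    "allele": hap_label - 1,
                    "hap": hap_label,
                    "phase_set": phase_set,
                }
            )
    for pos in somatic_sites:
        if start <= pos <= end:
            rows.append(
                {
                    "barcode": barcode,
                    "chrom": chrom,
                    "pos": pos,
                    "allele": 1 if pos in carries else 0,
                    "hap": hap_label,
                    "phase_set": phase_set,
                }
            )
    return rows


@dataclass
class Bundle:
    """A full fixture bundle: inputs for every module plus the truth."""

    name: str
    seed: int
    params: SimulationParams
    variants: list[PhasedVariant] = field(default_factory=list)
    blocks: list[PhaseBlock] = field(default_factory=list)
    observations: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=OBS_COLUMNS)
    )
    mutations: list[PlantedMutation] = field(default_factory=list)
    cnv: list[CNVSegment] = field(default_factory=list)
    clone_tree: Optional[CloneTree] = None
    germline: Optional[GermlineTruth] = None
    # matched_pair extras
    target_variants: Optional[list[PhasedVariant]] = None
    reference_variants: Optional[list[PhasedVariant]] = None
    target_truth: Optional[GermlineTruth] = None
    reference_truth: Optional[GermlineTruth] = None
    # ibd_trio extras
    ibd_segments: Optional[list[IBDSegment]] = None
    donor_alleles: Optional[dict] = None
    truth: dict = field(default_factory=dict)

    @property
    def somatic_sites(self) -> list[SomaticMutation]:
        return [m.site for m in self.mutations]

    def write(self, out_dir: Union[str, Path]) -> dict[str, Path]:
        """Emit the bundle as plain-text artifacts; returns paths by kind."""
        from linkedhap import io as lio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        if self.variants:
            paths["vcf"] = out / "sample.phased.vcf"
            lio.write_phased_vcf(self.variants, paths["vcf"])
        if len(self.observations):
            paths["barcodes"] = out / "barcodes.tsv"
            lio.write_barcode_tsv(self.observations, paths["barcodes"])
        if self.mutations:
            paths["maf"] = out / "somatic.maf"
            lio.write_maf(self.somatic_sites, paths["maf"])
        if self.cnv:
            paths["cnv"] = out / "cnv.bed"
            lio.write_cnv_bed(self.cnv, paths["cnv"])
        if self.target_variants is not None:
            paths["target_vcf"] = out / "target.phased.vcf"
            lio.write_phased_vcf(self.target_variants, paths["target_vcf"])
        if self.reference_variants is not None:
            paths["reference_vcf"] = out / "reference.phased.vcf"
            lio.write_phased_vcf(self.reference_variants, paths["reference_vcf"])
        if self.ibd_segments:
            paths["ibd"] = out / "segments.ibd"
            lio.write_refined_ibd(self.ibd_segments, paths["ibd"])
        paths["truth"] = out / "truth.json"
        paths["truth"].write_text(json.dumps(self.truth, indent=2, default=str))
        return paths


def _fixture_variants(
    chrom: str, snp_positions: Sequence[int], phase_set: int
) -> list[PhasedVariant]:
    # ref on H1, alt on H2 at every fixture SNP
    return [
        PhasedVariant(
            chrom=chrom,
            pos=pos,
            ref_allele="A",
            alt_allele="G",
            genotype=(0, 1),
            phased=True,
            phase_set=phase_set,
            hap1_allele=0,
            hap2_allele=1,
        )
        for pos in snp_positions
    ]


def _nras_like(seed: int) -> Bundle:
    """Two hotspot mutations on the same haplotype in sibling subclones.

    The shared-barcode tabulation of the pair yields allele-pair classes
    (REF-REF, REF-ALT, ALT-REF, ALT-ALT) = (2, 1, 1, 0): both single-mutant
    patterns observed, never both mutations together.
    """
    chrom = "chr1"
    snps = [1_148_600 + 500 * i for i in range(12)]
    ps = snps[0]
    site_a, site_b = 1_150_000, 1_152_000
    rows: list[dict] = []

    def mol(bc, hap, start, end, carries=()):
        rows.extend(
            _fixture_molecule_rows(
                bc, hap, start, end, snps, (site_a, site_b), set(carries), ps, chrom
            )
        )

    # shared barcodes spanning both somatic sites
    mol("BC_RR1", 1, 1_149_500, 1_152_500)
    mol("BC_RR2", 2, 1_149_500, 1_152_500)  # H2 molecule from a cell without either mutation
    mol("BC_RA1", 2, 1_149_500, 1_152_500, carries={site_b})
    mol("BC_AR1", 2, 1_149_500, 1_152_500, carries={site_a})
    # site-A-only barcodes
    for i in range(4):
        mol(f"BC_A_ALT{i}", 2, 1_149_000, 1_151_000, carries={site_a})
    for i in range(2):
        mol(f"BC_A_REF_H1_{i}", 1, 1_149_000, 1_151_000)
        mol(f"BC_A_REF_H2_{i}", 2, 1_149_000, 1_151_000)
    # site-B-only barcodes
    for i in range(3):
        mol(f"BC_B_ALT{i}", 2, 1_151_200, 1_153_200, carries={site_b})
    for i in range(3):
        mol(f"BC_B_REF_H1_{i}", 1, 1_151_200, 1_153_200)
    for i in range(2):
        mol(f"BC_B_REF_H2_{i}", 2, 1_151_200, 1_153_200)

    params = SimulationParams(chrom=chrom, region_start=1_140_000, region_length=20_000)
    variants = _fixture_variants(chrom, snps, ps)
    tree = CloneTree.siblings(fraction_a=0.4, fraction_b=0.2, purity=1.0)
    mutations = [
        PlantedMutation(
            site=SomaticMutation(chrom, site_a, "G", "C", gene="NRAS_like_a"),
            clone="sib_a",
            truth_hap=2,
            emitted_hap=2,
            expected_vaf=0.20,
        ),
        PlantedMutation(
            site=SomaticMutation(chrom, site_b, "C", "A", gene="NRAS_like_b"),
            clone="sib_b",
            truth_hap=2,
            emitted_hap=2,
            expected_vaf=0.10,
        ),
    ]
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return Bundle(
        name="nras_like",
        seed=seed,
        params=params,
        variants=variants,
        blocks=build_phase_blocks(variants),
        observations=obs,
        mutations=mutations,
        cnv=[CNVSegment(chrom, 1_100_000, 1_200_000, 0.0)],
        clone_tree=tree,
        truth={
            "scenario": "nras_like",
            "pattern_counts": {"REF-REF": 2, "REF-ALT": 1, "ALT-REF": 1, "ALT-ALT": 0},
            "expected_interpretation": "independent_subclones",
            "mutation_haplotype": {"all": "H2"},
        },
    )


def _actg1_like(seed: int) -> Bundle:
    """Nested subclones: the first mutation precedes the second.

    ALT-REF (first mutated, second not) and ALT-ALT (both mutated) are
    observed, REF-ALT never is; with REF-REF barcodes present the presence
    pattern is 1011, the sequential exemplar.  (The printed counts cover only
    ALT-REF = 6 and ALT-ALT = 24; the REF-REF barcodes here are a fixture
    choice.)  Copy number in the region is elevated (log2 ratio 0.406,
    i.e. ~2.65 copies), which the barcode patterns tolerate.
    """
    chrom = "chr17"
    snps = [2_498_000 + 500 * i for i in range(12)]
    ps = snps[0]
    site_a, site_b = 2_500_050, 2_500_450  # a = earlier mutation (G156-like)
    rows: list[dict] = []

    def mol(bc, hap, carries=()):
        rows.extend(
            _fixture_molecule_rows(
                bc, hap, 2_499_000, 2_501_500, snps, (site_a, site_b), set(carries), ps, chrom
            )
        )

    for i in range(5):
        mol(f"BC_RR_H1_{i}", 1)
        mol(f"BC_RR_H2_{i}", 2)
    for i in range(6):
        mol(f"BC_AR_{i}", 2, carries={site_a})
    for i in range(24):
        mol(f"BC_AA_{i:02d}", 2, carries={site_a, site_b})

    params = SimulationParams(chrom=chrom, region_start=2_490_000, region_length=20_000)
    variants = _fixture_variants(chrom, snps, ps)
    tree = CloneTree.nested(fraction_parent_only=0.2, fraction_child=0.8, purity=1.0)
    mutations = [
        PlantedMutation(
            site=SomaticMutation(chrom, site_a, "C", "T", gene="ACTG1_like_G156"),
            clone="parent",
            truth_hap=2,
            emitted_hap=2,
            expected_vaf=0.5,
        ),
        PlantedMutation(
            site=SomaticMutation(chrom, site_b, "G", "A", gene="ACTG1_like_L104"),
            clone="child",
            truth_hap=2,
            emitted_hap=2,
            expected_vaf=0.4,
        ),
    ]
    obs = pd.DataFrame(rows, columns=OBS_COLUMNS)
    return Bundle(
        name="actg1_like",
        seed=seed,
        params=params,
        variants=variants,
        blocks=build_phase_blocks(variants),
        observations=obs,
        mutations=mutations,
        cnv=[CNVSegment(chrom, 2_490_000, 2_510_000, 0.406)],
        clone_tree=tree,
        truth={
            "scenario": "actg1_like",
            "pattern_counts": {"REF-REF": 10, "REF-ALT": 0, "ALT-REF": 6, "ALT-ALT": 24},
            "expected_interpretation": "sequential_a_first",
            "mutation_haplotype": {"all": "H2"},
        },
    )


def _basic(seed: int, params: Optional[SimulationParams] = None) -> Bundle:
    params = params or SimulationParams(region_length=1_000_000, mean_depth=40.0)
    rng = _rng(seed)
    germ = simulate_germline(params, rng)
    tumor = simulate_tumor(germ, CloneTree.single(n_mutations=10), rng)
    obs = simulate_barcodes(germ, tumor, params, rng)
    variants = germ.variants()
    return Bundle(
        name="basic",
        seed=seed,
        params=params,
        variants=variants,
        blocks=build_phase_blocks(variants),
        observations=obs,
        mutations=tumor.mutations,
        cnv=tumor.cnv,
        clone_tree=tumor.clone_tree,
        germline=germ,
        truth={
            "scenario": "basic",
            "n_variants": int(germ.n_variants),
            "n_blocks": int(len(germ.block_ids)),
            "mutations": [
                {
                    "pos": m.site.pos,
                    "clone": m.clone,
                    "truth_hap": m.truth_hap,
                    "emitted_hap": m.emitted_hap,
                    "expected_vaf": m.expected_vaf,
                }
                for m in tumor.mutations
            ],
        },
    )


def _matched_pair(seed: int, params: Optional[SimulationParams] = None) -> Bundle:
    """Two samples of one truth genome with different phase-block fragmentation."""
    params = params or SimulationParams(
        region_length=5_000_000, fragmentation_rate=2e-3, switch_error_rate=0.0
    )
    rng = _rng(seed)
    shared = simulate_germline(replace(params, fragmentation_rate=0.0), rng)
    t_bi, t_ids, t_flip = _fragment(shared.positions, params, rng)
    r_bi, r_ids, r_flip = _fragment(shared.positions, params, rng)
    target = GermlineTruth(
        params=params,
        positions=shared.positions,
        ref=shared.ref,
        alt=shared.alt,
        h1=shared.h1,
        block_index=t_bi,
        block_ids=t_ids,
        flip=t_flip,
    )
    reference = GermlineTruth(
        params=params,
        positions=shared.positions,
        ref=shared.ref,
        alt=shared.alt,
        h1=shared.h1,
        block_index=r_bi,
        block_ids=r_ids,
        flip=r_flip,
    )
    tv, rv = target.variants(), reference.variants()
    return Bundle(
        name="matched_pair",
        seed=seed,
        params=params,
        variants=tv,
        blocks=build_phase_blocks(tv),
        target_variants=tv,
        reference_variants=rv,
        target_truth=target,
        reference_truth=reference,
        truth={
            "scenario": "matched_pair",
            "target_block_flips": {
                str(int(bid)): bool(f)
                for bid, f in zip(target.block_ids, target.block_flips())
            },
            "reference_block_flips": {
                str(int(bid)): bool(f)
                for bid, f in zip(reference.block_ids, reference.block_flips())
            },
        },
    )


def _ibd_trio(seed: int, params: Optional[SimulationParams] = None) -> Bundle:
    """A donor shares truth haplotype 1 over a subinterval, bridging blocks."""
    params = params or SimulationParams(
        region_length=2_000_000, fragmentation_rate=2e-3
    )
    rng = _rng(seed)
    germ = simulate_germline(params, rng)
    variants = germ.variants()
    seg_start = params.region_start + params.region_length // 4
    seg_end = params.region_start + 3 * params.region_length // 4
    segment = IBDSegment(
        sample1="SAMPLE",
        hap_index1=1,
        sample2="DONOR",
        hap_index2=1,
        chrom=params.chrom,
        start=seg_start,
        end=seg_end,
        lod=15.64,
        cm_length=1.576,
    )
    # donor haplotype 1 copies truth haplotype 1 inside the segment
    donor_alleles = {}
    for i, pos in enumerate(germ.positions):
        if seg_start <= pos <= seg_end:
            other = int(rng.integers(0, 2))
            donor_alleles[(params.chrom, int(pos))] = (int(germ.h1[i]), other)
    return Bundle(
        name="ibd_trio",
        seed=seed,
        params=params,
        variants=variants,
        blocks=build_phase_blocks(variants),
        germline=germ,
        ibd_segments=[segment],
        donor_alleles=donor_alleles,
        truth={
            "scenario": "ibd_trio",
            "segment": {"start": seg_start, "end": seg_end},
            # in emitted labels, donor hap1 matches sample H1 where the block
            # is unflipped and H2 where it is flipped
            "block_flips": {
                str(int(bid)): bool(f)
                for bid, f in zip(germ.block_ids, germ.block_flips())
            },
        },
    )


def scenario(
    name: str,
    seed: int = 0,
    params: Optional[SimulationParams] = None,
) -> Bundle:
    """Build a named fixture bundle.

    ``nras_like`` and ``actg1_like`` are deterministic hand-specified fixtures
    reproducing the worked examples exactly (the seed is recorded but does not
    alter them); the other scenarios are seeded stochastic draws.
    """
    if name == "basic":
        return _basic(seed, params)
    if name == "nras_like":
        return _nras_like(seed)
    if name == "actg1_like":
        return _actg1_like(seed)
    if name == "matched_pair":
        return _matched_pair(seed, params)
    if name == "ibd_trio":
        return _ibd_trio(seed, params)
    raise ValueError(f"unknown scenario {name!r}; choose from {SCENARIOS}")
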