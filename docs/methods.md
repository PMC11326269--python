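# Methods

## Data model and conventions

All coordinates are 1-based inclusive (VCF convention); block length is
`end − start + 1` over the outermost phased *heterozygous* member variants.
Homozygous phased records stay block members but never define the range or
vote in any rule, since only heterozygosity carries phasing information. A
phase set is any consistent per-sample identifier; the common convention of
using the position of a block's first variant is accepted but not required.
Phase-block boundaries are defined by member variants — whether an upstream
tool considers the block to extend beyond its outermost variant is not
observable from the VCF, so we do not model it.

Barcode evidence is one row per (read, site): `barcode, chrom, pos,
allele∈{0,1}, hap∈{0,1,2}` (0 = untagged) and an optional phase set. This
table is the abstraction of a haplotype-tagged BAM; an adapter producing it
from a BAM is deliberately out of the test surface (no alignment handling
here).

## Somatic phasing

Linked alleles: a vote is counted once per (barcode, germline site), pooling
all reads of the barcode — votes reflect molecules, not read depth. The
consensus allele per (barcode, site) is the read majority; exact ties drop
the barcode (a chimeric-barcode signature). The 91% majority threshold is
inclusive ("at least"), applied only to votes from ALT-supporting barcodes;
REF-side votes are tallied for QC (a skewed REF side flags block-level
problems) but never drive the verdict. Coverage floor: 10 phased
linked-allele votes on the ALT side. The barcodes rule requires complete
agreement of haplotype-tagged ALT reads, minimum one tagged read.

Combination: exactly one phased verdict wins; equal verdicts agree; unequal
phased verdicts yield `NP` with `discordant=True`. We deliberately prefer no
tie-break — discordance is rare on real data and diagnostically interesting,
and the conservative default is configurable. Somatic sites outside every
phase block can still be phased (the rules only need phased linked alleles or
tagged reads); block assignment is metadata.

Floating-point note: the threshold comparison adds 1e-9 so that exact
boundary fractions (91/100) pass the inclusive rule regardless of binary
rounding.

## Mutation pairs

Eligibility: both sites in a copy-number-neutral segment (log2 ratio in
[−0.25, 0.2], inclusive at both ends), 10–100 haplotype-tagged barcodes per
site, ≥ 1 ALT barcode, pair distance ≤ 62,000 bp (inclusive; "within");
"near" pairs are < 100 bp (strict). 62 kb is the typical HMW molecule
length, beyond which barcode sharing is essentially absent.

The presence pattern orders the classes (REF-REF, REF-ALT, ALT-REF,
ALT-ALT); this order reproduces both canonical exemplars (1110 "distinct",
1011/1101 "sequential"). Interpretation is parsimony-based (each mutation
arises once, hard-coded). For 1110/0110 the independent-subclones reading
additionally requires both ALTs phased to the same haplotype in a
copy-number-neutral context; when those side conditions fail the classifier
returns `uninformative` rather than inventing a weaker category — absence of
ALT-ALT barcodes for mutations on *different* haplotypes is expected and
carries no clonal signal.

SV mapping: windows of 100 kb per breakpoint side (larger than a typical
molecule, so spanning molecules register in both), ≥ 2 supporting barcodes,
consensus over all haplotype tags on supporting barcodes' flanking reads;
any disagreement is reported `inconsistent`, never resolved silently.

## Phase-block extension

A shared variant (matched on chrom, pos, ref, alt; het and phased in both
samples; no liftover — same individual, same reference) votes "switch" when
the target's H1 allele differs from the reference's H1 allele. Verdicts
require ≥ 10 shared variants, rejection of a two-sided exact binomial test
(null proportion 0.5, α = 0.05) and a strict hard cutoff (> 95% or < 5%
switch votes). The source material specifies the test only qualitatively
("conservative switch error rate"); null 0.5 makes the test a guard against
low-information overlaps while the hard cutoff carries the conservatism —
both are configuration values.

Parity graph: weight 1 (switch) / 2 (no switch); relative orientation of two
target blocks = path weight sum mod 2. Components where two paths disagree
are flagged inconsistent and produce *no* orientations — a switch error
would propagate through any repair, so repair is out of scope. Group output
is anchored at the member target block with the lowest genomic coordinate,
making it deterministic. The "after" length of a group is the span from
minimum start to maximum end of its members; the target VCF is not
rewritten (group tables only).

## IBD bridging

Within a segment ∩ block intersection, each phased het sample position with
a donor genotype compares the donor's IBD-haplotype allele to the sample's
H1/H2 alleles. A block qualifies on a segment with ≥ 10 informative
positions and a ≥ 0.95 majority toward one haplotype — thresholds chosen by
analogy with the extension cutoffs, as the source gives none for bridging;
both are parameters. Qualifying block pairs on one segment yield SAME /
OPPOSITE recommendations that enter the extension parity graph as weight-2 /
weight-1 edges. Population-history annotation is pass-through of segment
metadata onto the intersected interval; no inference is performed.

## Synthetic data generator

The generator's defaults are the stated world of the cohort it emulates:

| parameter | default | rationale |
|---|---|---|
| het SNP density | 1 per 1,000 bp | typical human heterozygosity |
| molecule length | exponential, mean 62 kb | cohort median of per-sample mean molecule lengths |
| linked-reads per molecule | 62 per mean length | cohort median N50 linked-reads/molecule |
| read length | 150 bp | 2×150 bp chemistry; pairs are not modeled, each read is one 150 bp segment |
| mean depth | 60× | tumor sequencing target |
| fraction of reads haplotype-tagged | 0.716 | observed share of tagged reads at somatic sites |
| block-break probability | 1.75e-4 per variant | ≈ 5.7 Mb expected block span at 1 SNP/kb, the cohort median N50 |
| switch error rate | 0 | clean default; configurable per variant |
| molecules per barcode | 1 | clean fixtures (real assays pool ~10 molecules per droplet; configurable) |

Molecule lengths are exponential because the memoryless property matches the
observed exponential decay of barcode sharing with distance; only means/N50s
are reported for the real assay, so the distribution is an implementation
choice (lognormal available). Cells are implicit — molecules are drawn per
clone with probability purity × clone fraction (plus a normal-cell mass of
1 − purity); this suffices for every downstream statistic. Expected VAF of a
mutation is purity × (carrying-clone fraction sum) / 2 in CN-neutral
regions. Somatic mutations are never placed on both haplotypes of one clone,
and mutation positions re-draw on collision with germline SNPs.

Haplotype tags hold the *emitted* (phase-block-local) label of the
molecule's truth haplotype at the read position, so tags flip across block
boundaries and planted switch errors exactly as a phasing pipeline's would.
The truth set records, per mutation, both the truth-label haplotype and the
emitted-label haplotype at its position — recovery is always scored against
the emitted label, since block labels are arbitrary.

What the generator does **not** emulate: sequencing errors and base
qualities, alignment and mapping artifacts, GC/coverage bias, real
molecule-per-barcode multiplexing by default, read pairing, and indels. A
green test therefore establishes correctness of the decision rules and
plumbing under the stated model, not robustness to platform noise.

The two worked-example scenarios (`nras_like`, `actg1_like`) are
deterministic hand-specified barcode tables whose tabulation reproduces the
printed class counts exactly; the seed is accepted but does not perturb
them. The `actg1_like` REF-REF count (10) is a fixture choice — the printed
counts cover only ALT-REF = 6 and ALT-ALT = 24 — included so the encoded
pattern is the sequential exemplar 1011. Its CNV segment carries log2 ratio
0.406 (~2.65 copies), matching the reported elevated copy number; the
sequential interpretation tolerates non-neutral copy number by design.

## Numerical and degenerate-input choices

* N50 of an empty multiset is an error; an empty block set summarizes with
  `n50_bp = None`, flagged rather than 0.
* Duplicated (chrom, pos, ref, alt) inside one sample is a malformed-input
  error in extension; same-position different-alt records (decomposed
  multiallelics) are skipped for cross-sample matching.
* Multiallelic VCF records decompose into biallelic variants keeping the
  original phase set; other alt alleles project to REF.
* A malformed phase-set annotation skips the record with a warning; a VCF
  without a sample column is an error.
* Binomial tests use the exact two-sided test (`scipy.stats.binomtest`).
* Observation tables are sorted (chrom, pos, barcode) with a stable sort, so
  identical seeds give byte-identical artifacts.

## Interfaces in lieu of a CLI

The package is consumed from Python: the pipeline stage functions in
`linkedhap.pipeline` (`run_phaseblock`, `run_summarize`, `run_somatic`,
`run_pairs`, `run_extend`, `run_ancestry`, `run_simulate`) each load the
declared inputs, run one stage and write documented TSV/JSON artifacts —
portable, versionable formats rather than opaque serialized objects — and
the scripts in `examples/` demonstrate each capability end to end. The
pairwise analysis is exposed as its own stage (rather than folded into the
somatic stage) for a separable test surface.

## Known limitations

* Indel phasing is not supported; the somatic rules are stated for SNVs.
* No formal subclone-tree inference or purity estimation; interpretations
  are per-pair and parsimony-based.
* Extension composes pairwise sample runs; no joint multi-sample model.
* Cohort-scale performance numbers reported for patient data (fraction
  phased, precision/recall of the threshold, method concordance rate,
  median extension fold change) depend on real tumor purity and coverage
  profiles and are not reproducible from desk-scale synthetic data; the
  tests assert the rules and worked examples, and recovery rates on the
  generator's stated world only.
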