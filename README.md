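# linkedhap

Haplotype-aware analysis of somatic mutations from linked-read whole-genome
sequencing (lrWGS).

Linked-read platforms (10X Chromium style) partition high-molecular-weight
(HMW) DNA molecules into droplets and tag all short reads from one molecule
with a shared barcode. Because a molecule comes from a single parental
haplotype, reads sharing a barcode in a genomic window carry joint haplotype
information far beyond the read length. Upstream pipelines use this to phase
germline variants into *phase blocks* — ranges in which H1/H2 labels are
mutually consistent but arbitrary between blocks. `linkedhap` builds on that
output to answer questions those pipelines do not: which haplotype carries a
*somatic* mutation, how pairs of nearby somatic mutations relate clonally, and
how phase blocks can be joined across samples.

It is a library for cancer-genomics and statistical-genetics analysts working
with phased VCFs, haplotype-tagged read evidence, somatic mutation calls,
copy-number segments and identity-by-descent (IBD) reports.

## What it computes

**Somatic mutation phasing** — two complementary rules per mutation site:

* *linked alleles*: every phased heterozygous germline allele observed on a
  barcode supporting the mutant (ALT) allele votes for the haplotype carrying
  it. With votes $n_{H1} + n_{H2} \ge 10$, the site is assigned to a haplotype
  when $\max(n_{H1}, n_{H2}) / (n_{H1}+n_{H2}) \ge 0.91$;
* *barcodes*: all haplotype-tagged reads supporting the ALT allele must agree
  (complete agreement; one tagged read suffices).

Verdicts are `H1`/`H2`, `NP` (covered but not phased), `NC` (insufficient
coverage); conflicts between the rules give `NP` with a discordant flag.

**Mutation-pair clonality** — for two somatic sites within a molecule length
(≤ 62 kb), each shared barcode contributes one allele pair (REF-REF, REF-ALT,
ALT-REF, ALT-ALT). The 4-bit presence pattern over these classes is read
under parsimony: `1011` ⇒ the first mutation preceded the second (nested
subclones); `1110` with both ALTs on one haplotype in a copy-number-neutral
region ⇒ independent sibling subclones; `1001` ⇒ co-occurrence only.
Structural variants are mapped to haplotypes from barcodes flanking both
breakpoints.

**Phase-block extension** — shared germline het variants between two samples
of one individual vote "switch"/"no switch" per overlapping block pair; a
verdict needs ≥ 10 shared variants, a two-sided binomial test against 0.5,
and a strict >95% / <5% cutoff. Determined verdicts become edges (weight 1 =
switch, 2 = no switch) of a bipartite parity graph; two target blocks have
the same orientation iff the path weight sum is even. IBD segments from a
donor provide equivalent parity edges where no matched sample overlaps.

**Synthetic data** — a seeded generator of diploid haplotypes, phase blocks
with switch errors, barcoded molecules, tumor subclones and copy-number
segments, with a truth set for every emitted observation, plus deterministic
scenarios reproducing the worked examples above.

## Worked example

```bash
python examples/03_mutation_pairs.py
```

prints

```
nras_like: sites 1150000 / 1152000, 4 shared barcodes
  allele-pair classes: {'REF-REF': 2, 'REF-ALT': 1, 'ALT-REF': 1, 'ALT-ALT': 0}
  pattern 1110 -> independent_subclones; per-site verdicts ['H2', 'H2']
actg1_like: sites 2500050 / 2500450, 40 shared barcodes
  allele-pair classes: {'REF-REF': 10, 'REF-ALT': 0, 'ALT-REF': 6, 'ALT-ALT': 24}
  pattern 1011 -> sequential_a_first; per-site verdicts ['H2', 'H2']
```

The first pair: both mutations sit on haplotype 2, yet of 4 shared barcodes
two carry neither mutation, one carries only the first and one only the
second — the mutations never co-occur on a molecule, so they arose
independently in sibling subclones. The second pair: 6 barcodes carry only
the first mutation and 24 carry both, never the second alone, so the first
mutation must have preceded the second.

The other scripts in `examples/` cover phase-block summaries, somatic
phasing on simulated tumors, cross-sample extension, IBD bridging and the
artifact-writing pipeline stages.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from package output alone: the shared-barcode class counts of the
two deterministic mutation-pair fixtures, the linked-allele fraction and
verdict on a 602:398 vote profile, and the exact decision boundaries of the
linked-allele majority rule (sweeping majorities of 100 votes) and of the
extension overlap minimum (sweeping unanimous overlaps), writing one JSON
object per target.

## Layout

```
src/linkedhap/
  core.py       phase-block model, phased-VCF reading, N50/summaries
  somatic.py    linked-allele + barcode phasing rules
  pairs.py      mutation-pair patterns, CN filters, SV haplotype mapping
  extend.py     switch recommendations and the parity graph
  ancestry.py   IBD segment overlap and block bridging
  simulate.py   synthetic linked-read generator and named scenarios
  io.py         VCF/TSV/MAF/BED/IBD readers and writers
  pipeline.py   stage functions writing TSV/JSON artifacts
```

See `docs/methods.md` for the model details, parameter defaults and known
limitations.
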