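"""Readers and writers for the plain-text formats around the analysis.

On-disk conventions:

* phased VCF (v4.2) — ``GT`` with ``|`` marking phased genotypes and ``PS``
  for phase-set membership (read through cyvcf2 in :mod:`linkedhap.core`; the
  writer here serves the simulator);
* barcode evidence — TSV with header ``barcode chrom pos allele hap
  phase_set``, one row per read-site observation, ``.`` for an untagged read
  or unknown phase set;
* somatic mutations — MAF (minimal columns ``Chromosome, Start_Position,
  Reference_Allele, Tumor_Seq_Allele2``, optional ``Hugo_Symbol``) or a plain
  list of ``chrom:pos:ref:alt`` lines;
* copy-number segments — BED-like TSV (0-based half-open on disk, converted
  to 1-based inclusive on read) with a ``log2_ratio`` column;
* IBD segments — Refined-IBD dialect, tab-separated ``sample1 hap1 sample2
  hap2 chrom start end LOD cM``;
* structural variants — TSV ``chrom1 pos1 chrom2 pos2 type``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from linkedhap.ancestry import IBDSegment
from linkedhap.core import PhasedVariant
from linkedhap.pairs import CNVSegment, SVCall
from linkedhap.somatic import OBS_COLUMNS, SomaticMutation

PathLike = Union[str, Path]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=linkedhap-simulate
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">
{contigs}#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_phased_vcf(
    variants: Sequence[PhasedVariant], path: PathLike, sample: str = "SAMPLE"
) -> None:
    """Minimal single-sample phased VCF writer (simulator output)."""
    chroms = sorted({v.chrom for v in variants})
    contigs = "".join(f"##contig=<ID={c}>\n" for c in chroms)
    lines = [_VCF_HEADER.format(sample=sample, contigs=contigs)]
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos)):
        if v.phased:
            gt = f"{v.hap1_allele}|{v.hap2_allele}"
            fmt, val = "GT:PS", f"{gt}:{v.phase_set}"
        else:
            fmt, val = "GT", f"{v.genotype[0]}/{v.genotype[1]}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t.\tPASS\t.\t{fmt}\t{val}\n"
        )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# barcode evidence


def write_barcode_tsv(observations: pd.DataFrame, path: PathLike) -> None:
    df = observations[OBS_COLUMNS].copy()
    df["hap"] = df["hap"].map(lambda h: "." if h == 0 else str(int(h)))
    df["phase_set"] = df["phase_set"].map(lambda p: "." if p < 0 else str(int(p)))
    df.to_csv(path, sep="\t", index=False)


def read_barcode_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"barcode": str, "chrom": str},
        na_values=["."],
        keep_default_na=False,
    )
    missing = set(OBS_COLUMNS[:5]) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: barcode table missing columns {sorted(missing)}")
    if "phase_set" not in df.columns:
        df["phase_set"] = -1
    df["hap"] = df["hap"].fillna(0).astype(int)
    df["phase_set"] = df["phase_set"].fillna(-1).astype(int)
    df["allele"] = df["allele"].astype(int)
    df["pos"] = df["pos"].astype(int)
    return df[OBS_COLUMNS]


# ---------------------------------------------------------------------------
# somatic mutations

_MAF_REQUIRED = ["Chromosome", "Start_Position", "Reference_Allele", "Tumor_Seq_Allele2"]


def write_maf(mutations: Sequence[SomaticMutation], path: PathLike) -> None:
    rows = [
        {
            "Hugo_Symbol": m.gene or "Unknown",
            "Chromosome": m.chrom,
            "Start_Position": m.pos,
            "Reference_Allele": m.ref_allele,
            "Tumor_Seq_Allele2": m.alt_allele,
        }
        for m in mutations
    ]
    pd.DataFrame(
        rows, columns=["Hugo_Symbol"] + _MAF_REQUIRED
    ).to_csv(path, sep="\t", index=False)


def read_maf(path: PathLike) -> list[SomaticMutation]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str})
    missing = set(_MAF_REQUIRED) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: MAF missing columns {sorted(missing)}")
    return [
        SomaticMutation(
            chrom=str(r.Chromosome),
            pos=int(r.Start_Position),
            ref_allele=str(r.Reference_Allele),
            alt_allele=str(r.Tumor_Seq_Allele2),
            gene=str(r.Hugo_Symbol) if "Hugo_Symbol" in df.columns else None,
        )
        for r in df.itertuples()
    ]


def read_mutation_list(path: PathLike) -> list[SomaticMutation]:
    """One ``chrom:pos:ref:alt`` per line; blank lines and ``#`` comments skipped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            chrom, pos, ref, alt = line.split(":")
        except ValueError:
            raise ValueError(f"{path}: malformed mutation line {line!r}") from None
        out.append(SomaticMutation(chrom, int(pos), ref, alt))
    return out


def read_somatic_sites(path: PathLike) -> list[SomaticMutation]:
    """Dispatch MAF vs plain-list on the header line."""
    first = Path(path).read_text().splitlines()
    first = next((l for l in first if l.strip() and not l.startswith("#")), "")
    if "Chromosome" in first:
        return read_maf(path)
    return read_mutation_list(path)


# ---------------------------------------------------------------------------
# copy-number segments (BED-like: 0-based half-open on disk)


def write_cnv_bed(segments: Sequence[CNVSegment], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tlog2_ratio\n")
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.log2_ratio}\n")


def read_cnv_bed(path: PathLike) -> list[CNVSegment]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        CNVSegment(
            chrom=str(r.chrom),
            start=int(r.start) + 1,
            end=int(r.end),
            log2_ratio=float(r.log2_ratio),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# IBD segments (Refined-IBD dialect)

_IBD_COLUMNS = [
    "sample1",
    "hap_index1",
    "sample2",
    "hap_index2",
    "chrom",
    "start",
    "end",
    "lod",
    "cm_length",
]


def write_refined_ibd(segments: Sequence[IBDSegment], path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        s.sample1,
                        s.hap_index1,
                        s.sample2,
                        s.hap_index2,
                        s.chrom,
                        s.start,
                        s.end,
                        s.lod,
                        s.cm_length,
                    )
                )
                + "\n"
            )


def read_refined_ibd(path: PathLike) -> list[IBDSegment]:
    df = pd.read_csv(
        path, sep="\t", header=None, names=_IBD_COLUMNS, dtype={"chrom": str}
    )
    return [
        IBDSegment(
            sample1=str(r.sample1),
            hap_index1=int(r.hap_index1),
            sample2=str(r.sample2),
            hap_index2=int(r.hap_index2),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            lod=float(r.lod),
            cm_length=float(r.cm_length),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# structural variants


def read_sv_tsv(path: PathLike) -> list[SVCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom1": str, "chrom2": str})
    return [
        SVCall(
            chrom1=str(r.chrom1),
            pos1=int(r.pos1),
            chrom2=str(r.chrom2),
            pos2=int(r.pos2),
            sv_type=str(getattr(r, "type", "BND")),
        )
        for r in df.itertuples()
    ]


def write_sv_tsv(svs: Sequence[SVCall], path: PathLike) -> None:
    pd.DataFrame(
        [
            {
                "chrom1": s.chrom1,
                "pos1": s.pos1,
                "chrom2": s.chrom2,
                "pos2": s.pos2,
                "type": s.sv_type,
            }
            for s in svs
        ]
    ).to_csv(path, sep="\t", index=False)
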