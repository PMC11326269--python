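"""Pipeline stages: one function per analysis step, writing portable artifacts.

Each ``run_*`` function is a thin orchestration layer over the library: it
loads the declared inputs, executes one analysis stage and writes documented
TSV/JSON artifacts into an output directory, returning the artifact paths.
Stages compose: the phase-block artifacts of :func:`run_phaseblock` are
sufficient input for every downstream stage.  Outputs are deterministic given
(inputs, config, seed); every run logs its configuration and inputs.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Union

import pandas as pd

from linkedhap import io as lio
from linkedhap.ancestry import bridge_by_ibd, bridges_table, matches_table, overlap_ibd
from linkedhap.core import (
    build_phase_blocks,
    read_phased_vcf,
    summarize_phase_blocks,
)
from linkedhap.extend import (
    ExtendConfig,
    build_graph,
    extension_stats,
    find_overlaps,
    propagate_orientation,
    recommend_switch,
    recommendations_table,
)
from linkedhap.pairs import PairAnalysisConfig, filter_pairs, pair_report
from linkedhap.simulate import SCENARIOS, scenario
from linkedhap.somatic import (
    SomaticPhasingConfig,
    phase_somatic_mutations,
    summarize_somatic_by_phase_block,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def _prepare(out_dir: PathLike) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    return out


def _checksum(path: PathLike) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _log_run(stage: str, inputs: dict, config: Optional[object] = None) -> None:
    digests = {k: _checksum(v) for k, v in inputs.items() if v is not None}
    logger.info(
        "stage=%s inputs=%s config=%s",
        stage,
        digests,
        asdict(config) if config is not None else None,
    )


def run_phaseblock(
    vcf_path: PathLike,
    out_dir: PathLike,
    region: Optional[str] = None,
) -> dict[str, Path]:
    """Construct phase blocks from a phased VCF; write the per-block table."""
    _log_run("phaseblock", {"vcf": vcf_path})
    out = _prepare(out_dir)
    variants = read_phased_vcf(str(vcf_path), region=region)
    blocks = build_phase_blocks(variants)
    summary = summarize_phase_blocks(blocks)
    blocks_path = out / "phase_blocks.tsv"
    summary.per_block.to_csv(blocks_path, sep="\t", index=False)
    return {"blocks": blocks_path}


def run_summarize(
    vcf_path: PathLike,
    out_dir: PathLike,
    region: Optional[str] = None,
) -> dict[str, Path]:
    """Per-block rows plus a JSON sidecar of global length statistics."""
    _log_run("summarize", {"vcf": vcf_path})
    out = _prepare(out_dir)
    variants = read_phased_vcf(str(vcf_path), region=region)
    summary = summarize_phase_blocks(build_phase_blocks(variants), region=region)
    blocks_path = out / "phase_blocks.tsv"
    stats_path = out / "phase_block_stats.json"
    summary.per_block.to_csv(blocks_path, sep="\t", index=False)
    stats_path.write_text(summary.to_json())
    return {"blocks": blocks_path, "stats": stats_path}


def run_somatic(
    vcf_path: PathLike,
    barcode_path: PathLike,
    mutations_path: PathLike,
    out_dir: PathLike,
    config: Optional[SomaticPhasingConfig] = None,
) -> dict[str, Path]:
    """Phase somatic mutations; write per-mutation calls and per-block summary."""
    config = config or SomaticPhasingConfig()
    _log_run(
        "somatic",
        {"vcf": vcf_path, "barcodes": barcode_path, "mutations": mutations_path},
        config,
    )
    out = _prepare(out_dir)
    variants = read_phased_vcf(str(vcf_path))
    observations = lio.read_barcode_tsv(barcode_path)
    mutations = lio.read_somatic_sites(mutations_path)
    calls = phase_somatic_mutations(mutations, observations, variants, config)
    calls_path = out / "somatic_phasing.tsv"
    pd.DataFrame(
        [
            {
                "chrom": c.site.chrom,
                "pos": c.site.pos,
                "ref": c.site.ref_allele,
                "alt": c.site.alt_allele,
                "verdict": c.verdict,
                "method": c.method,
                "h1_fraction": c.h1_fraction,
                "alt_votes_h1": c.alt_votes_h1,
                "alt_votes_h2": c.alt_votes_h2,
                "alt_reads_h1": c.alt_reads_h1,
                "alt_reads_h2": c.alt_reads_h2,
                "phase_set": -1 if c.phase_set is None else c.phase_set,
                "discordant": c.discordant,
            }
            for c in calls
        ]
    ).to_csv(calls_path, sep="\t", index=False)
    blocks = build_phase_blocks(variants)
    per_block_path = out / "somatic_by_block.tsv"
    summarize_somatic_by_phase_block(calls, blocks).to_csv(
        per_block_path, sep="\t", index=False
    )
    return {"calls": calls_path, "per_block": per_block_path}


def run_pairs(
    vcf_path: PathLike,
    barcode_path: PathLike,
    mutations_path: PathLike,
    cnv_path: PathLike,
    out_dir: PathLike,
    config: Optional[PairAnalysisConfig] = None,
    phasing_config: Optional[SomaticPhasingConfig] = None,
) -> dict[str, Path]:
    """Pairwise barcode-sharing analysis; write the pair report."""
    config = config or PairAnalysisConfig()
    _log_run(
        "pairs",
        {
            "vcf": vcf_path,
            "barcodes": barcode_path,
            "mutations": mutations_path,
            "cnv": cnv_path,
        },
        config,
    )
    out = _prepare(out_dir)
    variants = read_phased_vcf(str(vcf_path))
    observations = lio.read_barcode_tsv(barcode_path)
    mutations = lio.read_somatic_sites(mutations_path)
    cnv = lio.read_cnv_bed(cnv_path)
    calls = phase_somatic_mutations(
        mutations, observations, variants, phasing_config
    )
    calls_by_site = {c.site.key: c for c in calls}
    pairs = filter_pairs(mutations, cnv, observations, config)
    report = pair_report(pairs, observations, calls_by_site, cnv, config)
    report_path = out / "pair_report.tsv"
    report.to_csv(report_path, sep="\t", index=False)
    return {"pairs": report_path}


def run_extend(
    target_vcf: PathLike,
    reference_vcf: PathLike,
    out_dir: PathLike,
    config: Optional[ExtendConfig] = None,
) -> dict[str, Path]:
    """Switch recommendations and orientation groups for a sample pair."""
    config = config or ExtendConfig()
    _log_run("extend", {"target": target_vcf, "reference": reference_vcf}, config)
    out = _prepare(out_dir)
    target = read_phased_vcf(str(target_vcf))
    reference = read_phased_vcf(str(reference_vcf))
    overlaps = find_overlaps(target, reference)
    recs = [recommend_switch(o, config) for o in overlaps]
    graph = build_graph(recs)
    blocks = {b.key: b for b in build_phase_blocks(target)}
    groups = propagate_orientation(graph, blocks)
    rec_path = out / "switch_recommendations.tsv"
    recommendations_table(recs).to_csv(rec_path, sep="\t", index=False)
    group_rows = []
    for grp in groups:
        for t in grp.target_blocks:
            group_rows.append(
                {
                    "group_id": grp.group_id,
                    "block": repr(t),
                    "orientation": (
                        grp.orientations[t] if grp.orientations is not None else -1
                    ),
                    "consistent": grp.consistent,
                    "anchor": repr(grp.anchor),
                }
            )
    groups_path = out / "extension_groups.tsv"
    pd.DataFrame(
        group_rows, columns=["group_id", "block", "orientation", "consistent", "anchor"]
    ).to_csv(groups_path, sep="\t", index=False)
    stats_path = out / "extension_stats.tsv"
    stats = extension_stats(blocks, groups)
    stats.to_csv(stats_path, sep="\t", index=False)
    return {"recommendations": rec_path, "groups": groups_path, "stats": stats_path}


def run_ancestry(
    vcf_path: PathLike,
    ibd_path: PathLike,
    out_dir: PathLike,
    donor_vcf: Optional[PathLike] = None,
    donor_sample: Optional[str] = None,
    donor_alleles: Optional[dict] = None,
    min_informative: int = 10,
    majority: float = 0.95,
) -> dict[str, Path]:
    """IBD/phase-block matches and bridge recommendations."""
    _log_run("ancestry", {"vcf": vcf_path, "ibd": ibd_path})
    out = _prepare(out_dir)
    variants = read_phased_vcf(str(vcf_path))
    blocks = build_phase_blocks(variants)
    segments = lio.read_refined_ibd(ibd_path)
    if donor_alleles is None:
        if donor_vcf is None:
            raise ValueError("provide donor_vcf or donor_alleles")
        donor_variants = read_phased_vcf(str(donor_vcf), sample=donor_sample)
        donor_alleles = {
            (v.chrom, v.pos): (v.hap1_allele, v.hap2_allele)
            for v in donor_variants
            if v.phased
        }
    matches = overlap_ibd(segments, blocks, variants, donor_alleles)
    recs = bridge_by_ibd(matches, min_informative=min_informative, majority=majority)
    matches_path = out / "ibd_block_matches.tsv"
    bridges_path = out / "ibd_bridges.tsv"
    matches_table(matches).to_csv(matches_path, sep="\t", index=False)
    bridges_table(recs).to_csv(bridges_path, sep="\t", index=False)
    return {"matches": matches_path, "bridges": bridges_path}


def run_simulate(
    scenario_name: str,
    seed: int,
    out_dir: PathLike,
) -> dict[str, Path]:
    """Generate a named scenario bundle and write its artifacts."""
    if scenario_name not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario_name!r}; choose from {SCENARIOS}")
    logger.info("stage=simulate scenario=%s seed=%d", scenario_name, seed)
    bundle = scenario(scenario_name, seed)
    return bundle.write(_prepare(out_dir))
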