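"""Generate a full synthetic linked-read bundle and write its artifacts.

Writes the phased VCF, barcode-evidence TSV, MAF, CNV BED and truth JSON for
the 'basic' scenario, then reloads them through the pipeline stage functions.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

import pandas as pd

from linkedhap import pipeline

with TemporaryDirectory() as tmp:
    paths = pipeline.run_simulate("basic", seed=7, out_dir=Path(tmp) / "sim")
    print("artifacts:", {k: p.name for k, p in paths.items()})
    arts = pipeline.run_summarize(paths["vcf"], Path(tmp) / "out")
    blocks = pd.read_csv(arts["blocks"], sep="\t")
    print(f"\n{len(blocks)} phase blocks reconstructed from the emitted VCF")
    calls = pipeline.run_somatic(
        paths["vcf"], paths["barcodes"], paths["maf"], Path(tmp) / "out"
    )
    table = pd.read_csv(calls["calls"], sep="\t")
    print(table[["chrom", "pos", "verdict", "alt_votes_h1", "alt_votes_h2"]]
          .head().to_string(index=False))
print(
    "\nEvery artifact is plain text and versionable; identical seeds give"
    "\nbyte-identical bundles, so downstream analyses are fully reproducible."
)
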