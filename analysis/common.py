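"""Shared glue for the numbered analysis scripts: dataset paths -> pipeline config."""

from __future__ import annotations

from pathlib import Path

from episcreen.pipeline import PipelineConfig

DATASET_DIR = Path("results/dataset")


def config_for(dataset: Path, outdir: Path, seed: int) -> PipelineConfig:
    return PipelineConfig(
        gwas=str(dataset / "gwas.tsv"),
        fragments=str(dataset / "atac_fragments.bed"),
        peaks=str(dataset / "h3k27ac_peaks.bed"),
        coverage=str(dataset / "atac_coverage.bedgraph"),
        genes=str(dataset / "genes.gtf"),
        expression=str(dataset / "expression.tsv"),
        pairs=str(dataset / "pairs.tsv"),
        genome=str(dataset / "genome.fa"),
        pwms=str(dataset / "planted_motifs.jaspar"),
        outdir=str(outdir),
        seed=seed,
    )
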