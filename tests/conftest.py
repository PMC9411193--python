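"""Shared fixtures: one default synthetic dataset and one pipeline run per session."""

from __future__ import annotations

import pytest

from episcreen.pipeline import PipelineConfig, run_pipeline
from episcreen.synthetic import SimConfig, generate_dataset

SESSION_SEED = 7


@pytest.fixture(scope="session")
def sim(tmp_path_factory):
    """Default-condition synthetic dataset (the study conditions)."""
    outdir = tmp_path_factory.mktemp("simdata")
    return generate_dataset(SimConfig(seed=SESSION_SEED), outdir)


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A reduced dataset for fast unit-level checks."""
    outdir = tmp_path_factory.mktemp("simsmall")
    cfg = SimConfig(
        n_chroms=1, chrom_length=2_500_000, n_genes=60, n_nfrs=300,
        n_snps=400, depth=40_000, hub_targets=(), seed=11,
    )
    return generate_dataset(cfg, outdir)


def _pipeline_config(sim, outdir) -> PipelineConfig:
    p = sim.paths
    return PipelineConfig(
        gwas=str(p["gwas"]), fragments=str(p["fragments"]), peaks=str(p["peaks"]),
        coverage=str(p["coverage"]), genes=str(p["genes"]),
        expression=str(p["expression"]), pairs=str(p["pairs"]),
        genome=str(p["genome"]), pwms=str(p["pwms"]), outdir=str(outdir),
        seed=SESSION_SEED,
    )


@pytest.fixture(scope="session")
def pipeline_cfg(sim, tmp_path_factory):
    return _pipeline_config(sim, tmp_path_factory.mktemp("pipeout"))


@pytest.fixture(scope="session")
def pipeline_ctx(pipeline_cfg):
    """Pipeline run through the linking stage on the default dataset."""
    return run_pipeline(
        pipeline_cfg, ["load", "annotate", "enhancers", "contacts", "link"]
    )


@pytest.fixture(scope="session")
def gkm_ctx(pipeline_cfg, pipeline_ctx):
    """Adds the trained gkm model, deltaSVM scores and random-SNP background."""
    run_pipeline(pipeline_cfg, ["gkm"], pipeline_ctx)
    return pipeline_ctx
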