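"""End-to-end orchestration: annotate -> classify -> contacts -> link ->
gkm/deltaSVM -> motif gain/loss, with a single config and seeded stages.

Every output carries the config hash and seed in a header comment so a run
can be traced back to its exact settings.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import annotate as ann
from . import contacts as hic
from . import enhancers as enh
from . import gkm
from . import linking
from . import motifs as mot
from .data_model import (
    read_bed,
    read_bedgraph,
    read_expression_table,
    read_gene_models,
    read_gwas_table,
    read_jaspar_pfms,
    read_pairs,
    bin_contacts,
)

log = logging.getLogger(__name__)

STAGES = ["load", "annotate", "enhancers", "contacts", "link", "gkm", "motifs", "report"]


class PipelineError(RuntimeError):
    """A stage failure, annotated with the stage name."""


@dataclass
class PipelineConfig:
    """All thresholds and paths for one screen."""

    # inputs
    gwas: str = ""
    fragments: str = ""
    peaks: str = ""
    coverage: str = ""
    genes: str = ""
    expression: str = ""
    pairs: str = ""
    genome: str = ""
    pwms: str = ""
    outdir: str = "results"
    # variant selection / annotation
    p_max: float = 1e-3
    p_suggestive: float = 1e-6
    promoter_upstream: int = 2000
    promoter_downstream: int = 500
    # enhancer classification
    nfr_max_len: int = 100
    flank_min: int = 1000
    flank_max: int = 20000
    flank_sides: str = "any"
    # expression gate
    tpm_min: float = 0.5
    # contact significance
    bin_size: int = 10_000
    alpha: float = 0.05
    n_distance_bins: int = 100
    d_min: int | None = None
    d_max: int = 2_000_000
    short_range_cutoff: int = 5000
    # gkm / deltaSVM
    gkm_l: int = 10
    gkm_k: int = 6
    gkm_width: int = 400
    repeat_max: float = 0.70
    neg_ratio: int = 10
    svm_c: float = 1.0
    cv_folds: int = 5
    background_snps: int = 1000
    # motif gain/loss
    motif_threshold: float = 0.80
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.p_max <= 1 and 0 < self.p_suggestive <= 1):
            raise ValueError("p thresholds must be in (0,1]")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0,1)")
        if not (0 < self.motif_threshold <= 1):
            raise ValueError("motif threshold must be in (0,1]")
        if self.flank_sides not in ("any", "both"):
            raise ValueError("flank_sides must be 'any' or 'both'")

    @property
    def config_hash(self) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={config.config_hash} seed={config.seed}\n")
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def stage_load(config: PipelineConfig, ctx: dict) -> None:
    import pyfaidx

    ctx["snps"] = read_gwas_table(config.gwas)
    ctx["genes"] = read_gene_models(config.genes)
    ctx["expression"] = read_expression_table(config.expression)
    ctx["fragments"] = read_bed(config.fragments)
    ctx["peaks"] = read_bed(config.peaks)
    ctx["coverage"] = enh.StepCoverage(read_bedgraph(config.coverage))
    ctx["pairs"] = read_pairs(config.pairs)
    fa = pyfaidx.Fasta(config.genome)
    ctx["genome"] = fa
    ctx["chrom_sizes"] = {name: len(fa[name]) for name in fa.keys()}
    ctx["pwms"] = (
        [mot.Pwm.from_biopython(m) for m in read_jaspar_pfms(config.pwms)]
        if config.pwms
        else []
    )


def stage_annotate(config: PipelineConfig, ctx: dict) -> None:
    cands = ann.select_candidates(ctx["snps"], config.p_max, config.p_suggestive)
    ann.annotate_context(
        cands, ctx["genes"], config.promoter_upstream, config.promoter_downstream,
        tpm_table=ctx["expression"],
    )
    ctx["candidates"] = cands


def stage_enhancers(config: PipelineConfig, ctx: dict) -> None:
    nfrs = enh.filter_nfr_fragments(ctx["fragments"], config.nfr_max_len)
    calls = enh.classify_nfrs(
        nfrs, ctx["peaks"], config.flank_min, config.flank_max,
        coverage=ctx["coverage"], flank_sides=config.flank_sides,
    )
    ctx["ae_calls"] = calls
    ann.partition_by_epigenome(ctx["candidates"], calls)


def stage_contacts(config: PipelineConfig, ctx: dict) -> None:
    ctx["cis_trans"] = hic.cis_trans_summary(ctx["pairs"], config.short_range_cutoff)
    matrix = bin_contacts(ctx["pairs"], config.bin_size, ctx["chrom_sizes"])
    model = hic.fit_expected_model(
        matrix, config.n_distance_bins, config.d_min, config.d_max
    )
    ctx["matrix"] = matrix
    ctx["expected_model"] = model
    ctx["significant"] = hic.call_significant_contacts(matrix, model, config.alpha)


def stage_link(config: PipelineConfig, ctx: dict) -> None:
    promoters = linking.promoters_of_expressed_genes(
        ctx["genes"], ctx["expression"], config.tpm_min,
        config.promoter_upstream, config.promoter_downstream,
    )
    links, summary = linking.link_variants(
        ctx["candidates"], ctx["significant"], promoters, config.bin_size
    )
    ctx["promoters"] = promoters
    ctx["links"] = links
    ctx["link_summary"] = summary
    ctx["degrees"] = linking.degree_distributions(links)


def stage_gkm(config: PipelineConfig, ctx: dict) -> None:
    linked_rsids = {t.rsid for t in ctx["links"]}
    linked_snps = [a for a in ctx["candidates"] if a.rsid in linked_rsids]
    linked_aes = [a.host_ae for a in linked_snps if a.host_ae is not None]
    if not linked_aes:
        log.warning("no linked AEs; skipping gkm stage")
        ctx["gkm_metrics"] = {}
        ctx["delta_scores"] = []
        return
    params = gkm.GkmParams(l=config.gkm_l, k=config.gkm_k)
    training = gkm.build_training_sets(
        linked_aes, ctx["genome"], ctx["chrom_sizes"],
        width=config.gkm_width, repeat_max=config.repeat_max,
        neg_ratio=config.neg_ratio, seed=config.seed,
    )
    model, metrics = gkm.train_and_evaluate(
        training, params, C=config.svm_c, folds=config.cv_folds, seed=config.seed
    )
    background = gkm.background_deltas(
        ctx["genome"], model, ctx["chrom_sizes"], config.background_snps,
        seed=config.seed,
    )
    scores = []
    for a in linked_snps:
        delta = gkm.delta_svm(a.snp, ctx["genome"], model)
        scores.append(
            gkm.outlier_assessment(
                delta, ctx["genome"], model, ctx["chrom_sizes"],
                rsid=a.rsid, background=background,
            )
        )
    ctx["gkm_training"] = training
    ctx["gkm_model"] = model
    ctx["gkm_metrics"] = metrics
    ctx["gkm_background"] = background
    ctx["delta_scores"] = scores


def stage_motifs(config: PipelineConfig, ctx: dict) -> None:
    pwms = ctx.get("pwms") or []
    deltas = []
    if pwms:
        linked_rsids = {t.rsid for t in ctx["links"]}
        for a in ctx["candidates"]:
            if a.rsid in linked_rsids:
                deltas.append(
                    mot.motif_delta(
                        a.snp, ctx["genome"], pwms, threshold=config.motif_threshold
                    )
                )
    ctx["motif_deltas"] = deltas


def stage_report(config: PipelineConfig, ctx: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cands = ctx["candidates"]
    _write_tsv(ann.annotation_table(cands), outdir / "candidates.tsv", config)
    enh.write_ae_calls(ctx["ae_calls"], outdir / "ae_calls.bed")
    hic.write_significant_bedpe(ctx["significant"], outdir / "significant_contacts.bedpe")
    _write_tsv(
        linking.links_table(ctx["links"], ctx["expression"]),
        outdir / "links.tsv", config,
    )
    if ctx.get("delta_scores"):
        _write_tsv(
            pd.DataFrame(
                {
                    "rsid": [d.rsid for d in ctx["delta_scores"]],
                    "delta": [d.delta for d in ctx["delta_scores"]],
                    "outlier": [d.outlier for d in ctx["delta_scores"]],
                }
            ),
            outdir / "delta_scores.tsv", config,
        )
    if ctx.get("gkm_model") is not None:
        ctx["gkm_model"].to_json(outdir / "gkm_model.json")
    if ctx.get("motif_deltas"):
        mot.write_motif_delta_table(
            ctx["motif_deltas"], ctx["pwms"], outdir / "motif_delta.tsv"
        )
    by = lambda attr: {
        v: sum(1 for a in cands if getattr(a, attr) == v)
        for v in sorted({getattr(a, attr) for a in cands if getattr(a, attr)})
    }
    metrics = ctx.get("gkm_metrics") or {}
    summary = {
        "config_hash": config.config_hash,
        "seed": config.seed,
        "n_snps_total": len(ctx["snps"]),
        "n_candidates": len(cands),
        "strata": by("stratum"),
        "contexts": by("context"),
        "epigenome_classes": by("epigenome_class"),
        "n_nfrs": len(ctx["ae_calls"]),
        "n_aes": sum(1 for c in ctx["ae_calls"] if c.is_ae),
        "cis_trans": ctx["cis_trans"],
        "n_significant_contacts": int(ctx["significant"]["significant"].sum()),
        "links": ctx["link_summary"],
        "gkm": {
            k: metrics[k] for k in ("cv_auroc", "cv_aupr", "fold_auroc")
            if k in metrics
        },
        "n_delta_outliers": sum(
            1 for d in ctx.get("delta_scores", []) if d.outlier
        ),
        "n_motif_lost": sum(len(d.lost) for d in ctx.get("motif_deltas", [])),
        "n_motif_gained": sum(len(d.gained) for d in ctx.get("motif_deltas", [])),
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=1)
    ctx["summary"] = summary


_STAGE_FUNCS = {
    "load": stage_load,
    "annotate": stage_annotate,
    "enhancers": stage_enhancers,
    "contacts": stage_contacts,
    "link": stage_link,
    "gkm": stage_gkm,
    "motifs": stage_motifs,
    "report": stage_report,
}


def run_pipeline(
    config: PipelineConfig,
    stages: list[str] | None = None,
    ctx: dict | None = None,
) -> dict:
    """Run the requested stages (default: all) in dependency order.

    ``ctx`` carries intermediates between calls, so a stage-wise rerun from a
    cached context equals the monolithic run.  Stage errors re-raise as
    PipelineError naming the stage; partial outputs are retained in ctx.
    """
    ctx = ctx if ctx is not None else {}
    for name in stages if stages is not None else STAGES:
        if name not in _STAGE_FUNCS:
            raise ValueError(f"unknown stage {name!r}")
        log.info("pipeline stage: %s", name)
        try:
            _STAGE_FUNCS[name](config, ctx)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(
                f"stage {name!r} failed: {exc} "
                "(check the corresponding input paths and thresholds)"
            ) from exc
    return ctx
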