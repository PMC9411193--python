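"""Sub-threshold candidate SNP selection and annotation.

Candidates are GWAS variants below the relaxed threshold (P < 1e-3 by
default) that miss genome-wide significance.  Each candidate gets exactly one
significance stratum, one genomic context (promoter > exon > intron >
intergenic), a distance to the nearest TSS, and one epigenome class (AE /
H3K27ac-negative NFR / outside NFRs).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .data_model import ExpressionTable, GeneRecord, SnpRecord
from .enhancers import AECall, ks_two_sample

log = logging.getLogger(__name__)

Stratum = Literal["genome_wide", "suggestive", "subthreshold"]
Context = Literal["promoter", "exon", "intron", "intergenic"]
EpigenomeClass = Literal["AE", "nfr_only", "outside"]


@dataclass
class AnnotatedSnp:
    snp: SnpRecord
    stratum: Stratum
    context: Context | None = None
    tss_distance: int | None = None
    epigenome_class: EpigenomeClass | None = None
    host_gene: str | None = None
    host_tpm: float | None = None
    host_ae: AECall | None = None

    @property
    def rsid(self) -> str:
        return self.snp.rsid


def select_candidates(
    snps: Sequence[SnpRecord],
    p_max: float = 1e-3,
    p_suggestive: float = 1e-6,
    p_genome_wide: float = 5e-8,
) -> list[AnnotatedSnp]:
    """Retain SNPs with pvalue strictly below ``p_max`` and assign strata.

    ``suggestive`` means p < 1e-6 (but not genome-wide significant);
    ``subthreshold`` covers 1e-6 <= p < 1e-3.
    """
    out = []
    for s in snps:
        if s.pvalue >= p_max:
            continue
        if s.pvalue < p_genome_wide:
            stratum: Stratum = "genome_wide"
        elif s.pvalue < p_suggestive:
            stratum = "suggestive"
        else:
            stratum = "subthreshold"
        out.append(AnnotatedSnp(snp=s, stratum=stratum))
    return out


def annotate_context(
    annotated: Sequence[AnnotatedSnp],
    genes: Sequence[GeneRecord],
    promoter_upstream: int = 2000,
    promoter_downstream: int = 500,
    tpm_table: ExpressionTable | None = None,
) -> list[AnnotatedSnp]:
    """Assign one genomic context per SNP with promoter > exon > intron >
    intergenic precedence across all genes, plus the distance to the nearest
    TSS.  SNPs on chromosomes absent from the gene models become intergenic
    with no TSS distance (logged)."""
    by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tss_arrays = {
        c: (np.array(sorted(g.tss for g in gs)), gs) for c, gs in by_chrom.items()
    }
    n_orphan = 0
    for a in annotated:
        pos, chrom = a.snp.pos, a.snp.chrom
        if chrom not in by_chrom:
            a.context, a.tss_distance = "intergenic", None
            n_orphan += 1
            continue
        best: tuple[int, str, GeneRecord] | None = None  # (precedence, ctx, gene)
        rank = {"promoter": 0, "exon": 1, "intron": 2}
        for g in by_chrom[chrom]:
            prom = g.promoter(promoter_upstream, promoter_downstream)
            if prom.start <= pos < prom.end:
                ctx = "promoter"
            elif any(e.start <= pos < e.end for e in g.exons):
                ctx = "exon"
            else:
                span = g.span
                ctx = "intron" if span.start <= pos < span.end else None
            if ctx is None:
                continue
            key = (rank[ctx], abs(pos - g.tss))
            if best is None or key < (rank[best[1]], abs(pos - best[2].tss)):
                best = (rank[ctx], ctx, g)
        tss_sorted, _ = tss_arrays[chrom]
        i = np.searchsorted(tss_sorted, pos)
        cands = tss_sorted[max(0, i - 1) : i + 1]
        a.tss_distance = int(np.abs(cands - pos).min())
        if best is None:
            a.context = "intergenic"
        else:
            a.context = best[1]
            a.host_gene = best[2].gene_id
            if tpm_table is not None:
                a.host_tpm = tpm_table.get(best[2].gene_id, 0.0)
    if n_orphan:
        log.info("annotate_context: %d SNPs on chromosomes without gene models", n_orphan)
    return list(annotated)


def partition_by_epigenome(
    annotated: Sequence[AnnotatedSnp], ae_calls: Sequence[AECall]
) -> list[AnnotatedSnp]:
    """Assign the exclusive epigenome class: AE > nfr_only > outside."""
    ae_by_chrom: dict[str, list[AECall]] = {}
    for c in ae_calls:
        ae_by_chrom.setdefault(c.nfr.chrom, []).append(c)
    lookup = {}
    for chrom, calls in ae_by_chrom.items():
        calls = sorted(calls, key=lambda c: c.nfr.start)
        lookup[chrom] = (
            np.array([c.nfr.start for c in calls]),
            np.array([c.nfr.end for c in calls]),
            calls,
        )
    for a in annotated:
        a.epigenome_class = "outside"
        a.host_ae = None
        if a.snp.chrom not in lookup:
            continue
        starts, ends, calls = lookup[a.snp.chrom]
        max_len = int((ends - starts).max()) if len(starts) else 0
        hi = int(np.searchsorted(starts, a.snp.pos, side="right"))
        lo = int(np.searchsorted(starts, a.snp.pos - max_len, side="left"))
        hits = [calls[i] for i in range(lo, hi) if ends[i] > a.snp.pos]
        if not hits:
            continue
        ae_hits = [h for h in hits if h.is_ae]
        if ae_hits:
            a.epigenome_class = "AE"
            a.host_ae = ae_hits[0]
        else:
            a.epigenome_class = "nfr_only"
            a.host_ae = hits[0]
    return list(annotated)


def expression_matched_control(
    pool_tpms: Sequence[float],
    target_tpms: Sequence[float],
    n_draws: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """KS-compare target TPMs against ``n_draws`` random same-size gene sets.

    Emulates the random-gene expression control: if the targets behave like a
    random draw from the pool, the per-draw p-values are null-distributed.
    """
    pool = np.asarray(pool_tpms, dtype=float)
    target = np.asarray(target_tpms, dtype=float)
    if len(target) == 0:
        raise ValueError("target gene set is empty")
    if len(pool) < len(target):
        raise ValueError("pool smaller than target set")
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_draws):
        draw = rng.choice(pool, size=len(target), replace=False)
        d, p = ks_two_sample(draw, target)
        rows.append((i, d, p))
    return pd.DataFrame(rows, columns=["draw", "D", "pvalue"])


def annotation_table(annotated: Sequence[AnnotatedSnp]) -> pd.DataFrame:
    """One row per SNP with all annotation columns."""
    return pd.DataFrame(
        {
            "rsid": [a.rsid for a in annotated],
            "chrom": [a.snp.chrom for a in annotated],
            "pos": [a.snp.pos for a in annotated],
            "ref": [a.snp.ref for a in annotated],
            "alt": [a.snp.alt for a in annotated],
            "pvalue": [a.snp.pvalue for a in annotated],
            "odds_ratio": [a.snp.odds_ratio for a in annotated],
            "stratum": [a.stratum for a in annotated],
            "context": [a.context for a in annotated],
            "tss_distance": [a.tss_distance for a in annotated],
            "epigenome_class": [a.epigenome_class for a in annotated],
            "host_gene": [a.host_gene for a in annotated],
            "host_tpm": [a.host_tpm for a in annotated],
        }
    )
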