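"""Join SNP-bearing active enhancers to expressed-gene promoters through
significant chromatin contacts at a fixed bin size.

A link triple (SNP, AE, gene promoter) is emitted when the SNP's position
falls in one anchor bin of a significant contact, the SNP lies inside an AE,
and a promoter of an expressed gene (TPM > threshold) overlaps the other
anchor bin; both orientations of each pair are tested.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .annotate import AnnotatedSnp
from .data_model import ExpressionTable, GeneRecord, GenomicInterval
from .enhancers import AECall

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class LinkTriple:
    rsid: str
    ae: GenomicInterval
    gene_id: str
    promoter: GenomicInterval
    binA: int
    binB: int
    pvalue: float


def promoters_of_expressed_genes(
    genes: Sequence[GeneRecord],
    tpm_table: ExpressionTable,
    tpm_min: float = 0.5,
    upstream: int = 2000,
    downstream: int = 500,
) -> dict[str, GenomicInterval]:
    """One strand-oriented promoter per gene with TPM strictly above ``tpm_min``.

    Genes missing from the expression table count as TPM = 0 (logged).
    """
    missing = [g.gene_id for g in genes if g.gene_id not in tpm_table]
    if missing:
        log.info("%d genes missing from expression table; treated as TPM=0", len(missing))
    return {
        g.gene_id: g.promoter(upstream, downstream)
        for g in genes
        if tpm_table.get(g.gene_id, 0.0) > tpm_min
    }


def link_variants(
    annotated_snps: Sequence[AnnotatedSnp],
    significant: pd.DataFrame,
    promoters: Mapping[str, GenomicInterval],
    bin_size: int = 10_000,
) -> tuple[list[LinkTriple], dict[str, int]]:
    """Emit deduplicated link triples and the (n_snps, n_genes, n_links) summary.

    ``annotated_snps`` must carry epigenome classes (only AE-class SNPs link);
    ``significant`` is the output of ``call_significant_contacts`` called at
    ``bin_size`` resolution.
    """
    res = significant.attrs.get("resolution")
    if res != bin_size:
        raise ValueError(
            f"significant contacts at resolution {res}, requested bin size {bin_size}"
        )
    snp_by_bin: dict[tuple[str, int], list[AnnotatedSnp]] = defaultdict(list)
    for a in annotated_snps:
        if a.epigenome_class == "AE" and a.host_ae is not None:
            snp_by_bin[(a.snp.chrom, a.snp.pos // bin_size)].append(a)
    prom_by_bin: dict[tuple[str, int], list[str]] = defaultdict(list)
    for gid, prom in promoters.items():
        for b in range(prom.start // bin_size, (prom.end - 1) // bin_size + 1):
            prom_by_bin[(prom.chrom, b)].append(gid)
    triples: dict[tuple, LinkTriple] = {}
    sig = significant[significant["significant"]]
    for row in sig.itertuples():
        for snp_bin, prom_bin in ((row.binA, row.binB), (row.binB, row.binA)):
            snps = snp_by_bin.get((row.chrom, snp_bin), ())
            if not snps:
                continue
            gids = prom_by_bin.get((row.chrom, prom_bin), ())
            for a in snps:
                for gid in gids:
                    key = (a.rsid, gid, row.binA, row.binB)
                    if key not in triples:
                        triples[key] = LinkTriple(
                            rsid=a.rsid,
                            ae=a.host_ae.nfr,
                            gene_id=gid,
                            promoter=promoters[gid],
                            binA=row.binA,
                            binB=row.binB,
                            pvalue=row.pvalue,
                        )
    links = list(triples.values())
    summary = {
        "n_snps": len({t.rsid for t in links}),
        "n_genes": len({t.gene_id for t in links}),
        "n_links": len(links),
    }
    return links, summary


def degree_distributions(
    links: Sequence[LinkTriple],
) -> tuple[dict[str, int], dict[str, int]]:
    """Per-SNP distinct-gene counts and per-gene distinct-SNP counts."""
    snp_genes: dict[str, set[str]] = defaultdict(set)
    gene_snps: dict[str, set[str]] = defaultdict(set)
    for t in links:
        snp_genes[t.rsid].add(t.gene_id)
        gene_snps[t.gene_id].add(t.rsid)
    return (
        {r: len(gs) for r, gs in snp_genes.items()},
        {g: len(rs) for g, rs in gene_snps.items()},
    )


def links_table(
    links: Sequence[LinkTriple], tpm_table: ExpressionTable | None = None
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rsid": [t.rsid for t in links],
            "ae_chrom": [t.ae.chrom for t in links],
            "ae_start": [t.ae.start for t in links],
            "ae_end": [t.ae.end for t in links],
            "gene_id": [t.gene_id for t in links],
            "tpm": [
                tpm_table.get(t.gene_id) if tpm_table is not None else None
                for t in links
            ],
            "binA": [t.binA for t in links],
            "binB": [t.binB for t in links],
            "pvalue": [t.pvalue for t in links],
        }
    )
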