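"""Core genomic types, coordinate conventions, and standard-format I/O.

All internal coordinates are 0-based, half-open ([start, end)).  BED is native;
GTF, GWAS tables and pair files are converted on read.  Chromosome names are
normalised to the ``chrN`` form.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import sparse

log = logging.getLogger(__name__)

PAIR_COLUMNS = ["chromA", "posA", "chromB", "posB", "count"]


def normalize_chrom(name: str) -> str:
    """Normalise a chromosome name to the ``chrN`` form (``1`` -> ``chr1``)."""
    name = str(name).strip()
    if not name.lower().startswith("chr"):
        return "chr" + name
    return "chr" + name[3:]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "need 0 <= start < end"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return self.chrom == chrom and self.start <= pos < self.end


@dataclass(frozen=True)
class SnpRecord:
    """One GWAS variant: the ref allele is the non-risk, alt the risk allele."""

    rsid: str
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str
    pvalue: float
    odds_ratio: float

    def __post_init__(self):
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError(f"{self.rsid}: SNPs only (single-base alleles)")
        if self.ref.upper() == self.alt.upper():
            raise ValueError(f"{self.rsid}: ref == alt")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"{self.rsid}: pvalue {self.pvalue} not in (0,1]")
        if self.odds_ratio <= 0:
            raise ValueError(f"{self.rsid}: odds_ratio must be > 0")


@dataclass
class GeneRecord:
    """A gene with one TSS (5'-most transcript start on the gene strand)."""

    gene_id: str
    symbol: str
    chrom: str
    strand: str
    tss: int  # 0-based
    exons: list[GenomicInterval] = field(default_factory=list)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            name=self.gene_id,
            strand=self.strand,
        )

    def promoter(self, upstream: int = 2000, downstream: int = 500) -> GenomicInterval:
        """Strand-oriented promoter window around the TSS."""
        if self.strand == "+":
            start, end = self.tss - upstream, self.tss + downstream
        else:
            start, end = self.tss - downstream + 1, self.tss + upstream + 1
        return GenomicInterval(
            self.chrom, max(0, start), end, name=self.gene_id, strand=self.strand
        )


class ExpressionTable:
    """gene_id -> TPM (replicate-averaged), non-negative."""

    def __init__(self, tpm: Mapping[str, float]):
        bad = [g for g, v in tpm.items() if v < 0]
        if bad:
            raise ValueError(f"negative TPM for {bad[:3]}")
        self._tpm = dict(tpm)

    def __getitem__(self, gene_id: str) -> float:
        return self._tpm[gene_id]

    def get(self, gene_id: str, default: float = 0.0) -> float:
        return self._tpm.get(gene_id, default)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._tpm

    def __len__(self) -> int:
        return len(self._tpm)

    def items(self):
        return self._tpm.items()

    def expressed(self, tpm_min: float = 0.5) -> set[str]:
        """Gene ids with TPM strictly above ``tpm_min``."""
        return {g for g, v in self._tpm.items() if v > tpm_min}


@dataclass(frozen=True)
class ContactPair:
    """A chromatin contact between two genomic positions (canonical order)."""

    chromA: str
    posA: int
    chromB: str
    posB: int
    count: int = 1

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if (self.chromA, self.posA) > (self.chromB, self.posB):
            raise ValueError("pair not in canonical (chromA,posA) <= (chromB,posB) order")


def pairs_to_frame(pairs: Iterable[ContactPair]) -> pd.DataFrame:
    """Convert ContactPair records to the bulk DataFrame carrier."""
    rows = [(p.chromA, p.posA, p.chromB, p.posB, p.count) for p in pairs]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def frame_to_pairs(frame: pd.DataFrame) -> list[ContactPair]:
    return [
        ContactPair(r.chromA, int(r.posA), r.chromB, int(r.posB), int(r.count))
        for r in frame.itertuples()
    ]


def canonicalize_pairs(frame: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with (chromA,posA) <= (chromB,posB) on every row."""
    frame = frame.copy()
    if "count" not in frame:
        frame["count"] = 1
    cats = sorted(set(frame["chromA"]) | set(frame["chromB"]))
    code = {c: i for i, c in enumerate(cats)}
    ca = frame["chromA"].map(code).to_numpy()
    cb = frame["chromB"].map(code).to_numpy()
    pa = frame["posA"].to_numpy()
    pb = frame["posB"].to_numpy()
    flip = (ca > cb) | ((ca == cb) & (pa > pb))
    if flip.any():
        fa = frame.loc[flip, ["chromA", "posA"]].to_numpy()
        frame.loc[flip, ["chromA", "posA"]] = frame.loc[
            flip, ["chromB", "posB"]
        ].to_numpy()
        frame.loc[flip, ["chromB", "posB"]] = fa
    frame["posA"] = frame["posA"].astype(np.int64)
    frame["posB"] = frame["posB"].astype(np.int64)
    frame["count"] = frame["count"].astype(np.int64)
    return frame


class ContactMatrix:
    """Binned symmetric cis contact counts per chromosome.

    Bin index = floor(pos / resolution).  Trans (inter-chromosome) counts are
    tallied separately; they never enter the per-chromosome matrices.
    """

    def __init__(
        self,
        resolution: int,
        chrom_sizes: Mapping[str, int],
        matrices: Mapping[str, sparse.spmatrix],
        trans_count: int = 0,
    ):
        self.resolution = int(resolution)
        self.chrom_sizes = dict(chrom_sizes)
        self.matrices = {c: m.tocsr() for c, m in matrices.items()}
        self.trans_count = int(trans_count)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chrom_sizes[chrom] // self.resolution)

    @property
    def total_cis(self) -> int:
        """Total cis contact count (upper triangle + diagonal accounting)."""
        return sum(int(sparse.triu(m, k=0).sum()) for m in self.matrices.values())

    def chrom_matrix(self, chrom: str) -> sparse.csr_matrix:
        return self.matrices[chrom]


def bin_contacts(
    pairs: pd.DataFrame | Sequence[ContactPair],
    resolution: int,
    chrom_sizes: Mapping[str, int],
) -> ContactMatrix:
    """Bin contact pairs into per-chromosome symmetric sparse matrices.

    Cis pairs enter the matrices; trans pairs are tallied in ``trans_count``.
    Total cis count is conserved (upper-triangle-plus-diagonal accounting).
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0")
    if not isinstance(pairs, pd.DataFrame):
        pairs = pairs_to_frame(pairs)
    for chrom, pos_col in (("chromA", "posA"), ("chromB", "posB")):
        for c, g in pairs.groupby(chrom, observed=True):
            if c not in chrom_sizes:
                raise ValueError(f"unknown chromosome {c!r}")
            if (g[pos_col] >= chrom_sizes[c]).any() or (g[pos_col] < 0).any():
                raise ValueError(f"position beyond {c} size {chrom_sizes[c]}")
    cis_mask = pairs["chromA"].to_numpy() == pairs["chromB"].to_numpy()
    trans_count = int(pairs.loc[~cis_mask, "count"].sum())
    matrices: dict[str, sparse.spmatrix] = {}
    cis = pairs[cis_mask]
    for chrom, size in chrom_sizes.items():
        n = -(-size // resolution)
        g = cis[cis["chromA"] == chrom]
        if len(g) == 0:
            matrices[chrom] = sparse.csr_matrix((n, n), dtype=np.int64)
            continue
        i = g["posA"].to_numpy() // resolution
        j = g["posB"].to_numpy() // resolution
        w = g["count"].to_numpy()
        m = sparse.coo_matrix((w, (i, j)), shape=(n, n), dtype=np.int64)
        m = m + m.T  # symmetrise; doubles the diagonal
        d = m.diagonal() // 2
        m = m.tolil()
        m.setdiag(d)
        matrices[chrom] = m.tocsr()
    return ContactMatrix(resolution, chrom_sizes, matrices, trans_count)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_gwas_table(path: str | Path, one_based: bool = True) -> list[SnpRecord]:
    """Read a GWAS summary TSV (rsid, chrom, pos, ref, alt, pvalue, odds_ratio).

    Rows with out-of-domain p-values or indel alleles are rejected with a
    logged warning; row order is otherwise preserved.  Positions default to
    1-based (rs-table convention) and are converted to 0-based internally.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["rsid", "chrom", "pos", "ref", "alt", "pvalue", "odds_ratio"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"GWAS table missing columns: {missing}")
    records: list[SnpRecord] = []
    offset = 1 if one_based else 0
    for row in df.itertuples():
        try:
            p = float(row.pvalue)
            if not (0 < p <= 1):
                raise ValueError(f"pvalue {p} outside (0,1]")
            if len(row.ref) != 1 or len(row.alt) != 1:
                raise ValueError("indels are not supported (SNP-only pipeline)")
            records.append(
                SnpRecord(
                    rsid=row.rsid,
                    chrom=normalize_chrom(row.chrom),
                    pos=int(row.pos) - offset,
                    ref=row.ref.upper(),
                    alt=row.alt.upper(),
                    pvalue=p,
                    odds_ratio=float(row.odds_ratio),
                )
            )
        except ValueError as exc:
            log.warning("rejecting GWAS row %s: %s", row.rsid, exc)
    return records


def write_gwas_table(
    snps: Sequence[SnpRecord], path: str | Path, one_based: bool = True
) -> None:
    offset = 1 if one_based else 0
    with open(path, "w") as fh:
        fh.write("rsid\tchrom\tpos\tref\talt\tpvalue\todds_ratio\n")
        for s in snps:
            fh.write(
                f"{s.rsid}\t{s.chrom}\t{s.pos + offset}\t{s.ref}\t{s.alt}"
                f"\t{s.pvalue:.6g}\t{s.odds_ratio:.6g}\n"
            )


def _parse_gtf_attributes(text: str, lineno: int) -> dict[str, str]:
    attrs = {}
    for part in text.rstrip(";").split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        attrs[key] = value.strip().strip('"')
    return attrs


def read_gene_models(path: str | Path) -> list[GeneRecord]:
    """Read gene models from a GENCODE-dialect GTF.

    GTF 1-based inclusive spans become 0-based half-open; the TSS is the
    5'-most transcript/gene start respecting strand.  One TSS per gene.
    """
    genes: dict[str, GeneRecord] = {}
    spans: dict[str, tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"GTF line {lineno}: fewer than 9 fields")
            chrom, _, feature, start, end, _, strand, _, attr_text = fields[:9]
            if feature not in ("gene", "exon", "transcript"):
                continue
            attrs = _parse_gtf_attributes(attr_text, lineno)
            if "gene_id" not in attrs:
                raise ValueError(f"GTF line {lineno}: missing gene_id attribute")
            gid = attrs["gene_id"]
            chrom = normalize_chrom(chrom)
            s0, e0 = int(start) - 1, int(end)  # to 0-based half-open
            if gid not in genes:
                genes[gid] = GeneRecord(
                    gene_id=gid,
                    symbol=attrs.get("gene_name", gid),
                    chrom=chrom,
                    strand=strand,
                    tss=-1,
                )
                spans[gid] = (s0, e0)
            lo, hi = spans[gid]
            spans[gid] = (min(lo, s0), max(hi, e0))
            if feature == "exon":
                genes[gid].exons.append(GenomicInterval(chrom, s0, e0, name=gid))
    out = []
    for gid, gene in genes.items():
        lo, hi = spans[gid]
        gene.tss = lo if gene.strand == "+" else hi - 1
        if not gene.exons:
            gene.exons = [GenomicInterval(gene.chrom, lo, hi, name=gid)]
        gene.exons = merge_intervals(gene.exons)
        out.append(gene)
    return out


def write_gene_models(genes: Sequence[GeneRecord], path: str | Path) -> None:
    """Write gene models as a minimal GENCODE-dialect GTF."""
    with open(path, "w") as fh:
        for g in genes:
            span = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.chrom}\tepiscreen\tgene\t{span.start + 1}\t{span.end}\t."
                f"\t{g.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{g.chrom}\tepiscreen\texon\t{e.start + 1}\t{e.end}\t."
                    f"\t{g.strand}\t.\t{attrs}\n"
                )


def merge_intervals(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/abutting intervals into a disjoint sorted list."""
    out: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda x: (x.chrom, x.start, x.end)):
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            last = out.pop()
            out.append(
                GenomicInterval(
                    last.chrom, last.start, max(last.end, iv.end), name=last.name
                )
            )
        else:
            out.append(iv)
    return out


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3/BED6 into GenomicIntervals (BED is natively 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "browser", "#")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 and f[3] != "." else None
            score = float(f[4]) if len(f) > 4 and f[4] != "." else None
            strand = f[5] if len(f) > 5 and f[5] in "+-" else None
            out.append(
                GenomicInterval(
                    normalize_chrom(f[0]), int(f[1]), int(f[2]), name, score, strand
                )
            )
    return out


def write_bed(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fields = [iv.chrom, str(iv.start), str(iv.end)]
            if iv.name is not None or iv.score is not None or iv.strand is not None:
                fields.append(iv.name if iv.name is not None else ".")
                fields.append(f"{iv.score:g}" if iv.score is not None else ".")
                fields.append(iv.strand if iv.strand is not None else ".")
            fh.write("\t".join(fields) + "\n")


def read_pairs(path: str | Path, dialect: str = "pairs") -> pd.DataFrame:
    """Read contact pairs (``pairs``: chromA posA chromB posB [count], 0-based;
    ``bedpe``: chromA startA endA chromB startB endB ..., anchor midpoints used).
    """
    if dialect == "pairs":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=PAIR_COLUMNS, usecols=range(5),
        )
        if df["count"].isna().all():
            df["count"] = 1
    elif dialect == "bedpe":
        raw = pd.read_csv(path, sep="\t", comment="#", header=None)
        df = pd.DataFrame(
            {
                "chromA": raw[0],
                "posA": (raw[1] + raw[2]) // 2,
                "chromB": raw[3],
                "posB": (raw[4] + raw[5]) // 2,
                "count": raw[7] if raw.shape[1] > 7 else 1,
            }
        )
    else:
        raise ValueError(f"unknown pairs dialect {dialect!r}")
    df["chromA"] = df["chromA"].map(normalize_chrom)
    df["chromB"] = df["chromB"].map(normalize_chrom)
    return canonicalize_pairs(df)


def write_pairs(frame: pd.DataFrame, path: str | Path, dialect: str = "pairs") -> None:
    if dialect == "pairs":
        frame[PAIR_COLUMNS].to_csv(path, sep="\t", header=False, index=False)
    elif dialect == "bedpe":
        out = pd.DataFrame(
            {
                0: frame["chromA"], 1: frame["posA"], 2: frame["posA"] + 1,
                3: frame["chromB"], 4: frame["posB"], 5: frame["posB"] + 1,
                6: ".", 7: frame["count"],
            }
        )
        out.to_csv(path, sep="\t", header=False, index=False)
    else:
        raise ValueError(f"unknown pairs dialect {dialect!r}")


def read_expression_table(path: str | Path) -> ExpressionTable:
    df = pd.read_csv(path, sep="\t")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene_id in expression table")
    return ExpressionTable(dict(zip(df["gene_id"], df["tpm"].astype(float))))


def write_expression_table(table: ExpressionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\ttpm\n")
        for gid, tpm in table.items():
            fh.write(f"{gid}\t{tpm:.6g}\n")


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def fetch_sequence(fasta, interval: GenomicInterval) -> str:
    """Fetch a sequence (soft-mask case preserved) for a 0-based half-open interval.

    ``fasta`` is a ``pyfaidx.Fasta`` handle, a path, or a plain
    chrom -> sequence mapping.
    """
    import pyfaidx

    if isinstance(fasta, (str, Path)):
        fasta = pyfaidx.Fasta(str(fasta))
    if isinstance(fasta, Mapping):
        return fasta[interval.chrom][interval.start : interval.end]
    return str(fasta[interval.chrom][interval.start : interval.end])


def read_bedgraph(path: str | Path) -> pd.DataFrame:
    """Read a bedGraph coverage file (chrom, start, end, value; 0-based half-open)."""
    return pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
    )


def write_bedgraph(frame: pd.DataFrame, path: str | Path) -> None:
    frame[["chrom", "start", "end", "value"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_jaspar_pfms(path: str | Path) -> list:
    """Read JASPAR-format PFM text into Bio.motifs records (counts used downstream)."""
    from Bio import motifs

    with open(path) as fh:
        return list(motifs.parse(fh, "jaspar"))
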