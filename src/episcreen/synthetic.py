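"""Seeded synthetic dataset generator with a ground-truth manifest.

Produces a complete toy input set — soft-masked genome, gene models,
expression table, ATAC fragments and coverage, H3K27ac peaks, GWAS summary
table, and chromatin contact pairs — with planted causal structure:
functional SNPs sit inside active enhancers whose alt allele destroys a
planted transcription-factor motif, and whose enhancer loops (at a
configurable fold enrichment over the distance-decay background) to the
promoter of an expressed gene.

Everything derives from a single named random generator, so the same config
and seed reproduce the dataset byte for byte.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_model import (
    ExpressionTable,
    GeneRecord,
    GenomicInterval,
    SnpRecord,
    canonicalize_pairs,
    write_bed,
    write_bedgraph,
    write_expression_table,
    write_fasta,
    write_gene_models,
    write_gwas_table,
    write_pairs,
)
from .motifs import Pwm, revcomp, write_jaspar_pfms

log = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def default_planted_pwm() -> Pwm:
    """A 12-column PWM with four near-deterministic columns among weakly
    informative ones, so that mutating one strong column drops the relative
    score from 1.0 to below the 0.8 presence threshold."""
    consensus = "TGACGTCATTGC"
    strong_cols = {1, 4, 7, 9}
    counts = np.zeros((4, 12))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for j, b in enumerate(consensus):
        others = [i for i in range(4) if i != base_idx[b]]
        if j in strong_cols:
            counts[base_idx[b], j] = 994
            counts[others, j] = 2
        else:
            counts[base_idx[b], j] = 280
            counts[others, j] = [260, 240, 220]
    return Pwm(matrix_id="SYN0001", tf_name="PLANTED", counts=counts)


@dataclass
class SimConfig:
    """Generator settings; the defaults are the study conditions."""

    n_chroms: int = 2
    chrom_length: int = 5_000_000
    n_genes: int = 200
    tpm_mu: float = 1.0
    tpm_sigma: float = 1.5
    zero_inflation: float = 0.3
    n_nfrs: int = 1500
    class_mix: tuple[float, float, float] = (0.4, 0.5, 0.1)  # overlapped/flanked/negative
    n_snps: int = 2000
    fraction_functional: float = 0.05
    depth: int = 300_000  # cis background pairs per chromosome
    alpha: float = 1.0  # distance-decay exponent
    d0: int = 1000  # decay-law offset avoiding the d=0 singularity
    d_min: int = 10_000
    d_max: int = 2_000_000
    loop_fold: float = 8.0
    loop_d_min: int = 30_000
    loop_d_max: int = 1_500_000
    loop_bin: int = 10_000
    trans_fraction: float = 0.15
    repeat_fraction: float = 0.10
    tpm_min: float = 0.5
    hub_targets: tuple[int, ...] = (16, 30)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_chroms", "chrom_length", "n_genes", "n_nfrs", "n_snps", "depth"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("fraction_functional", "zero_inflation", "trans_fraction",
                     "repeat_fraction"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must be in [0,1]")
        if abs(sum(self.class_mix) - 1) > 1e-9:
            raise ValueError("class_mix must sum to 1")

    @property
    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}


@dataclass
class TruthManifest:
    """Ground truth for a generated dataset."""

    seed: int
    functional_rsids: list[str] = field(default_factory=list)
    loops: list[dict] = field(default_factory=list)  # rsid, gene_id, chrom, snp_pos, tss
    motif_instances: list[dict] = field(default_factory=list)
    nfr_classes: list[dict] = field(default_factory=list)
    expressed_genes: list[str] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "TruthManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SimulatedDataset:
    config: SimConfig
    chrom_sizes: dict[str, int]
    genome: dict[str, str]
    genes: list[GeneRecord]
    expression: ExpressionTable
    fragments: list[GenomicInterval]  # NFRs plus long decoy fragments
    nfrs: list[GenomicInterval]
    peaks: list[GenomicInterval]
    coverage: pd.DataFrame
    snps: list[SnpRecord]
    pairs: pd.DataFrame
    pwm: Pwm
    manifest: TruthManifest
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genome and annotation layers
# ---------------------------------------------------------------------------


def _random_genome(config: SimConfig, rng: np.random.Generator) -> dict[str, np.ndarray]:
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for chrom, size in config.chrom_sizes.items():
        arr = bases[rng.integers(0, 4, size)].copy()
        target = int(config.repeat_fraction * size)
        masked = 0
        while masked < target:
            length = int(rng.integers(500, 2000))
            start = int(rng.integers(0, size - length))
            seg = arr[start : start + length]
            newly = int((seg < 97).sum())
            arr[start : start + length] = seg | 0x20  # lowercase
            masked += newly
        genome[chrom] = arr
    return genome


def _layout_nfrs(config: SimConfig, rng: np.random.Generator):
    """Sequential cassette layout guaranteeing class-consistent truth labels.

    Negative NFRs are grouped into peak-free deserts with 21 kb margins;
    flanked gaps are drawn from U(1000, 6000) bp (inside the 1-20 kb window)
    to keep the layout feasible on the default genome.
    """
    nfrs, labels, peaks = [], [], []
    per_chrom = [config.n_nfrs // config.n_chroms] * config.n_chroms
    per_chrom[0] += config.n_nfrs - sum(per_chrom)
    for ci, (chrom, size) in enumerate(config.chrom_sizes.items()):
        n = per_chrom[ci]
        n_over = int(round(config.class_mix[0] * n))
        n_flank = int(round(config.class_mix[1] * n))
        n_neg = n - n_over - n_flank
        plan = list(rng.permutation(["o"] * n_over + ["f"] * n_flank))
        neg_at = int(rng.integers(0, len(plan) + 1))
        plan.insert(neg_at, "NEG")
        cursor = 50_000
        for item in plan:
            if item == "NEG":
                cursor += 21_000
                for _ in range(n_neg):
                    w = int(rng.integers(50, 100))
                    nfrs.append(GenomicInterval(chrom, cursor, cursor + w))
                    labels.append("negative")
                    cursor += w + int(rng.integers(1500, 4000))
                cursor += 21_000
                continue
            w = int(rng.integers(50, 100))
            if item == "o":
                peak_len = int(rng.integers(300, 801))
                peak_start = cursor
                nfr_start = peak_start + int(rng.integers(0, peak_len - 30))
                peaks.append(GenomicInterval(chrom, peak_start, peak_start + peak_len))
                nfrs.append(GenomicInterval(chrom, nfr_start, nfr_start + w))
                labels.append("overlapped")
                cursor = max(peak_start + peak_len, nfr_start + w)
            else:  # flanked
                gap = int(rng.integers(1000, 6001))
                peak_len = int(rng.integers(300, 801))
                if rng.random() < 0.5:  # peak left of NFR
                    peaks.append(GenomicInterval(chrom, cursor, cursor + peak_len))
                    nfr_start = cursor + peak_len + gap
                    nfrs.append(GenomicInterval(chrom, nfr_start, nfr_start + w))
                    cursor = nfr_start + w
                else:  # peak right of NFR
                    nfrs.append(GenomicInterval(chrom, cursor, cursor + w))
                    peak_start = cursor + w + gap
                    peaks.append(GenomicInterval(chrom, peak_start, peak_start + peak_len))
                    cursor = peak_start + peak_len
                labels.append("flanked")
            cursor += int(rng.integers(1500, 4000))
        if cursor > size - 50_000:
            raise ValueError(
                f"infeasible NFR placement: {n} NFRs need ~{cursor} bp on "
                f"{chrom} of {size} bp"
            )
    return nfrs, labels, peaks


def _make_genes(config: SimConfig, rng: np.random.Generator) -> list[GeneRecord]:
    raw = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    per_chrom[0] += config.n_genes - sum(per_chrom)
    for ci, (chrom, size) in enumerate(config.chrom_sizes.items()):
        for _ in range(per_chrom[ci]):
            span = int(rng.integers(5000, 30_000))
            start = int(rng.integers(50_000, size - 50_000 - span))
            strand = "+" if rng.random() < 0.5 else "-"
            n_ex = int(rng.integers(2, 5))
            exons = []
            pos = start
            for i in range(n_ex):
                elen = int(rng.integers(200, 1500))
                exons.append(GenomicInterval(chrom, pos, pos + elen))
                pos += elen + int(rng.integers(500, max(600, span // n_ex)))
            end = exons[-1].end
            tss = start if strand == "+" else end - 1
            raw.append((chrom, start, strand, tss, exons))
    raw.sort(key=lambda r: (r[0], r[1]))
    genes = []
    for i, (chrom, start, strand, tss, exons) in enumerate(raw):
        gid = f"G{i + 1:04d}"
        genes.append(
            GeneRecord(
                gene_id=gid, symbol=f"GENE{i + 1}", chrom=chrom, strand=strand,
                tss=tss, exons=[
                    GenomicInterval(e.chrom, e.start, e.end, name=gid) for e in exons
                ],
            )
        )
    return genes


def _make_expression(config: SimConfig, genes, rng) -> ExpressionTable:
    tpm = {}
    for g in genes:
        if rng.random() < config.zero_inflation:
            tpm[g.gene_id] = 0.0
        else:
            tpm[g.gene_id] = float(rng.lognormal(config.tpm_mu, config.tpm_sigma))
    return ExpressionTable(tpm)


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------


def _instance_relative_score(pwm: Pwm, seq: str) -> float:
    """Relative score of an exact-width instance, both strands."""
    return pwm.relative(max(pwm.score(seq), pwm.score(revcomp(seq))))


def destroying_allele_candidates(
    pwm: Pwm, ref_hi: float = 0.9, alt_lo: float = 0.8
) -> list[tuple[int, str]]:
    """(column, alt base) pairs for which the consensus scores >= ref_hi but
    the single-base substitution scores < alt_lo at the planted placement,
    strongest columns first; error when none exists."""
    cons = pwm.consensus
    if _instance_relative_score(pwm, cons) < ref_hi:
        raise ValueError("PWM consensus below the reference score floor")
    ranges = pwm._col_max - pwm._col_min
    out = []
    for col in np.argsort(-ranges):
        col = int(col)
        worst = "ACGT"[int(pwm.log_odds[:, col].argmin())]
        mutated = cons[:col] + worst + cons[col + 1 :]
        if _instance_relative_score(pwm, mutated) < alt_lo:
            out.append((col, worst))
    if not out:
        raise ValueError("PWM admits no motif-destroying allele at any position")
    return out


def choose_destroying_allele(
    pwm: Pwm, ref_hi: float = 0.9, alt_lo: float = 0.8
) -> tuple[int, str]:
    """First (column, alt base) pair from ``destroying_allele_candidates``."""
    return destroying_allele_candidates(pwm, ref_hi, alt_lo)[0]


def plant_motif_instance(
    genome: dict[str, np.ndarray],
    pwm: Pwm,
    chrom: str,
    start: int,
    strand: str,
) -> None:
    """Write the (strand-oriented) consensus into the genome, uppercase."""
    cons = pwm.consensus if strand == "+" else revcomp(pwm.consensus)
    genome[chrom][start : start + pwm.width] = np.frombuffer(
        cons.encode(), dtype=np.uint8
    )


def plant_motifs_and_alleles(
    genome: dict[str, np.ndarray],
    pwm: Pwm,
    sites: list[tuple[str, GenomicInterval]],
    rng: np.random.Generator,
) -> list[dict]:
    """Plant one motif instance inside each site (an AE NFR) and derive the
    SNP allele pair: the ref allele completes the instance (relative score
    >= 0.9), the alt allele destroys it (< 0.8).

    Returns one record per site: instance coordinates, strand, SNP position,
    ref/alt alleles, and the destroyed motif column.  The alt allele is
    verified to drop every placement covering the SNP below the presence
    threshold in its genomic flank context (placements are redrawn if the
    flanks rescue the motif).
    """
    from .motifs import _covering_max_relative

    w = pwm.width
    candidates = destroying_allele_candidates(pwm)
    flank = w - 1
    out = []
    for _, nfr in sites:
        if w > len(nfr):
            raise ValueError(f"PWM width {w} exceeds AE width {len(nfr)}")
        placed = None
        for _attempt in range(20):
            start = int(rng.integers(nfr.start, nfr.end - w + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            saved = genome[nfr.chrom][start : start + w].copy()
            plant_motif_instance(genome, pwm, nfr.chrom, start, strand)
            for col, alt_base in candidates:
                if strand == "+":
                    snp_pos, ref, alt = start + col, pwm.consensus[col], alt_base
                else:
                    snp_pos = start + (w - 1 - col)
                    ref = _COMP[pwm.consensus[col]]
                    alt = _COMP[alt_base]
                seg = (
                    genome[nfr.chrom][snp_pos - flank : snp_pos + flank + 1]
                    .tobytes().decode().upper()
                )
                alt_window = seg[:flank] + alt + seg[flank + 1 :]
                if _covering_max_relative(alt_window, flank, pwm) < 0.8:
                    placed = (start, strand, snp_pos, ref, alt, col)
                    break
            if placed:
                break
            genome[nfr.chrom][start : start + w] = saved  # undo, redraw
        if placed is None:
            raise ValueError(
                f"no destroyable motif placement inside AE "
                f"{nfr.chrom}:{nfr.start}-{nfr.end}"
            )
        start, strand, snp_pos, ref, alt, col = placed
        out.append(
            {
                "chrom": nfr.chrom, "start": start, "end": start + w,
                "strand": strand, "snp_pos": snp_pos, "ref": ref, "alt": alt,
                "destroyed_col": col,
            }
        )
    return out


# ---------------------------------------------------------------------------
# contacts
# ---------------------------------------------------------------------------


def _sample_decay_distances(
    n: int, d_min: int, d_max: int, alpha: float, d0: int, rng
) -> np.ndarray:
    """Inverse-CDF sample of d with density proportional to (d + d0)^-alpha."""
    u = rng.random(n)
    lo, hi = d_min + d0, d_max + d0
    if abs(alpha - 1.0) < 1e-12:
        d = lo * np.exp(u * np.log(hi / lo)) - d0
    else:
        a = 1.0 - alpha
        d = (u * (hi**a - lo**a) + lo**a) ** (1.0 / a) - d0
    return d.astype(np.int64)


def expected_bin_pair_count(
    d: float, n_bg: int, config: SimConfig, chrom_length: int
) -> float:
    """Approximate expected background count for one bin pair at distance d."""
    res = config.loop_bin
    lo, hi = config.d_min + config.d0, config.d_max + config.d0
    if abs(config.alpha - 1.0) < 1e-12:
        norm = np.log(hi / lo)
        f = 1.0 / ((d + config.d0) * norm)
    else:
        a = 1.0 - config.alpha
        norm = (hi**a - lo**a) / a
        f = (d + config.d0) ** (-config.alpha) / norm
    return n_bg * f * res * res / max(1, chrom_length - d)


def generate_contacts(
    config: SimConfig,
    loops: list[dict],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Background pairs with power-law distance decay, planted loops at
    ``loop_fold`` times the local expected count, and ~``trans_fraction``
    uniform cross-chromosome pairs."""
    frames = []
    chrom_sizes = config.chrom_sizes
    for chrom, size in chrom_sizes.items():
        d = _sample_decay_distances(
            config.depth, config.d_min, config.d_max, config.alpha, config.d0, rng
        )
        pos_a = (rng.random(config.depth) * (size - d)).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {"chromA": chrom, "posA": pos_a, "chromB": chrom, "posB": pos_a + d}
            )
        )
        for loop in (lp for lp in loops if lp["chrom"] == chrom):
            mu = expected_bin_pair_count(
                abs(loop["tss"] - loop["snp_pos"]), config.depth, config, size
            )
            extra = int(rng.poisson(max(0.0, (config.loop_fold - 1.0) * mu)))
            if extra == 0:
                continue
            pa = rng.integers(loop["snp_pos"] - 300, loop["snp_pos"] + 301, extra)
            pb = rng.integers(loop["tss"] - 300, loop["tss"] + 301, extra)
            pa = np.clip(pa, 0, size - 1)
            pb = np.clip(pb, 0, size - 1)
            frames.append(
                pd.DataFrame({"chromA": chrom, "posA": pa, "chromB": chrom, "posB": pb})
            )
    cis = pd.concat(frames, ignore_index=True)
    total_cis = len(cis)
    tf = config.trans_fraction
    n_trans = int(round(tf / (1 - tf) * total_cis)) if config.n_chroms > 1 else 0
    if n_trans:
        chroms = list(chrom_sizes)
        ci = rng.integers(0, len(chroms), n_trans)
        cj = rng.integers(0, len(chroms) - 1, n_trans)
        cj = np.where(cj >= ci, cj + 1, cj)
        frames.append(
            pd.DataFrame(
                {
                    "chromA": [chroms[i] for i in ci],
                    "posA": rng.integers(0, config.chrom_length, n_trans),
                    "chromB": [chroms[j] for j in cj],
                    "posB": rng.integers(0, config.chrom_length, n_trans),
                }
            )
        )
    pairs = pd.concat(frames, ignore_index=True)
    pairs["count"] = 1
    return canonicalize_pairs(pairs)


# ---------------------------------------------------------------------------
# top-level generation
# ---------------------------------------------------------------------------


def _make_coverage(nfrs, summits, rng) -> pd.DataFrame:
    rows = []
    half, step = 300, 25
    for nfr, summit in zip(nfrs, summits):
        h = float(rng.uniform(5, 15))
        for x in range(summit - half, summit + half, step):
            mid = x + step / 2
            v = h * max(0.0, 1.0 - abs(mid - summit) / half)
            if v > 0 and x >= 0:
                rows.append((nfr.chrom, x, x + step, round(v, 3)))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])


def generate_dataset(config: SimConfig, outdir: str | Path) -> SimulatedDataset:
    """Generate the complete dataset on disk plus its truth manifest.

    Deterministic given the config (including its seed); every file parses
    back through the data-model readers.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    log.info("synthetic dataset: seed=%d", config.seed)
    genome = _random_genome(config, rng)
    nfrs, labels, peaks = _layout_nfrs(config, rng)
    summits = [n.midpoint for n in nfrs]
    genes = _make_genes(config, rng)
    expression = _make_expression(config, genes, rng)
    expressed = sorted(expression.expressed(config.tpm_min))
    expressed_by_chrom: dict[str, list[GeneRecord]] = {}
    for g in genes:
        if g.gene_id in set(expressed):
            expressed_by_chrom.setdefault(g.chrom, []).append(g)

    pwm = default_planted_pwm()
    n_functional = int(round(config.n_snps * config.fraction_functional))
    ae_idx = [
        i for i, (nfr, lab) in enumerate(zip(nfrs, labels))
        if lab != "negative" and len(nfr) >= pwm.width + 4
    ]
    order = list(rng.permutation(ae_idx))
    targets_per_snp = list(config.hub_targets) + [1] * max(
        0, n_functional - len(config.hub_targets)
    )
    targets_per_snp = targets_per_snp[:n_functional]
    chosen_sites: list[tuple[int, list[GeneRecord]]] = []
    for want in targets_per_snp:
        found = None
        while order:
            i = order.pop()
            nfr = nfrs[i]
            mid = nfr.midpoint
            cands = [
                g for g in expressed_by_chrom.get(nfr.chrom, [])
                if config.loop_d_min <= abs(g.tss - mid) <= config.loop_d_max
            ]
            if len(cands) >= want:
                sel = list(rng.choice(len(cands), size=want, replace=False))
                found = (i, [cands[j] for j in sel])
                break
        if found is None:
            raise ValueError(
                f"cannot place {n_functional} functional SNPs: no AE with "
                f"{want} expressed genes in the loop distance range left"
            )
        chosen_sites.append(found)

    planted = plant_motifs_and_alleles(
        genome, pwm, [("", nfrs[i]) for i, _ in chosen_sites], rng
    )
    motif_ivs = [
        GenomicInterval(p["chrom"], p["start"], p["end"]) for p in planted
    ]

    # assemble SNPs: functional first (planted alleles), then background
    snp_rows = []  # (chrom, pos, ref, alt, pvalue, OR, functional, targets)
    for (i, target_genes), inst in zip(chosen_sites, planted):
        pval = float(10 ** rng.uniform(-6, -4))
        snp_rows.append(
            (
                inst["chrom"], inst["snp_pos"], inst["ref"], inst["alt"],
                pval, float(rng.uniform(1.1, 1.5)), True,
                [g.gene_id for g in target_genes],
            )
        )
    taken = {(r[0], r[1]) for r in snp_rows}
    chroms = list(config.chrom_sizes)
    weights = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    while len(snp_rows) < config.n_snps:
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        pos = int(rng.integers(1000, config.chrom_sizes[chrom] - 1000))
        if (chrom, pos) in taken:
            continue
        if any(iv.contains(chrom, pos) for iv in motif_ivs):
            continue
        ref = chr(genome[chrom][pos]).upper()
        alt = "ACGT".replace(ref, "")[int(rng.integers(0, 3))]
        snp_rows.append(
            (
                chrom, pos, ref, alt, float(rng.uniform(1e-9, 1.0)),
                float(rng.lognormal(0.0, 0.15)), False, [],
            )
        )
        taken.add((chrom, pos))
    snp_rows.sort(key=lambda r: (r[0], r[1]))
    snps, manifest_loops, functional_rsids = [], [], []
    gene_by_id = {g.gene_id: g for g in genes}
    for i, (chrom, pos, ref, alt, pval, oddsr, functional, target_ids) in enumerate(
        snp_rows
    ):
        rsid = f"rs{i + 1:06d}"
        snps.append(SnpRecord(rsid, chrom, pos, ref, alt, pval, oddsr))
        if functional:
            functional_rsids.append(rsid)
            for gid in target_ids:
                manifest_loops.append(
                    {
                        "rsid": rsid, "gene_id": gid, "chrom": chrom,
                        "snp_pos": pos, "tss": gene_by_id[gid].tss,
                    }
                )
    rsid_by_pos = {(s.chrom, s.pos): s.rsid for s in snps}
    motif_records = [
        dict(p, rsid=rsid_by_pos[(p["chrom"], p["snp_pos"])]) for p in planted
    ]

    coverage = _make_coverage(nfrs, summits, rng)
    pairs = generate_contacts(config, manifest_loops, rng)

    # decoy long fragments exercise the NFR length filter
    decoys = []
    for _ in range(config.n_nfrs // 10):
        chrom = chroms[int(rng.choice(len(chroms), p=weights))]
        w = int(rng.integers(100, 300))
        start = int(rng.integers(0, config.chrom_sizes[chrom] - w))
        decoys.append(GenomicInterval(chrom, start, start + w))
    fragments = sorted(nfrs + decoys, key=lambda x: (x.chrom, x.start))

    manifest = TruthManifest(
        seed=config.seed,
        functional_rsids=functional_rsids,
        loops=manifest_loops,
        motif_instances=motif_records,
        nfr_classes=[
            {"chrom": n.chrom, "start": n.start, "end": n.end, "label": lab,
             "summit": s}
            for n, lab, s in zip(nfrs, labels, summits)
        ],
        expressed_genes=expressed,
        config={**asdict(config), "pwm_id": pwm.matrix_id},
    )

    genome_str = {c: arr.tobytes().decode("ascii") for c, arr in genome.items()}
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gtf",
        "expression": outdir / "expression.tsv",
        "fragments": outdir / "atac_fragments.bed",
        "peaks": outdir / "h3k27ac_peaks.bed",
        "coverage": outdir / "atac_coverage.bedgraph",
        "gwas": outdir / "gwas.tsv",
        "pairs": outdir / "pairs.tsv",
        "pwms": outdir / "planted_motifs.jaspar",
        "manifest": outdir / "manifest.json",
    }
    write_fasta(genome_str, paths["genome"])
    write_gene_models(genes, paths["genes"])
    write_expression_table(expression, paths["expression"])
    write_bed(fragments, paths["fragments"])
    write_bed(peaks, paths["peaks"])
    write_bedgraph(coverage, paths["coverage"])
    write_gwas_table(snps, paths["gwas"])
    write_pairs(pairs, paths["pairs"])
    write_jaspar_pfms([pwm], paths["pwms"])
    manifest.to_json(paths["manifest"])
    return SimulatedDataset(
        config=config, chrom_sizes=config.chrom_sizes, genome=genome_str,
        genes=genes, expression=expression, fragments=fragments, nfrs=nfrs,
        peaks=peaks, coverage=coverage, snps=snps, pairs=pairs, pwm=pwm,
        manifest=manifest, paths=paths,
    )
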