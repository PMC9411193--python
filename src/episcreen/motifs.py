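"""PWM scanning of ref/alt windows around a SNP: lost / gained / retained motifs.

Motif presence is defined by the *relative profile score*: the log-odds score
rescaled to [0, 1] between the worst and best achievable match, with presence
at a configurable threshold (default 0.80).  By default only placements whose
window covers the SNP base count toward presence, so that a gain or loss is
attributable to the allele.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import GenomicInterval, SnpRecord, fetch_sequence

log = logging.getLogger(__name__)

BASES = "ACGT"
BASE_IDX = {b: i for i, b in enumerate(BASES)}
COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """A position frequency matrix with derived log-odds scores.

    ``counts`` is a (4, width) array over rows A, C, G, T.  A
    background-proportional pseudocount totalling ``pseudocount`` is added to
    each column before taking log-odds against the background.
    """

    matrix_id: str
    tf_name: str
    counts: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape[0] != 4:
            raise ValueError("counts must be 4 x width (rows A,C,G,T)")
        if self.width < 4:
            raise ValueError(f"{self.matrix_id}: PWM width must be >= 4")
        if (self.counts < 0).any():
            raise ValueError(f"{self.matrix_id}: negative counts")
        bg = np.asarray(self.background, dtype=float)
        self.background = bg / bg.sum()
        pc = self.pseudocount * self.background[:, None]
        freqs = (self.counts + pc) / (self.counts.sum(axis=0) + self.pseudocount)
        self.log_odds = np.log2(freqs / self.background[:, None])
        if not np.isfinite(self.log_odds).all():
            raise ValueError(f"{self.matrix_id}: non-finite log-odds")
        self._col_max = self.log_odds.max(axis=0)
        self._col_min = self.log_odds.min(axis=0)

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def smax(self) -> float:
        return float(self._col_max.sum())

    @property
    def smin(self) -> float:
        return float(self._col_min.sum())

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.log_odds.argmax(axis=0))

    @classmethod
    def from_biopython(cls, motif, **kwargs) -> "Pwm":
        counts = np.array([motif.counts[b] for b in BASES], dtype=float)
        name = getattr(motif, "name", None) or motif.matrix_id
        return cls(matrix_id=motif.matrix_id, tf_name=name, counts=counts, **kwargs)

    def score(self, seq: str) -> float:
        """Log-odds score of an exact-width sequence.

        Ambiguous bases contribute the background-weighted column average.
        """
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != width {self.width}")
        s = 0.0
        warned = False
        for j, base in enumerate(seq.upper()):
            if base in BASE_IDX:
                s += self.log_odds[BASE_IDX[base], j]
            else:
                s += float(self.background @ self.log_odds[:, j])
                warned = True
        if warned:
            log.debug("%s: ambiguous base scored with background average", self.matrix_id)
        return s

    def relative(self, raw: float) -> float:
        return (raw - self.smin) / (self.smax - self.smin)


def relative_score_scan(seq: str, pwm: Pwm) -> float:
    """Max relative score of ``pwm`` over all offsets of ``seq``, both strands."""
    if len(seq) < pwm.width:
        raise ValueError("sequence shorter than PWM width")
    best = -np.inf
    for strand_seq in (seq, revcomp(seq)):
        for off in range(len(strand_seq) - pwm.width + 1):
            best = max(best, pwm.score(strand_seq[off : off + pwm.width]))
    return pwm.relative(best)


def _covering_max_relative(window: str, snp_index: int, pwm: Pwm) -> float:
    """Max relative score among placements (both strands) covering ``snp_index``."""
    n, w = len(window), pwm.width
    best = -np.inf
    rc = revcomp(window)
    for off in range(n - w + 1):
        if off <= snp_index <= off + w - 1:
            best = max(best, pwm.score(window[off : off + w]))
        # reverse-strand placement at rc offset ``off`` spans forward
        # coordinates [n - w - off, n - off)
        fwd_start = n - w - off
        if fwd_start <= snp_index <= fwd_start + w - 1:
            best = max(best, pwm.score(rc[off : off + w]))
    if not np.isfinite(best):
        return 0.0
    return pwm.relative(best)


@dataclass
class MotifDelta:
    """Lost/gained/retained motif ids for a ref -> alt substitution."""

    rsid: str
    lost: set[str]
    gained: set[str]
    retained: set[str]
    scores: dict[str, tuple[float, float]]  # motif id -> (ref, alt) relative score


def motif_delta(
    snp: SnpRecord,
    genome,
    pwms: list[Pwm],
    threshold: float = 0.80,
    flank: int | None = None,
    require_snp_overlap: bool = True,
) -> MotifDelta:
    """Classify each PWM as lost / gained / retained for a SNP's ref -> alt change.

    A motif is *present* for an allele when its max relative score over the
    allele window reaches ``threshold``; with ``require_snp_overlap`` (default)
    only placements covering the SNP base are considered.  lost = present(ref)
    and not present(alt); gained the reverse; retained = present in both.
    """
    if not pwms:
        return MotifDelta(snp.rsid, set(), set(), set(), {})
    if flank is None:
        flank = max(p.width for p in pwms) - 1
    iv = GenomicInterval(snp.chrom, snp.pos - flank, snp.pos + flank + 1)
    if iv.start < 0:
        raise ValueError(f"{snp.rsid}: window off chromosome start")
    window = fetch_sequence(genome, iv).upper()
    if len(window) != 2 * flank + 1:
        raise ValueError(f"{snp.rsid}: window off chromosome end")
    ref_window = window[:flank] + snp.ref + window[flank + 1 :]
    alt_window = window[:flank] + snp.alt + window[flank + 1 :]
    lost, gained, retained = set(), set(), set()
    scores: dict[str, tuple[float, float]] = {}
    for pwm in pwms:
        if require_snp_overlap:
            r = _covering_max_relative(ref_window, flank, pwm)
            a = _covering_max_relative(alt_window, flank, pwm)
        else:
            r = relative_score_scan(ref_window, pwm)
            a = relative_score_scan(alt_window, pwm)
        scores[pwm.matrix_id] = (r, a)
        pref, palt = r >= threshold, a >= threshold
        if pref and not palt:
            lost.add(pwm.matrix_id)
        elif palt and not pref:
            gained.add(pwm.matrix_id)
        elif pref and palt:
            retained.add(pwm.matrix_id)
    return MotifDelta(snp.rsid, lost, gained, retained, scores)


def write_motif_delta_table(deltas: list[MotifDelta], pwms: list[Pwm], path) -> None:
    by_id = {p.matrix_id: p for p in pwms}
    with open(path, "w") as fh:
        fh.write("rsid\tmotif_id\ttf\tstatus\tref_score\talt_score\n")
        for d in deltas:
            for status, ids in (
                ("lost", d.lost), ("gained", d.gained), ("retained", d.retained)
            ):
                for mid in sorted(ids):
                    r, a = d.scores[mid]
                    fh.write(
                        f"{d.rsid}\t{mid}\t{by_id[mid].tf_name}\t{status}"
                        f"\t{r:.4f}\t{a:.4f}\n"
                    )


def write_jaspar_pfms(pwms: list[Pwm], path) -> None:
    """Write PWMs in JASPAR (2016+) PFM text format."""
    with open(path, "w") as fh:
        for p in pwms:
            fh.write(f">{p.matrix_id} {p.tf_name}\n")
            for i, base in enumerate(BASES):
                row = " ".join(f"{v:7.2f}" for v in p.counts[i])
                fh.write(f"{base}  [ {row} ]\n")
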