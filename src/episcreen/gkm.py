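"""Gapped k-mer SVM and deltaSVM allele scoring.

The gapped k-mer kernel counts shared length-``l`` words between two
sequences that agree at ``k`` informative positions: an l-mer pair with m
mismatches contributes C(l - m, k) (zero when m > l - k).  The kernel is
computed exactly, either pairwise through mismatch combinatorics or, for
Gram matrices, through an equivalent sparse gapped-feature expansion.

deltaSVM scores an allele substitution as the sum, over the l l-mers
covering the variant, of the trained model's l-mer weight difference
(alt minus ref).
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from math import comb
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .data_model import GenomicInterval, SnpRecord, fetch_sequence
from .enhancers import AECall

log = logging.getLogger(__name__)

_BASE_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
    _BASE_CODE[_b + 32] = _i  # lowercase


@dataclass(frozen=True)
class GkmParams:
    """Word length ``l`` and number of informative positions ``k``."""

    l: int = 10
    k: int = 6

    def __post_init__(self):
        if not (1 <= self.k <= self.l):
            raise ValueError(f"need 1 <= k <= l, got k={self.k}, l={self.l}")

    @property
    def mismatch_table(self) -> np.ndarray:
        """contribution C(matches, k) indexed by number of matching positions."""
        return np.array([comb(t, self.k) if t >= self.k else 0 for t in range(self.l + 1)],
                        dtype=np.float64)


def encode_lmers(seq: str, l: int) -> np.ndarray:
    """All valid (ACGT-only, case-folded) l-mers of ``seq`` as an (n, l) int8 array."""
    codes = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if len(codes) < l:
        return np.empty((0, l), dtype=np.int8)
    win = np.lib.stride_tricks.sliding_window_view(codes, l)
    return win[(win < 4).all(axis=1)]


def _onehot(lmers: np.ndarray) -> np.ndarray:
    n, l = lmers.shape
    out = np.zeros((n, 4 * l), dtype=np.float32)
    rows = np.repeat(np.arange(n), l)
    cols = np.arange(l) * 4 + lmers.astype(np.int64)
    out[rows, cols.ravel()] = 1.0
    return out


def _raw_kernel_lmers(a: np.ndarray, b: np.ndarray, params: GkmParams) -> float:
    """Exact raw kernel between two l-mer sets via mismatch combinatorics."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("sequence shorter than l (or no ACGT l-mers)")
    table = params.mismatch_table
    A, B = _onehot(a), _onehot(b)
    total = 0.0
    step = max(1, 2_000_000 // max(1, len(b)))
    for i in range(0, len(a), step):
        matches = np.rint(A[i : i + step] @ B.T).astype(np.int64)
        total += float(table[matches].sum())
    return total


def gkm_kernel(
    seq_a: str, seq_b: str, params: GkmParams = GkmParams(), normalized: bool = True
) -> float:
    """Gapped k-mer kernel between two sequences.

    Raw value is the integer sum over all l-mer pairs of C(l - m, k);
    normalised divides by sqrt(K_AA * K_BB).
    """
    a, b = encode_lmers(seq_a, params.l), encode_lmers(seq_b, params.l)
    raw = _raw_kernel_lmers(a, b, params)
    if not normalized:
        return raw
    return raw / np.sqrt(
        _raw_kernel_lmers(a, a, params) * _raw_kernel_lmers(b, b, params)
    )


def _feature_matrix(seqs: Sequence[str], params: GkmParams) -> sparse.csr_matrix:
    """Sparse gapped-feature count matrix: one row per sequence, one column per
    (position-subset, k-mer) feature.  Dot products of rows equal the raw kernel."""
    l, k = params.l, params.k
    subsets = np.array(list(itertools.combinations(range(l), k)), dtype=np.int64)
    pow4 = 4 ** np.arange(k, dtype=np.int64)
    n_subsets = len(subsets)
    n_feat = n_subsets * 4**k
    subset_base = np.arange(n_subsets, dtype=np.int64) * 4**k
    blocks = []
    chunk = 256
    for c0 in range(0, len(seqs), chunk):
        rows, cols = [], []
        for i, seq in enumerate(seqs[c0 : c0 + chunk]):
            lm = encode_lmers(seq, l).astype(np.int64)
            if len(lm) == 0:
                raise ValueError(f"sequence {c0 + i} has no valid l-mers")
            codes = lm[:, subsets.ravel()].reshape(len(lm), n_subsets, k) @ pow4
            feats = (codes + subset_base).ravel()
            rows.append(np.full(len(feats), i, dtype=np.int32))
            cols.append(feats)
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        m = sparse.coo_matrix(
            (np.ones(len(rows), dtype=np.int32), (rows, cols)),
            shape=(min(chunk, len(seqs) - c0), n_feat),
        ).tocsr()
        blocks.append(m)
    return sparse.vstack(blocks).tocsr()


def gkm_gram(
    seqs: Sequence[str], params: GkmParams = GkmParams(), normalized: bool = True
) -> np.ndarray:
    """Exact Gram matrix of the gapped k-mer kernel over ``seqs``."""
    X = _feature_matrix(seqs, params)
    G = np.asarray((X @ X.T).todense(), dtype=np.float64)
    if normalized:
        d = np.sqrt(np.diag(G))
        G = G / np.outer(d, d)
    return G


@dataclass
class TrainingSet:
    """Positive (AE) and negative (random genomic) fixed-width sequences."""

    positives: list[str]
    negatives: list[str]
    provenance: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        widths = {len(s) for s in self.positives} | {len(s) for s in self.negatives}
        if len(widths) > 1:
            raise ValueError(f"mixed sequence widths {sorted(widths)}")

    @property
    def sequences(self) -> list[str]:
        return self.positives + self.negatives

    @property
    def labels(self) -> np.ndarray:
        return np.r_[np.ones(len(self.positives)), np.zeros(len(self.negatives))]


def repeat_fraction(seq: str) -> float:
    """Soft-masked (lowercase) fraction of a sequence."""
    return sum(1 for c in seq if c.islower()) / len(seq)


def build_training_sets(
    linked_aes: Sequence[AECall],
    genome,
    chrom_sizes: Mapping[str, int],
    width: int = 400,
    repeat_max: float = 0.70,
    neg_ratio: int = 10,
    seed: int = 0,
) -> TrainingSet:
    """Positives: AEs appearing in links, recentred on the NFR summit and
    resized to ``width`` bp, with sequences more than ``repeat_max`` repeat
    (soft-masked) removed.  Negatives: ``neg_ratio`` times as many random
    genomic windows avoiding the positive intervals and N bases."""
    rng = np.random.default_rng(seed)
    pos_seqs, pos_iv = [], []
    n_shifted = n_repeat = 0
    seen = set()
    for call in linked_aes:
        key = (call.nfr.chrom, call.nfr.start, call.nfr.end)
        if key in seen:
            continue
        seen.add(key)
        start = call.summit - width // 2
        size = chrom_sizes[call.nfr.chrom]
        if start < 0 or start + width > size:
            start = min(max(0, start), size - width)
            n_shifted += 1
        iv = GenomicInterval(call.nfr.chrom, start, start + width)
        seq = fetch_sequence(genome, iv)
        if repeat_fraction(seq) > repeat_max:
            n_repeat += 1
            continue
        pos_seqs.append(seq)
        pos_iv.append(iv)
    if n_shifted:
        log.info("build_training_sets: %d windows shifted inward at chromosome ends", n_shifted)
    if n_repeat:
        log.info("build_training_sets: %d positives removed as >%d%% repeat",
                 n_repeat, int(repeat_max * 100))
    if not pos_seqs:
        raise ValueError("no positive sequences after filtering")
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] - width for c in chroms], dtype=float)
    if (weights <= 0).any():
        raise ValueError("genome too small for negative sampling")
    weights /= weights.sum()
    neg_seqs, neg_iv = [], []
    n_needed = neg_ratio * len(pos_seqs)
    attempts = 0
    while len(neg_seqs) < n_needed:
        attempts += 1
        if attempts > 100 * n_needed:
            raise ValueError("insufficient genome for negative sampling")
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        start = int(rng.integers(0, chrom_sizes[chrom] - width))
        iv = GenomicInterval(chrom, start, start + width)
        if any(iv.overlaps(p) for p in pos_iv):
            continue
        seq = fetch_sequence(genome, iv)
        if "N" in seq.upper():
            continue
        neg_seqs.append(seq)
        neg_iv.append(iv)
    return TrainingSet(
        positives=pos_seqs,
        negatives=neg_seqs,
        provenance={
            "positives": [(iv.chrom, iv.start, iv.end) for iv in pos_iv],
            "negatives": [(iv.chrom, iv.start, iv.end) for iv in neg_iv],
        },
        seed=seed,
    )


@dataclass
class GkmModel:
    """A trained gapped k-mer SVM in its dual (support-sequence) form."""

    support_seqs: list[str]
    dual_coef: np.ndarray  # signed alpha_i * y_i, one per support sequence
    bias: float
    params: GkmParams
    normalized: bool = True

    def __post_init__(self):
        self.dual_coef = np.asarray(self.dual_coef, dtype=np.float64)
        self._sv_lmers = [encode_lmers(s, self.params.l) for s in self.support_seqs]
        self._sv_onehot = _onehot(np.vstack(self._sv_lmers))
        counts = np.array([len(x) for x in self._sv_lmers])
        self._sv_edges = np.r_[0, np.cumsum(counts)][:-1]
        self._sv_selfraw = np.array(
            [_raw_kernel_lmers(x, x, self.params) for x in self._sv_lmers]
        )
        # self-kernel of a single l-mer is C(l, k)
        self._lmer_self = comb(self.params.l, self.params.k)

    def score_lmers(self, lmers: np.ndarray | Sequence[str]) -> np.ndarray:
        """Unbiased decision score w(x) for each length-l word x."""
        if not isinstance(lmers, np.ndarray):
            lmers = np.vstack([encode_lmers(s, self.params.l) for s in lmers])
        if lmers.shape[1] != self.params.l:
            raise ValueError("l-mer width mismatch")
        table = self.params.mismatch_table
        Q = _onehot(lmers)
        coef = self.dual_coef.copy()
        if self.normalized:
            coef = coef / np.sqrt(self._sv_selfraw * self._lmer_self)
        out = np.empty(len(lmers))
        step = max(1, 40_000_000 // max(1, self._sv_onehot.shape[0]))
        for i in range(0, len(lmers), step):
            matches = np.rint(Q[i : i + step] @ self._sv_onehot.T).astype(np.int64)
            w = table[matches]
            per_sv = np.add.reduceat(w, self._sv_edges, axis=1)
            out[i : i + step] = per_sv @ coef
        return out

    def decision_function(self, seqs: Sequence[str]) -> np.ndarray:
        """Full-sequence decision score (kernel expansion plus bias)."""
        out = np.empty(len(seqs))
        for i, seq in enumerate(seqs):
            q = encode_lmers(seq, self.params.l)
            ks = np.array(
                [_raw_kernel_lmers(q, sv, self.params) for sv in self._sv_lmers]
            )
            if self.normalized:
                qself = _raw_kernel_lmers(q, q, self.params)
                ks = ks / np.sqrt(self._sv_selfraw * qself)
            out[i] = ks @ self.dual_coef + self.bias
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "support_seqs": self.support_seqs,
                    "dual_coef": self.dual_coef.tolist(),
                    "bias": self.bias,
                    "l": self.params.l,
                    "k": self.params.k,
                    "normalized": self.normalized,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path) -> "GkmModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            support_seqs=d["support_seqs"],
            dual_coef=np.array(d["dual_coef"]),
            bias=d["bias"],
            params=GkmParams(l=d["l"], k=d["k"]),
            normalized=d["normalized"],
        )


def train_and_evaluate(
    training: TrainingSet,
    params: GkmParams = GkmParams(),
    C: float = 1.0,
    folds: int = 5,
    seed: int = 0,
    normalized: bool = True,
    gram: np.ndarray | None = None,
) -> tuple[GkmModel, dict]:
    """Train the SVM on the precomputed kernel and cross-validate ROC/PR.

    Returns the final model (trained on all data) and a metrics dict with
    per-fold and mean AUROC / average precision plus pooled ROC and PR curves.
    ``gram``, if given, must be the Gram matrix of ``training.sequences``.
    """
    seqs, y = training.sequences, training.labels
    G = gram if gram is not None else gkm_gram(seqs, params, normalized=normalized)

    def _fit(gram, labels):
        svc = SVC(C=C, kernel="precomputed")
        try:
            svc.fit(gram, labels)
        except Exception:
            log.warning("SVM solver failed; jittering kernel diagonal by 1e-8")
            svc = SVC(C=C, kernel="precomputed")
            svc.fit(gram + 1e-8 * np.eye(len(gram)), labels)
        return svc

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_auroc, fold_aupr = [], []
    pooled_scores = np.empty(len(y))
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        svc = _fit(G[np.ix_(train_idx, train_idx)], y[train_idx])
        scores = svc.decision_function(G[np.ix_(test_idx, train_idx)])
        pooled_scores[test_idx] = scores
        fold_auroc.append(roc_auc_score(y[test_idx], scores))
        fold_aupr.append(average_precision_score(y[test_idx], scores))
    fpr, tpr, _ = roc_curve(y, pooled_scores)
    prec, rec, _ = precision_recall_curve(y, pooled_scores)
    svc = _fit(G, y)
    model = GkmModel(
        support_seqs=[seqs[i] for i in svc.support_],
        dual_coef=svc.dual_coef_.ravel(),
        bias=float(svc.intercept_[0]),
        params=params,
        normalized=normalized,
    )
    metrics = {
        "cv_auroc": float(np.mean(fold_auroc)),
        "cv_aupr": float(np.mean(fold_aupr)),
        "fold_auroc": [float(x) for x in fold_auroc],
        "fold_aupr": [float(x) for x in fold_aupr],
        "roc": (fpr, tpr),
        "pr": (prec, rec),
    }
    return model, metrics


def lmer_weight_table(
    model: GkmModel, lmers: Sequence[str] | None = None
) -> dict[str, float]:
    """Weights w(x) for the given l-mers (default: all 4^l, which is large)."""
    l = model.params.l
    if lmers is None:
        if 4**l > 2**22:
            raise ValueError(
                f"full table has 4^{l} entries; pass an explicit l-mer list"
            )
        lmers = ["".join(p) for p in itertools.product("ACGT", repeat=l)]
    scores = model.score_lmers(list(lmers))
    return dict(zip(lmers, scores.tolist()))


@dataclass(frozen=True)
class DeltaScore:
    rsid: str
    delta: float
    q1: float | None = None
    q3: float | None = None
    lo_fence: float | None = None
    hi_fence: float | None = None
    outlier: bool | None = None


def delta_svm(
    snp: SnpRecord, genome, model: GkmModel, flank: int | None = None
) -> float:
    """deltaSVM: sum over the l l-mers covering the SNP of w(alt) - w(ref)."""
    l = model.params.l
    if flank is None:
        flank = l - 1
    iv = GenomicInterval(snp.chrom, snp.pos - flank, snp.pos + flank + 1)
    window = fetch_sequence(genome, iv).upper()
    if len(window) != 2 * flank + 1:
        raise ValueError(f"{snp.rsid}: window off chromosome end")
    if window[flank] not in (snp.ref, snp.alt):
        log.warning(
            "%s: genome base %s is neither ref %s nor alt %s",
            snp.rsid, window[flank], snp.ref, snp.alt,
        )
    ref_w = window[:flank] + snp.ref + window[flank + 1 :]
    alt_w = window[:flank] + snp.alt + window[flank + 1 :]
    ref_lm, alt_lm, skipped = _covering_lmer_pairs(ref_w, alt_w, flank, l)
    if skipped:
        log.info("%s: %d l-mers skipped (ambiguous bases)", snp.rsid, skipped)
    if len(ref_lm) == 0:
        return 0.0
    scores = model.score_lmers(np.vstack([alt_lm, ref_lm]))
    n = len(alt_lm)
    return float(scores[:n].sum() - scores[n:].sum())


def _covering_lmer_pairs(ref_w: str, alt_w: str, center: int, l: int):
    """Paired ref/alt l-mers covering the centre base; ambiguous ones skipped."""
    ref_codes = _BASE_CODE[np.frombuffer(ref_w.encode(), dtype=np.uint8)]
    alt_codes = _BASE_CODE[np.frombuffer(alt_w.encode(), dtype=np.uint8)]
    ref_list, alt_list = [], []
    skipped = 0
    for off in range(center - l + 1, center + 1):
        if off < 0 or off + l > len(ref_w):
            continue
        r = ref_codes[off : off + l]
        a = alt_codes[off : off + l]
        if (r >= 4).any() or (a >= 4).any():
            skipped += 1
            continue
        ref_list.append(r)
        alt_list.append(a)
    if not ref_list:
        return np.empty((0, l), np.int8), np.empty((0, l), np.int8), skipped
    return np.array(ref_list), np.array(alt_list), skipped


def background_deltas(
    genome,
    model: GkmModel,
    chrom_sizes: Mapping[str, int],
    n: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """deltaSVM scores of ``n`` random genomic SNPs with random alt alleles."""
    rng = np.random.default_rng(seed)
    l = model.params.l
    flank = l - 1
    chroms = list(chrom_sizes)
    weights = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    weights /= weights.sum()
    ref_all, alt_all, counts = [], [], []
    made = 0
    while made < n:
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        pos = int(rng.integers(flank, chrom_sizes[chrom] - flank - 1))
        iv = GenomicInterval(chrom, pos - flank, pos + flank + 1)
        window = fetch_sequence(genome, iv).upper()
        ref = window[flank]
        if ref not in "ACGT":
            continue
        alt = "ACGT".replace(ref, "")[rng.integers(0, 3)]
        ref_w = window
        alt_w = window[:flank] + alt + window[flank + 1 :]
        r, a, _ = _covering_lmer_pairs(ref_w, alt_w, flank, l)
        if len(r) == 0:
            continue
        ref_all.append(r)
        alt_all.append(a)
        counts.append(len(r))
        made += 1
    ref_stack, alt_stack = np.vstack(ref_all), np.vstack(alt_all)
    scores = model.score_lmers(np.vstack([alt_stack, ref_stack]))
    m = len(alt_stack)
    diff = scores[:m] - scores[m:]
    edges = np.r_[0, np.cumsum(counts)][:-1]
    return np.add.reduceat(diff, edges)


def outlier_assessment(
    delta: float,
    genome,
    model: GkmModel,
    chrom_sizes: Mapping[str, int],
    background_snps: int = 1000,
    seed: int = 0,
    rsid: str = "",
    background: np.ndarray | None = None,
) -> DeltaScore:
    """Tukey-fence outlier call of a deltaSVM score against a random-SNP
    background (delta beyond Q1 - 1.5 IQR or Q3 + 1.5 IQR)."""
    if background is None:
        background = background_deltas(genome, model, chrom_sizes, background_snps, seed)
    q1, q3 = np.percentile(background, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return DeltaScore(
        rsid=rsid, delta=float(delta), q1=float(q1), q3=float(q3),
        lo_fence=float(lo), hi_fence=float(hi),
        outlier=bool(delta < lo or delta > hi),
    )
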