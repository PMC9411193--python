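"""Distance-decay expected model and binomial significance for cis contacts.

The expected model groups mid-range cis bin pairs into equal-occupancy
distance strata, estimates a per-locus-pair contact probability in each
stratum, enforces monotone (non-increasing) decay by isotonic regression,
and renormalises.  Each observed bin pair is then tested with an exact
binomial upper tail P(X >= k) with X ~ Binomial(N, p_d); interactions with
p < 0.05 are called significant, matching the published convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, stats
from sklearn.isotonic import IsotonicRegression

from .data_model import ContactMatrix, GeneRecord, GenomicInterval
from .annotate import AnnotatedSnp
from .enhancers import AECall

log = logging.getLogger(__name__)


def cis_trans_summary(
    pairs: pd.DataFrame, short_range_cutoff: int = 5000
) -> dict[str, float]:
    """Fractions of trans, short-range cis (distance <= cutoff, inclusive) and
    long-range cis contacts; the three sum to 1."""
    if len(pairs) == 0:
        raise ValueError("no contact pairs")
    w = pairs["count"].to_numpy(dtype=float)
    cis = pairs["chromA"].to_numpy() == pairs["chromB"].to_numpy()
    dist = np.abs(pairs["posB"].to_numpy() - pairs["posA"].to_numpy())
    total = w.sum()
    trans = w[~cis].sum() / total
    cis_short = w[cis & (dist <= short_range_cutoff)].sum() / total
    cis_long = w[cis & (dist > short_range_cutoff)].sum() / total
    return {"trans": trans, "cis_short": cis_short, "cis_long": cis_long}


@dataclass
class ExpectedModel:
    """Distance-stratified expected contact probability per locus pair."""

    resolution: int
    offsets: np.ndarray  # bin-index offsets covered by the model
    prob: np.ndarray  # per-offset probability per locus pair (monotone)
    locus_pairs: np.ndarray  # number of possible locus pairs per offset
    n_total: int  # informative cis contact count N
    d_min: int
    d_max: int
    n_strata: int

    def prob_at(self, offset: int) -> float:
        i = np.searchsorted(self.offsets, offset)
        if i >= len(self.offsets) or self.offsets[i] != offset:
            raise KeyError(f"offset {offset} outside model range")
        return float(self.prob[i])


def _diagonal_counts(matrix: ContactMatrix, offsets: np.ndarray):
    """Observed contact count and locus-pair count per distance offset."""
    counts = np.zeros(len(offsets), dtype=np.int64)
    pairs = np.zeros(len(offsets), dtype=np.int64)
    for chrom, m in matrix.matrices.items():
        n = matrix.n_bins(chrom)
        for idx, o in enumerate(offsets):
            if o < n:
                counts[idx] += int(m.diagonal(int(o)).sum())
                pairs[idx] += n - o
    return counts, pairs


def fit_expected_model(
    matrix: ContactMatrix,
    n_bins: int = 100,
    d_min: int | None = None,
    d_max: int = 2_000_000,
) -> ExpectedModel:
    """Fit the equal-occupancy, isotonic distance-decay expected model.

    ``d_min`` defaults to twice the resolution, excluding self and adjacent
    bins (mid-range contacts only).
    """
    res = matrix.resolution
    if d_min is None:
        d_min = 2 * res
    if d_min >= d_max:
        raise ValueError("d_min must be < d_max")
    o_min = max(1, -(-d_min // res))
    o_max = d_max // res
    offsets = np.arange(o_min, o_max + 1)
    counts, locus_pairs = _diagonal_counts(matrix, offsets)
    keep = locus_pairs > 0
    offsets, counts, locus_pairs = offsets[keep], counts[keep], locus_pairs[keep]
    n_total = int(counts.sum())
    if n_total == 0:
        raise ValueError("no informative cis contacts in distance range")
    if len(offsets) < n_bins:
        log.warning(
            "fit_expected_model: only %d distance offsets, reducing n_bins from %d",
            len(offsets), n_bins,
        )
        n_bins = len(offsets)
    if n_bins == len(offsets):
        stratum = np.arange(len(offsets))
    else:
        # equal-occupancy strata: ~N/n_bins contacts per stratum
        cum = np.cumsum(counts)
        edges = np.searchsorted(
            cum, np.linspace(0, n_total, n_bins + 1)[1:-1], side="left"
        )
        stratum = np.zeros(len(offsets), dtype=int)
        for e in edges:
            stratum[e + 1 :] += 1
        _, stratum = np.unique(stratum, return_inverse=True)
    n_strata = stratum.max() + 1
    raw = np.zeros(n_strata)
    sdist = np.zeros(n_strata)
    spairs = np.zeros(n_strata)
    for s in range(n_strata):
        m = stratum == s
        spairs[s] = locus_pairs[m].sum()
        raw[s] = counts[m].sum() / n_total / spairs[s]
        sdist[s] = np.average(offsets[m] * res, weights=locus_pairs[m])
    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    fitted = iso.fit_transform(sdist, raw, sample_weight=spairs)
    fitted = np.clip(fitted, 0, None)
    prob = fitted[stratum]
    norm = float((prob * locus_pairs).sum())
    if norm <= 0:
        raise ValueError("degenerate expected model (all-zero probabilities)")
    prob = prob / norm
    return ExpectedModel(
        resolution=res, offsets=offsets, prob=prob, locus_pairs=locus_pairs,
        n_total=n_total, d_min=d_min, d_max=d_max, n_strata=n_strata,
    )


def binomial_pvalue(k, n: int, p) -> np.ndarray:
    """Exact upper-tail P(X >= k), X ~ Binomial(n, p); k = 0 gives 1."""
    k = np.asarray(k)
    return np.where(k <= 0, 1.0, stats.binom.sf(k - 1, n, p))


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def call_significant_contacts(
    matrix: ContactMatrix,
    model: ExpectedModel,
    alpha: float = 0.05,
    fdr: float | None = None,
) -> pd.DataFrame:
    """Binomial upper-tail test for every observed bin pair in the model range.

    Returns a frame (chrom, binA, binB, observed, expected_p, pvalue,
    significant[, qvalue]); ``significant`` means p < alpha, or BH q < fdr
    when ``fdr`` is given.  Pairs outside the distance range are skipped and
    counted in the log.
    """
    if model.resolution != matrix.resolution:
        raise ValueError("model fitted at a different resolution")
    frames = []
    skipped = 0
    o_min, o_max = model.offsets[0], model.offsets[-1]
    for chrom, m in matrix.matrices.items():
        coo = sparse.triu(m, k=1).tocoo()
        off = coo.col - coo.row
        in_range = (off >= o_min) & (off <= o_max)
        skipped += int((~in_range).sum())
        if in_range.any():
            idx = np.searchsorted(model.offsets, off[in_range])
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": chrom,
                        "binA": coo.row[in_range].astype(int),
                        "binB": coo.col[in_range].astype(int),
                        "observed": coo.data[in_range].astype(int),
                        "expected_p": model.prob[idx],
                    }
                )
            )
    if skipped:
        log.info("call_significant_contacts: %d bin pairs outside distance range", skipped)
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(
            columns=["chrom", "binA", "binB", "observed", "expected_p"]
        )
    if len(df):
        df["pvalue"] = binomial_pvalue(
            df["observed"].to_numpy(), model.n_total, df["expected_p"].to_numpy()
        )
    else:
        df["pvalue"] = pd.Series(dtype=float)
    if fdr is not None:
        df["qvalue"] = bh_adjust(df["pvalue"].to_numpy()) if len(df) else np.nan
        df["significant"] = df["qvalue"] < fdr
    else:
        df["significant"] = df["pvalue"] < alpha
    df.attrs["resolution"] = matrix.resolution
    return df


def compartment_eigenvector(
    matrix: ContactMatrix,
    genes: Sequence[GeneRecord] | None = None,
    min_bins: int = 10,
) -> dict[str, pd.DataFrame]:
    """A/B compartment calls from the leading eigenvector of the O/E Pearson
    correlation matrix, per chromosome.

    The sign is oriented so that the positive (A) class has the higher gene
    density when gene models are supplied; zero-coverage bins get label None.
    Returns per-chromosome frames (bin, value, label, strength).
    """
    out = {}
    for chrom, m in matrix.matrices.items():
        n = matrix.n_bins(chrom)
        if n < min_bins:
            continue
        dense = np.asarray(m.todense(), dtype=float)
        cov = dense.sum(axis=1)
        good = cov > 0
        if good.sum() < min_bins:
            continue
        # observed / expected by distance
        oe = np.ones_like(dense)
        for o in range(n):
            d = np.diagonal(dense, o)
            mu = d.mean()
            if mu > 0:
                idx = np.arange(n - o)
                oe[idx, idx + o] = d / mu
                oe[idx + o, idx] = d / mu
        sub = oe[np.ix_(good, good)]
        if np.allclose(sub, sub.flat[0]):
            raise ValueError(f"{chrom}: no compartment signal (constant matrix)")
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(sub)
        corr = np.nan_to_num(corr)
        evals, evecs = np.linalg.eigh(corr)
        lead = np.argmax(np.abs(evals))
        strength = float(np.abs(evals[lead]) / np.abs(evals).sum())
        vec = evecs[:, lead]
        if genes is not None:
            density = np.zeros(n)
            for g in genes:
                if g.chrom == chrom and 0 <= g.tss // matrix.resolution < n:
                    density[g.tss // matrix.resolution] += 1
            dsub = density[good]
            pos_density = dsub[vec > 0].mean() if (vec > 0).any() else 0.0
            neg_density = dsub[vec < 0].mean() if (vec < 0).any() else 0.0
            if pos_density < neg_density:
                vec = -vec
        elif vec.sum() < 0:
            vec = -vec
        values = np.full(n, np.nan)
        values[good] = vec
        labels = np.where(np.isnan(values), None, np.where(values > 0, "A", "B"))
        out[chrom] = pd.DataFrame(
            {"bin": np.arange(n), "value": values, "label": labels}
        )
        out[chrom].attrs["strength"] = strength
        if strength < 0.2:
            log.warning("%s: weak compartment signal (strength %.3f)", chrom, strength)
    return out


@dataclass(frozen=True)
class CaptureResult:
    snps_per_interaction: float
    aes_per_interaction: float
    n_interactions: int


def capture_per_interaction(
    significant: pd.DataFrame,
    snps: Sequence[AnnotatedSnp],
    aes: Sequence[AECall],
    bin_size: int,
) -> CaptureResult:
    """Distinct candidate SNPs and AEs captured per significant interaction
    after expanding each anchor symmetrically about its centre to ``bin_size``."""
    sig = significant[significant["significant"]]
    n = len(sig)
    if n == 0:
        raise ValueError("no significant interactions")
    res = significant.attrs.get("resolution")
    if res is None:
        raise ValueError("significant-contact frame lacks resolution metadata")
    anchors: dict[str, list[tuple[int, int]]] = {}
    for row in sig.itertuples():
        for b in (row.binA, row.binB):
            center = b * res + res // 2
            anchors.setdefault(row.chrom, []).append(
                (center - bin_size // 2, center + bin_size // 2)
            )
    merged: dict[str, list[tuple[int, int]]] = {}
    for chrom, ivs in anchors.items():
        ivs.sort()
        acc = []
        for s, e in ivs:
            if acc and s <= acc[-1][1]:
                acc[-1] = (acc[-1][0], max(acc[-1][1], e))
            else:
                acc.append((s, e))
        merged[chrom] = acc

    def _covered(chrom: str, start: int, end: int) -> bool:
        ivs = merged.get(chrom)
        if not ivs:
            return False
        starts = np.array([s for s, _ in ivs])
        i = np.searchsorted(starts, end, side="left")
        return any(ivs[j][1] > start for j in range(max(0, i - 2), i))

    n_snps = sum(1 for a in snps if _covered(a.snp.chrom, a.snp.pos, a.snp.pos + 1))
    n_aes = sum(1 for c in aes if _covered(c.nfr.chrom, c.nfr.start, c.nfr.end))
    return CaptureResult(n_snps / n, n_aes / n, n)


def relative_ability(a: CaptureResult, b: CaptureResult) -> tuple[float, float]:
    """Elementwise ratio of per-interaction capture (SNPs, AEs) of A over B."""
    return (
        a.snps_per_interaction / b.snps_per_interaction,
        a.aes_per_interaction / b.aes_per_interaction,
    )


def write_significant_bedpe(significant: pd.DataFrame, path) -> None:
    """Significant contacts as BEDPE with the p-value in the score column."""
    res = significant.attrs.get("resolution", 1)
    sig = significant[significant["significant"]]
    with open(path, "w") as fh:
        for r in sig.itertuples():
            fh.write(
                f"{r.chrom}\t{r.binA * res}\t{(r.binA + 1) * res}"
                f"\t{r.chrom}\t{r.binB * res}\t{(r.binB + 1) * res}"
                f"\t.\t{r.pvalue:.3e}\n"
            )
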