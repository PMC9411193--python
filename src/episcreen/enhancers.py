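"""Classify nucleosome-free regions (NFRs) into active-enhancer classes.

An NFR (ATAC fragment shorter than 100 bp) is *overlapped* when it intersects
an H3K27ac peak by at least 1 bp, *flanked* when it lies 1-20 kb (edge to
edge) from the nearest peak, and *negative* otherwise.  Active enhancers /
promoters (AEs) are the union of the overlapped and flanked classes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import GenomicInterval

log = logging.getLogger(__name__)

Label = Literal["overlapped", "flanked", "negative"]


@dataclass(frozen=True)
class AECall:
    """An NFR with its activity class and ATAC-signal summit."""

    nfr: GenomicInterval
    label: Label
    summit: int
    nearest_peak_gap: int | None = None

    def __post_init__(self):
        if not (self.nfr.start <= self.summit < self.nfr.end):
            raise ValueError("summit outside NFR")

    @property
    def is_ae(self) -> bool:
        return self.label in ("overlapped", "flanked")


class StepCoverage:
    """Piecewise-constant coverage from a bedGraph frame, with exact integrals."""

    def __init__(self, bedgraph: pd.DataFrame):
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, g in bedgraph.groupby("chrom"):
            g = g.sort_values("start")
            starts = g["start"].to_numpy(dtype=np.int64)
            ends = g["end"].to_numpy(dtype=np.int64)
            values = g["value"].to_numpy(dtype=float)
            if (values < 0).any():
                raise ValueError("coverage must be non-negative")
            self._chrom[chrom] = (starts, ends, values)

    def argmax(self, chrom: str, start: int, end: int) -> int | None:
        """Leftmost position of maximal coverage in [start, end); None if zero."""
        if chrom not in self._chrom:
            return None
        starts, ends, values = self._chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        best_v, best_pos = 0.0, None
        for i in range(lo, hi):
            if values[i] > best_v:
                best_v = values[i]
                best_pos = max(starts[i], start)
        return best_pos

    def integral(self, chrom: str, start: int, end: int) -> float:
        """Exact integral of coverage over [start, end); zero outside segments."""
        if chrom not in self._chrom or end <= start:
            return 0.0
        starts, ends, values = self._chrom[chrom]
        lo = np.searchsorted(ends, start, side="right")
        hi = np.searchsorted(starts, end, side="left")
        total = 0.0
        for i in range(lo, hi):
            total += values[i] * max(
                0, min(ends[i], end) - max(starts[i], start)
            )
        return total


def filter_nfr_fragments(
    fragments: Sequence[GenomicInterval], max_len: int = 100
) -> list[GenomicInterval]:
    """Keep fragments strictly shorter than ``max_len`` bp (NFR definition)."""
    return [f for f in fragments if len(f) < max_len]


def classify_nfrs(
    nfrs: Sequence[GenomicInterval],
    peaks: Sequence[GenomicInterval],
    flank_min: int = 1000,
    flank_max: int = 20000,
    coverage: StepCoverage | pd.DataFrame | None = None,
    flank_sides: Literal["any", "both"] = "any",
) -> list[AECall]:
    """Label every NFR exactly once: overlapped > flanked > negative.

    ``flanked`` requires no overlap and an edge-to-edge gap to the nearest
    peak in [flank_min, flank_max] (on at least one side by default; set
    ``flank_sides='both'`` for the two-sided reading).  Summits come from the
    ATAC coverage argmax inside the NFR (leftmost tie, midpoint fallback).
    """
    if isinstance(coverage, pd.DataFrame):
        coverage = StepCoverage(coverage)
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom in {p.chrom for p in peaks}:
        cp = sorted((p.start, p.end) for p in peaks if p.chrom == chrom)
        by_chrom[chrom] = (
            np.array([s for s, _ in cp], dtype=np.int64),
            np.array([e for _, e in cp], dtype=np.int64),
        )
    calls: list[AECall] = []
    for nfr in nfrs:
        summit = None
        if coverage is not None:
            summit = coverage.argmax(nfr.chrom, nfr.start, nfr.end)
        if summit is None:
            summit = nfr.midpoint
        left_gap = right_gap = None
        overlap = False
        if nfr.chrom in by_chrom:
            starts, ends = by_chrom[nfr.chrom]
            overlap = bool(np.any((starts < nfr.end) & (ends > nfr.start)))
            if not overlap and len(starts):
                left = ends[ends <= nfr.start]
                right = starts[starts >= nfr.end]
                if len(left):
                    left_gap = int(nfr.start - left.max())
                if len(right):
                    right_gap = int(right.min() - nfr.end)
        gaps = [g for g in (left_gap, right_gap) if g is not None]
        nearest = min(gaps) if gaps else None
        if overlap:
            label, nearest = "overlapped", None
        elif nearest is not None:
            if flank_sides == "any":
                flanked = flank_min <= nearest <= flank_max
            else:
                flanked = (
                    left_gap is not None
                    and right_gap is not None
                    and flank_min <= left_gap <= flank_max
                    and flank_min <= right_gap <= flank_max
                )
            label = "flanked" if flanked else "negative"
        else:
            label = "negative"
        calls.append(AECall(nfr=nfr, label=label, summit=summit, nearest_peak_gap=nearest))
    return calls


def aggregate_signal(
    calls: Sequence[AECall],
    coverage: StepCoverage | pd.DataFrame,
    window: int = 2000,
    nbins: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Summit-centred signal matrix (rows = NFRs, columns = nbins) + mean profile.

    Each column is the mean coverage over a window/nbins-bp bin across
    [summit - window/2, summit + window/2); out-of-bounds bins are zero-filled.
    """
    if isinstance(coverage, pd.DataFrame):
        coverage = StepCoverage(coverage)
    half = window // 2
    width = window / nbins
    matrix = np.zeros((len(calls), nbins))
    clipped = 0
    for r, call in enumerate(calls):
        lo = call.summit - half
        if lo < 0:
            clipped += 1
        for b in range(nbins):
            a = lo + b * width
            z = lo + (b + 1) * width
            a_c, z_c = max(0, a), max(0, z)
            if z_c > a_c:
                matrix[r, b] = coverage.integral(
                    call.nfr.chrom, int(round(a_c)), int(round(z_c))
                ) / (z - a)
    if clipped:
        log.info("aggregate_signal: %d windows clipped at chromosome start", clipped)
    return matrix, matrix.mean(axis=0) if len(calls) else np.zeros(nbins)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D, two-sided p).

    Uses the exact null distribution for small samples and the asymptotic
    approximation otherwise.
    """
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("ks_two_sample needs >= 2 observations per sample")
    res = stats.ks_2samp(a, b, method="auto")
    return float(res.statistic), float(res.pvalue)


def write_ae_calls(calls: Sequence[AECall], path) -> None:
    """Write AE calls as BED6 with the class label in the name field."""
    with open(path, "w") as fh:
        for c in calls:
            fh.write(
                f"{c.nfr.chrom}\t{c.nfr.start}\t{c.nfr.end}\t{c.label}"
                f"\t{c.summit}\t.\n"
            )


def read_ae_calls(path) -> list[AECall]:
    calls = []
    with open(path) as fh:
        for line in fh:
            f = line.rstrip("\n").split("\t")
            calls.append(
                AECall(
                    nfr=GenomicInterval(f[0], int(f[1]), int(f[2])),
                    label=f[3],
                    summit=int(f[4]),
                )
            )
    return calls
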