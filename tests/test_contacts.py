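"""Cis/trans summaries, expected model, binomial calls, compartments, capture."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from episcreen.annotate import partition_by_epigenome, select_candidates
from episcreen.contacts import (
    CaptureResult,
    binomial_pvalue,
    bh_adjust,
    call_significant_contacts,
    capture_per_interaction,
    cis_trans_summary,
    compartment_eigenvector,
    fit_expected_model,
    relative_ability,
)
from episcreen.data_model import (
    ContactMatrix,
    GeneRecord,
    GenomicInterval,
    SnpRecord,
    bin_contacts,
)
from episcreen.enhancers import AECall
from episcreen.synthetic import SimConfig, generate_contacts


def frame(rows):
    return pd.DataFrame(rows, columns=["chromA", "posA", "chromB", "posB", "count"])


def binom_tail_oracle(k: int, n: int, p: float) -> float:
    """Exact direct summation of P(X >= k) = 1 - sum_{i<k} C(n,i) p^i q^(n-i)
    in integer arithmetic: the float p is m/2^s exactly, so every term is a
    rational with denominator 2^(s n); the final subtraction and the single
    conversion to float are exact up to one correctly-rounded step."""
    from fractions import Fraction

    if k <= 0:
        return 1.0
    m, two_s = p.as_integer_ratio()  # denominator is a power of two
    s = two_s.bit_length() - 1
    qm = two_s - m
    acc = 0
    qm_pow = qm**n  # q^(n-i) numerators, i ascending
    m_pow = 1
    for i in range(k):
        acc += math.comb(n, i) * m_pow * qm_pow
        qm_pow //= qm  # exact: qm_pow always holds qm^(n-i)
        m_pow *= m
    return float(1 - Fraction(acc, 1 << (s * n)))


class TestCisTrans:
    def test_all_long_cis(self):
        df = frame([("chr1", 0, "chr1", 6000 + i, 1) for i in range(5)])
        s = cis_trans_summary(df)
        assert (s["trans"], s["cis_short"], s["cis_long"]) == (0, 0, 1)

    def test_trans_fraction_counting(self):
        rows = [("chr1", 0, "chr2", 50, 1)] * 3 + [("chr1", 0, "chr1", 9000, 1)] * 17
        s = cis_trans_summary(frame(rows))
        assert s["trans"] == pytest.approx(0.15)
        assert sum(s.values()) == pytest.approx(1.0)

    def test_exactly_5kb_is_short_range(self):
        s = cis_trans_summary(frame([("chr1", 0, "chr1", 5000, 1)]))
        assert s["cis_short"] == 1.0

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            cis_trans_summary(frame([]))


class TestBinomial:
    def test_worked_example(self):
        # 1 - sum_{i<3} C(10,i) 0.1^i 0.9^(10-i)
        assert binomial_pvalue(3, 10, 0.1) == pytest.approx(0.0702, abs=5e-5)

    def test_zero_count_gives_one(self):
        assert binomial_pvalue(0, 10, 0.1) == 1.0

    def test_matches_direct_summation(self):
        # brute-force oracle: exact tail sum with fsum, k <= 50
        rng = np.random.default_rng(4)
        for _ in range(60):
            n = int(rng.integers(100, 5000))
            p = float(rng.uniform(1e-5, 0.05))
            k = int(rng.integers(1, 51))
            oracle = binom_tail_oracle(k, n, p)
            assert abs(float(binomial_pvalue(k, n, p)) - oracle) < 1e-12

    def test_monotone_in_k(self):
        ps = binomial_pvalue(np.arange(0, 20), 1000, 0.005)
        assert (np.diff(ps) <= 1e-15).all()

    def test_bh_adjust_matches_definition(self):
        p = np.array([0.01, 0.04, 0.03, 0.5])
        q = bh_adjust(p)
        assert q[0] == pytest.approx(0.04)
        assert q[3] == pytest.approx(0.5)
        assert (q >= p - 1e-15).all()


def _power_law_matrix(seed=3, depth=100_000):
    cfg = SimConfig(
        n_chroms=1, chrom_length=5_000_000, depth=depth,
        fraction_functional=0.0, n_snps=0, hub_targets=(), seed=seed,
    )
    pairs = generate_contacts(cfg, [], np.random.default_rng(seed))
    return cfg, bin_contacts(pairs, 10_000, cfg.chrom_sizes)


class TestExpectedModel:
    def test_power_law_probabilities_close_to_truth(self):
        cfg, matrix = _power_law_matrix(depth=300_000)
        model = fit_expected_model(matrix, n_bins=50)
        # generating law: P(pair at offset o) ~ integral of c/(d+d0) over the bin,
        # divided among the locus pairs at that offset
        lo, hi = cfg.d_min + cfg.d0, cfg.d_max + cfg.d0
        norm = np.log(hi / lo)
        for o, p_hat, npairs in zip(model.offsets, model.prob, model.locus_pairs):
            d = o * 10_000
            if d < 30_000 or d > 1_000_000:
                continue  # edge strata straddle the sampling bounds
            p_true = (10_000 / ((d + cfg.d0) * norm)) / npairs
            assert p_hat == pytest.approx(p_true, rel=0.20)

    def test_single_distance_degenerate(self):
        rows = [("chr1", i * 50_000, "chr1", i * 50_000 + 30_000, 1) for i in range(50)]
        matrix = bin_contacts(frame(rows), 10_000, {"chr1": 5_000_000})
        model = fit_expected_model(matrix, n_bins=10)
        assert model.prob[model.offsets == 3][0] > 0
        positive = model.prob[model.prob > 0]
        assert len(np.unique(np.round(positive, 18))) == 1  # one effective stratum

    def test_monotone_non_increasing_for_any_input(self):
        _, matrix = _power_law_matrix(seed=9, depth=50_000)
        model = fit_expected_model(matrix, n_bins=40)
        assert (np.diff(model.prob) <= 1e-18).all()

    def test_reduces_bins_with_warning(self, caplog):
        _, matrix = _power_law_matrix(seed=1, depth=5_000)
        with caplog.at_level("WARNING"):
            model = fit_expected_model(matrix, n_bins=100_000)
        assert model.n_strata <= len(model.offsets)
        assert any("reducing n_bins" in r.message for r in caplog.records)


class TestSignificance:
    def test_calls_match_vectorised_pvalues(self):
        _, matrix = _power_law_matrix(seed=5, depth=80_000)
        model = fit_expected_model(matrix, n_bins=30)
        df = call_significant_contacts(matrix, model, alpha=0.05)
        assert ((df["pvalue"] < 0.05) == df["significant"]).all()
        spot = df.sample(20, random_state=0)
        for r in spot.itertuples():
            assert r.pvalue == pytest.approx(
                float(binomial_pvalue(r.observed, model.n_total, r.expected_p)),
                abs=1e-15,
            )

    def test_resolution_mismatch_errors(self):
        _, matrix = _power_law_matrix(seed=5, depth=20_000)
        model = fit_expected_model(matrix, n_bins=10)
        other = ContactMatrix(5_000, matrix.chrom_sizes, matrix.matrices)
        with pytest.raises(ValueError):
            call_significant_contacts(other, model)


class TestCompartments:
    def _block_matrix(self, n=40, strong=60, weak=4):
        # two irregularly interleaved block families (plaid / checkerboard)
        labels = np.random.default_rng(17).integers(0, 2, n)
        m = np.where(np.equal.outer(labels, labels), strong, weak).astype(float)
        decay = 1.0 / (1 + np.abs(np.subtract.outer(np.arange(n), np.arange(n))))
        counts = np.rint(m * decay * 10)
        np.fill_diagonal(counts, counts.diagonal() + 50)
        return labels, ContactMatrix(
            100_000, {"chr1": n * 100_000}, {"chr1": sparse.csr_matrix(counts)}
        )

    def test_checkerboard_partition_recovered(self):
        labels, matrix = self._block_matrix()
        (res,) = compartment_eigenvector(matrix).values()
        sign = np.sign(res["value"].to_numpy())
        agree = (sign == np.where(labels == labels[0], sign[0], -sign[0])).mean()
        assert agree == 1.0

    def test_pure_decay_flagged_weak(self):
        n = 60
        counts = np.rint(
            2000.0 / (1.0 + np.abs(np.subtract.outer(np.arange(n), np.arange(n))))
        )
        rng = np.random.default_rng(0)
        counts = np.rint(counts * rng.uniform(0.9, 1.1, counts.shape))
        counts = np.maximum(counts, counts.T)
        matrix = ContactMatrix(
            100_000, {"chr1": n * 100_000}, {"chr1": sparse.csr_matrix(counts)}
        )
        (res,) = compartment_eigenvector(matrix).values()
        assert res.attrs["strength"] < 0.2

    def test_gene_density_orientation_deterministic(self):
        labels, matrix = self._block_matrix()
        genes = [
            GeneRecord(f"g{i}", f"G{i}", "chr1", "+", int(b * 100_000 + 500), [
                GenomicInterval("chr1", b * 100_000 + 500, b * 100_000 + 1500)
            ])
            for i, b in enumerate(np.where(labels == 1)[0])
        ]
        (res,) = compartment_eigenvector(matrix, genes=genes).values()
        dense_bins = res["value"].to_numpy()[labels == 1]
        assert (dense_bins > 0).all()  # gene-dense family oriented to A

    def test_constant_matrix_errors(self):
        m = np.full((20, 20), 7.0)
        matrix = ContactMatrix(
            100_000, {"chr1": 2_000_000}, {"chr1": sparse.csr_matrix(m)}
        )
        with pytest.raises(ValueError, match="no compartment signal"):
            compartment_eigenvector(matrix)


class TestCapture:
    def _sig(self, rows, res=10_000):
        df = pd.DataFrame(rows, columns=["chrom", "binA", "binB"])
        df["observed"], df["expected_p"], df["pvalue"] = 5, 1e-6, 1e-4
        df["significant"] = True
        df.attrs["resolution"] = res
        return df

    def _snps(self, positions):
        return partition_by_epigenome(
            select_candidates(
                [SnpRecord(f"rs{i}", "chr1", p, "A", "G", 1e-4, 1.1)
                 for i, p in enumerate(positions)]
            ),
            [],
        )

    def test_counting_example(self):
        sig = self._sig([("chr1", 10, 50), ("chr1", 20, 60), ("chr1", 30, 70),
                         ("chr1", 40, 80)])
        snps = self._snps([105_000, 505_000, 2_000_000])  # first two in anchors
        res = capture_per_interaction(sig, snps, [], bin_size=10_000)
        assert res.snps_per_interaction == pytest.approx(2 / 4)

    def test_expansion_monotone(self):
        sig = self._sig([("chr1", 10, 50)])
        snps = self._snps(list(range(80_000, 160_000, 7_000)))
        aes = [AECall(GenomicInterval("chr1", s, s + 80), "overlapped", s + 40)
               for s in range(90_000, 130_000, 5_000)]
        prev_s = prev_a = -1.0
        for b in (5_000, 10_000, 100_000):
            r = capture_per_interaction(sig, snps, aes, bin_size=b)
            assert r.snps_per_interaction >= prev_s
            assert r.aes_per_interaction >= prev_a
            prev_s, prev_a = r.snps_per_interaction, r.aes_per_interaction

    def test_relative_ability_identity(self):
        x = CaptureResult(0.4, 1.2, 10)
        assert relative_ability(x, x) == (1.0, 1.0)

    def test_zero_interactions_error(self):
        sig = self._sig([])
        with pytest.raises(ValueError):
            capture_per_interaction(sig, [], [], bin_size=10_000)
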