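"""Gapped k-mer kernel exactness, SVM training, and deltaSVM scoring."""

import itertools
from collections import Counter

import numpy as np
import pytest

from episcreen.data_model import SnpRecord
from episcreen.enhancers import AECall
from episcreen.data_model import GenomicInterval
from episcreen.gkm import (
    GkmModel,
    GkmParams,
    TrainingSet,
    background_deltas,
    build_training_sets,
    delta_svm,
    gkm_gram,
    gkm_kernel,
    lmer_weight_table,
    outlier_assessment,
    train_and_evaluate,
)


def bruteforce_kernel(a: str, b: str, l: int, k: int) -> int:
    """Explicit gapped-feature dot product (independent oracle)."""

    def feats(seq):
        c = Counter()
        seq = seq.upper()
        for i in range(len(seq) - l + 1):
            w = seq[i : i + l]
            if any(ch not in "ACGT" for ch in w):
                continue
            for subset in itertools.combinations(range(l), k):
                c[(subset, tuple(w[j] for j in subset))] += 1
        return c

    fa, fb = feats(a), feats(b)
    return sum(v * fb[key] for key, v in fa.items())


def random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestKernel:
    def test_identical_single_lmer(self):
        assert gkm_kernel("ACGTACGTAC", "ACGTACGTAC", normalized=False) == 210  # C(10,6)
        assert gkm_kernel("ACGTACGTAC", "ACGTACGTAC") == pytest.approx(1.0)

    def test_five_mismatches_forced_zero(self):
        a = "ACGTACGTAC"
        b = "CGTACCGTAC"  # differs at first 5 positions
        assert gkm_kernel(a, b, normalized=False) == 0

    def test_one_mismatch(self):
        a = "ACGTACGTAC"
        b = "CCGTACGTAC"
        assert gkm_kernel(a, b, normalized=False) == 84  # C(9,6)
        assert bruteforce_kernel(a, b, 10, 6) == 84

    def test_matches_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            a = random_seq(rng, int(rng.integers(15, 31)))
            b = random_seq(rng, int(rng.integers(15, 31)))
            assert gkm_kernel(a, b, normalized=False) == bruteforce_kernel(a, b, 10, 6)

    def test_symmetry_and_unit_self(self):
        rng = np.random.default_rng(3)
        a, b = random_seq(rng, 40), random_seq(rng, 33)
        assert gkm_kernel(a, b) == pytest.approx(gkm_kernel(b, a))
        assert gkm_kernel(a, a) == pytest.approx(1.0)

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError):
            gkm_kernel("ACGT", "ACGTACGTAC")

    def test_gram_equals_pairwise(self):
        rng = np.random.default_rng(8)
        seqs = [random_seq(rng, 30) for _ in range(6)]
        for normalized in (False, True):
            G = gkm_gram(seqs, normalized=normalized)
            for i in range(6):
                for j in range(6):
                    assert G[i, j] == pytest.approx(
                        gkm_kernel(seqs[i], seqs[j], normalized=normalized), rel=1e-12
                    )


class TestTrainingSets:
    def _genome(self, rng, size=200_000, chrom="chr1"):
        return {chrom: random_seq(rng, size)}

    def test_window_arithmetic(self):
        rng = np.random.default_rng(0)
        genome = self._genome(rng)
        call = AECall(GenomicInterval("chr1", 5000, 5100), "overlapped", 5050)
        ts = build_training_sets(
            [call], genome, {"chr1": 200_000}, width=400, neg_ratio=2, seed=0
        )
        assert ts.provenance["positives"] == [("chr1", 4850, 5250)]
        assert ts.positives[0] == genome["chr1"][4850:5250]

    def test_repeat_filter(self):
        rng = np.random.default_rng(1)
        genome = self._genome(rng)
        # soft-mask 75% of the window of the second AE
        s = genome["chr1"]
        genome["chr1"] = s[:20_000] + s[20_000:20_300].lower() + s[20_300:]
        calls = [
            AECall(GenomicInterval("chr1", 5000, 5100), "overlapped", 5050),
            AECall(GenomicInterval("chr1", 20_100, 20_180), "overlapped", 20_150),
        ]
        ts = build_training_sets(
            [calls[0]], genome, {"chr1": 200_000}, width=400, neg_ratio=1, seed=0
        )
        assert len(ts.positives) == 1
        ts2 = build_training_sets(
            calls, genome, {"chr1": 200_000}, width=200, repeat_max=0.70,
            neg_ratio=1, seed=0,
        )
        assert len(ts2.positives) == 1  # 300/200 lowercase window removed

    def test_negative_ratio(self):
        rng = np.random.default_rng(2)
        genome = self._genome(rng, size=2_000_000)
        calls = [
            AECall(GenomicInterval("chr1", 10_000 + 3000 * i, 10_080 + 3000 * i),
                   "overlapped", 10_040 + 3000 * i)
            for i in range(50)
        ]
        ts = build_training_sets(
            calls, genome, {"chr1": 2_000_000}, width=100, neg_ratio=10, seed=3
        )
        assert len(ts.positives) == 50
        assert len(ts.negatives) == 500
        pos_iv = ts.provenance["positives"]
        for c, s, e in ts.provenance["negatives"]:
            assert all(not (s < pe and ps < e) for _, ps, pe in pos_iv)

    def test_edge_window_shifted_inward(self):
        rng = np.random.default_rng(4)
        genome = self._genome(rng, size=5_000)
        call = AECall(GenomicInterval("chr1", 10, 90), "overlapped", 50)
        ts = build_training_sets(
            [call], genome, {"chr1": 5_000}, width=400, neg_ratio=1, seed=0
        )
        assert ts.provenance["positives"] == [("chr1", 0, 400)]

    def test_mixed_width_rejected(self):
        with pytest.raises(ValueError):
            TrainingSet(positives=["ACGT" * 10], negatives=["ACGT" * 9])


def planted_training(rng, n_pos=60, n_neg=240, width=50, motif="GCGTATAC"):
    pos = []
    for _ in range(n_pos):
        s = random_seq(rng, width)
        i = int(rng.integers(0, width - len(motif)))
        pos.append(s[:i] + motif + s[i + len(motif) :])
    neg = [random_seq(rng, width) for _ in range(n_neg)]
    return TrainingSet(positives=pos, negatives=neg, seed=0)


class TestTraining:
    PARAMS = GkmParams(l=8, k=5)

    def test_planted_motif_separable(self):
        rng = np.random.default_rng(21)
        ts = planted_training(rng)
        _, metrics = train_and_evaluate(ts, self.PARAMS, folds=5, seed=0)
        assert metrics["cv_auroc"] >= 0.9

    def test_shuffled_labels_chance_level(self):
        rng = np.random.default_rng(22)
        ts = planted_training(rng)
        seqs = ts.sequences
        perm = rng.permutation(len(seqs))
        shuffled = TrainingSet(
            positives=[seqs[i] for i in perm[: len(ts.positives)]],
            negatives=[seqs[i] for i in perm[len(ts.positives) :]],
        )
        _, metrics = train_and_evaluate(shuffled, self.PARAMS, folds=5, seed=0)
        assert metrics["cv_auroc"] == pytest.approx(0.5, abs=0.1)

    def test_duplication_leaves_decision_unchanged(self):
        rng = np.random.default_rng(23)
        ts = planted_training(rng, n_pos=20, n_neg=40, width=30)
        doubled = TrainingSet(
            positives=ts.positives * 2, negatives=ts.negatives * 2, seed=0
        )
        m1, _ = train_and_evaluate(ts, self.PARAMS, C=100.0, folds=2, seed=0)
        m2, _ = train_and_evaluate(doubled, self.PARAMS, C=100.0, folds=2, seed=0)
        probes = [random_seq(rng, 30) for _ in range(10)] + ts.positives[:5]
        np.testing.assert_allclose(
            m1.decision_function(probes), m2.decision_function(probes), atol=1e-4
        )

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(24)
        ts = planted_training(rng, n_pos=15, n_neg=30, width=30)
        m1, met1 = train_and_evaluate(ts, self.PARAMS, seed=5)
        m2, met2 = train_and_evaluate(ts, self.PARAMS, seed=5)
        assert met1["cv_auroc"] == met2["cv_auroc"]
        np.testing.assert_array_equal(m1.dual_coef, m2.dual_coef)


def toy_model(rng, normalized=True, support_len=20):
    sv = random_seq(rng, support_len)
    return sv, GkmModel(
        support_seqs=[sv], dual_coef=np.array([0.7]), bias=0.3,
        params=GkmParams(l=10, k=6), normalized=normalized,
    )


class TestWeightsAndDelta:
    def test_weight_table_deterministic(self):
        rng = np.random.default_rng(31)
        _, model = toy_model(rng)
        lmers = [random_seq(rng, 10) for _ in range(20)]
        t1 = lmer_weight_table(model, lmers)
        t2 = lmer_weight_table(model, lmers)
        assert t1 == t2

    def test_weight_is_kernel_expansion(self):
        rng = np.random.default_rng(32)
        sv, model = toy_model(rng)
        x = sv[3:13]  # an l-mer of the support sequence
        w = lmer_weight_table(model, [x])[x]
        assert w == pytest.approx(0.7 * gkm_kernel(x, sv, normalized=True))

    def test_reverse_complement_not_symmetrised(self):
        rng = np.random.default_rng(33)
        _, model = toy_model(rng)
        x = "ACGTTGCACA"
        rc = "TGTGCAACGT"
        wx, wrc = lmer_weight_table(model, [x, rc]).values()
        assert wx != pytest.approx(wrc)

    def _snp_genome(self, rng, pos=500, ref=None, alt=None, size=1000):
        g = random_seq(rng, size)
        ref = ref or g[pos]
        alt = alt or "ACGT".replace(ref, "")[0]
        g = g[:pos] + ref + g[pos + 1 :]
        snp = SnpRecord("rsX", "chr1", pos, ref, alt, 1e-4, 1.2)
        return {"chr1": g}, snp

    def test_delta_antisymmetric(self):
        rng = np.random.default_rng(34)
        _, model = toy_model(rng)
        genome, snp = self._snp_genome(rng)
        swapped = SnpRecord("rsX", "chr1", snp.pos, snp.alt, snp.ref, 1e-4, 1.2)
        assert delta_svm(snp, genome, model) == pytest.approx(
            -delta_svm(swapped, genome, model), abs=1e-12
        )

    def test_delta_equals_full_window_rescoring(self):
        # with an unnormalised kernel the non-covering l-mers cancel exactly
        rng = np.random.default_rng(35)
        _, model = toy_model(rng, normalized=False)
        genome, snp = self._snp_genome(rng)
        flank = model.params.l - 1
        window = genome["chr1"][snp.pos - flank : snp.pos + flank + 1]
        ref_w = window
        alt_w = window[:flank] + snp.alt + window[flank + 1 :]
        brute = (
            model.decision_function([alt_w])[0] - model.decision_function([ref_w])[0]
        )
        assert delta_svm(snp, genome, model) == pytest.approx(brute, abs=1e-9)

    def test_ambiguous_bases_skipped(self):
        rng = np.random.default_rng(36)
        _, model = toy_model(rng)
        genome, snp = self._snp_genome(rng)
        g = genome["chr1"]
        genome["chr1"] = g[: snp.pos - 3] + "N" + g[snp.pos - 2 :]
        assert np.isfinite(delta_svm(snp, genome, model))

    def test_outlier_tukey_fences(self):
        bg = np.linspace(-1, 1, 1001)
        d = outlier_assessment(5.0, None, None, None, background=bg)
        assert d.outlier
        mid = outlier_assessment(0.0, None, None, None, background=bg)
        assert not mid.outlier

    def test_background_deltas_seeded(self):
        rng = np.random.default_rng(37)
        _, model = toy_model(rng)
        genome = {"chr1": random_seq(rng, 20_000)}
        b1 = background_deltas(genome, model, {"chr1": 20_000}, n=25, seed=4)
        b2 = background_deltas(genome, model, {"chr1": 20_000}, n=25, seed=4)
        assert len(b1) == 25
        np.testing.assert_array_equal(b1, b2)

    def test_model_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(38)
        _, model = toy_model(rng)
        model.to_json(tmp_path / "m.json")
        back = GkmModel.from_json(tmp_path / "m.json")
        lmers = [random_seq(rng, 10) for _ in range(5)]
        np.testing.assert_allclose(
            model.score_lmers(lmers), back.score_lmers(lmers), rtol=1e-12
        )
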