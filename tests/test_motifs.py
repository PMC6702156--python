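import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from corecirc import (
    GenomicInterval,
    MotifModel,
    bh_qvalues,
    exact_score_pvalue,
    pfm_to_pwm,
    scan_nfrs,
    scan_sequence,
)
from corecirc.motifs import UNIFORM_BACKGROUND, estimate_background
from corecirc.superenh import NucleosomeFreeRegion

from ._oracles import bh_oracle, pvalue_enumeration_oracle, pwm_scan_oracle


def consensus_counts(consensus, strong=100):
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    counts = np.zeros((4, len(consensus)))
    for i, b in enumerate(consensus):
        counts[:, i] = 0.0
        counts[idx[b], i] = strong
    return counts


class TestPfmToPwm:
    def test_uniform_counts_uniform_background_gives_zero(self):
        pwm = pfm_to_pwm(np.full((4, 5), 25.0), UNIFORM_BACKGROUND)
        assert np.allclose(pwm, 0.0)

    def test_hand_computed_column(self):
        counts = np.array([[10.0], [0.0], [0.0], [0.0]])
        pwm = pfm_to_pwm(counts, UNIFORM_BACKGROUND, pseudocount=0.1)
        # A: log2((10.025/10.1)/0.25) = 1.9892...
        assert pwm[0, 0] == pytest.approx(np.log2((10.025 / 10.1) / 0.25), abs=1e-12)
        assert pwm[0, 0] == pytest.approx(1.990, abs=1e-3)

    def test_scaling_counts_converges_to_pseudocount_free_log_odds(self):
        counts = np.array([[6.0], [2.0], [1.0], [1.0]])
        limit = np.log2((counts / counts.sum()) / 0.25)
        err10 = np.abs(pfm_to_pwm(counts * 10, UNIFORM_BACKGROUND) - limit).max()
        err1000 = np.abs(pfm_to_pwm(counts * 1000, UNIFORM_BACKGROUND) - limit).max()
        assert err1000 < err10 < 0.05

    def test_zero_column_sum_rejected(self):
        counts = np.zeros((4, 2))
        counts[:, 0] = 1
        with pytest.raises(ValueError):
            pfm_to_pwm(counts, UNIFORM_BACKGROUND)


class TestExactPValue:
    def test_single_column_best_base(self):
        m = MotifModel("t", consensus_counts("A"), UNIFORM_BACKGROUND)
        pfun = exact_score_pvalue(m)
        assert pfun(float(m.pwm[0, 0])) == pytest.approx(0.25)

    def test_below_minimum_score_is_one(self):
        m = MotifModel("t", consensus_counts("ACG"), UNIFORM_BACKGROUND)
        assert m.pvalue(-1e9) == 1.0

    @pytest.mark.parametrize("length", [1, 2, 4, 6])
    @pytest.mark.parametrize(
        "background", [UNIFORM_BACKGROUND, np.array([0.4, 0.1, 0.1, 0.4])]
    )
    def test_matches_enumeration(self, rng, length, background):
        counts = rng.integers(1, 50, size=(4, length)).astype(float)
        m = MotifModel("t", counts, background)
        qs = sorted({int(s) for s in rng.integers(m.qpwm.min(axis=0).sum(),
                                                  m.qpwm.max(axis=0).sum() + 1, 10)})
        for s in qs:
            assert m.pvalue_int(s) == pytest.approx(
                pvalue_enumeration_oracle(m.qpwm, background, s), abs=1e-12
            )

    def test_p_non_increasing_in_score(self, rng):
        m = MotifModel("t", rng.integers(1, 30, (4, 5)).astype(float), UNIFORM_BACKGROUND)
        lo = int(m.qpwm.min(axis=0).sum())
        hi = int(m.qpwm.max(axis=0).sum())
        ps = [m.pvalue_int(s) for s in range(lo, hi + 1, max((hi - lo) // 50, 1))]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestScanSequence:
    def test_planted_consensus_single_forward_hit(self):
        m = MotifModel("t", consensus_counts("ACGTAGGC"), UNIFORM_BACKGROUND)
        seq = "T" * 30 + "ACGTAGGC" + "T" * 30
        hits = scan_sequence(seq, m, p_threshold=1e-4)
        assert len(hits) == 1
        (h,) = hits
        assert (h.interval.start, h.strand) == (30, "+")
        assert h.p_value == pytest.approx(0.25**8, rel=1e-6)

    def test_reverse_complement_hit_same_interval(self):
        m = MotifModel("t", consensus_counts("ACGTAGGC"), UNIFORM_BACKGROUND)
        seq = "T" * 30 + "GCCTACGT" + "T" * 30  # revcomp of consensus
        (h,) = scan_sequence(seq, m, p_threshold=1e-4)
        assert (h.interval.start, h.interval.end, h.strand) == (30, 38, "-")

    def test_all_n_sequence_is_empty(self):
        m = MotifModel("t", consensus_counts("ACGT"), UNIFORM_BACKGROUND)
        assert scan_sequence("N" * 50, m, p_threshold=1.0) == []

    def test_sequence_shorter_than_motif_is_empty(self):
        m = MotifModel("t", consensus_counts("ACGTACGT"), UNIFORM_BACKGROUND)
        assert scan_sequence("ACG", m, p_threshold=1.0) == []

    def test_scores_match_naive_oracle(self, rng):
        bases = np.array(list("ACGTN"))
        for _ in range(30):
            L = int(rng.integers(2, 9))
            counts = rng.integers(1, 40, (4, L)).astype(float)
            m = MotifModel("t", counts, UNIFORM_BACKGROUND)
            seq = "".join(rng.choice(bases, p=[0.24, 0.24, 0.24, 0.24, 0.04], size=80))
            hits = scan_sequence(seq, m, p_threshold=1.0)
            got = {
                (h.interval.start, h.strand): int(round(h.score / m.granularity))
                for h in hits
            }
            expected = {(i, s): sc for i, s, sc in pwm_scan_oracle(seq, m.qpwm)}
            assert got == expected


class TestBHQValues:
    def test_single_pvalue_unchanged(self):
        assert bh_qvalues([0.04]) == pytest.approx([0.04])

    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_qvalues([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_qvalues([0.2] * 5), [0.2] * 5)

    def test_matches_textbook_oracle_and_statsmodels(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1, size=int(rng.integers(1, 30)))
            q = bh_qvalues(p)
            np.testing.assert_allclose(q, bh_oracle(list(p)), atol=1e-12)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(q, q_sm, atol=1e-12)

    def test_external_family_size_scales_q(self):
        q = bh_qvalues([0.001], n_tests=100)
        assert q == pytest.approx([0.1])

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.0, 0.5])


class TestScanNFRs:
    def make_genome(self, seq):
        return {"chr1": seq}

    def test_no_nfrs_empty(self):
        m = {"TFA": consensus_counts("ACGTACGTACGTACGTAC")}
        assert scan_nfrs([], self.make_genome("ACGT" * 100), m) == {}

    def test_planted_strong_motif_single_surviving_hit(self, rng):
        cons = "".join(rng.choice(list("ACGT"), 18))
        seq = list("".join(rng.choice(list("ACGT"), 2000)))
        seq[700:718] = list(cons)
        genome = self.make_genome("".join(seq))
        nfrs = [NucleosomeFreeRegion(GenomicInterval("chr1", 500, 1500), "se1")]
        hits = scan_nfrs(nfrs, genome, {"TFA": consensus_counts(cons, 197)})
        assert set(hits) == {"TFA"}
        # the plant survives; its genomic coordinates are correct
        positions = {h.interval.start for _, h in hits["TFA"]}
        assert 700 in positions
        for _, h in hits["TFA"]:
            assert h.q_value <= 1e-5 and h.q_value >= h.p_value

    def test_raising_q_threshold_never_removes_hits(self, rng):
        cons = "".join(rng.choice(list("ACGT"), 18))
        seq = list("".join(rng.choice(list("ACGT"), 1000)))
        seq[100:118] = list(cons)
        genome = self.make_genome("".join(seq))
        nfrs = [NucleosomeFreeRegion(GenomicInterval("chr1", 0, 1000), "se1")]
        db = {"TFA": consensus_counts(cons, 197)}
        strict = scan_nfrs(nfrs, genome, db, q_threshold=1e-5)
        loose = scan_nfrs(nfrs, genome, db, q_threshold=1e-3)
        strict_keys = {
            (tf, h.interval.start, h.strand) for tf in strict for _, h in strict[tf]
        }
        loose_keys = {
            (tf, h.interval.start, h.strand) for tf in loose for _, h in loose[tf]
        }
        assert strict_keys <= loose_keys

    def test_nfr_outside_fasta_bounds_rejected(self):
        nfrs = [NucleosomeFreeRegion(GenomicInterval("chr1", 0, 5000), "se1")]
        with pytest.raises(ValueError, match="chr1"):
            scan_nfrs(nfrs, self.make_genome("ACGT" * 10), {"T": consensus_counts("ACGT")})

    def test_background_estimated_from_nfr_composition(self):
        assert estimate_background(["AAAA", "AATT"]) == pytest.approx(
            [0.75, 0.0, 0.0, 0.25]
        )
        assert estimate_background(["NNNN"]) == pytest.approx([0.25] * 4)
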