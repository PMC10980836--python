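"""Unit and oracle tests for the sequence-comparison kernels."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from virolink import seqmatch as sm
from conftest import random_seq


# ---------------------------------------------------------------------------
# Independent oracles (deliberately naive; no shared code with the package)
# ---------------------------------------------------------------------------

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def brute_revcomp(seq):
    return "".join(_COMP[c] for c in reversed(seq))


def brute_spacer_scan(spacer, contig, max_mm):
    """Sliding-window scan over both strands, counting substitutions."""
    out = []
    L = len(spacer)
    for strand, sp in (("+", spacer), ("-", brute_revcomp(spacer))):
        for i in range(len(contig) - L + 1):
            mm = sum(1 for a, b in zip(sp, contig[i : i + L]) if a != b)
            if mm <= max_mm:
                out.append((i + 1, strand, mm))
    return sorted(out)


def brute_onf_expected(seq, k, order):
    """Markov chain-product expectation for one k-word, dict-based."""
    pooled_counts = {}

    def count(s, n):
        for i in range(len(s) - n + 1):
            w = s[i : i + n]
            pooled_counts.setdefault(n, {}).setdefault(w, 0)
            pooled_counts[n][w] += 1

    for s in (seq, brute_revcomp(seq)):
        count(s, order)
        count(s, order + 1)

    def p_ctx(w):
        total = sum(pooled_counts[order].values())
        return pooled_counts[order].get(w, 0) / total

    def p_trans(ctx, b):
        row_total = sum(
            pooled_counts[order + 1].get(ctx + c, 0) for c in "ACGT"
        )
        if row_total == 0:
            return 0.0
        return pooled_counts[order + 1].get(ctx + b, 0) / row_total

    def expected(word):
        p = p_ctx(word[:order])
        for i in range(len(word) - order):
            p *= p_trans(word[i : i + order], word[i + order])
        return p

    return expected


def brute_d2star(a, b, k=6, order=2):
    """Direct summation over all 4**k words with dict-counted profiles."""
    import itertools

    words = ["".join(w) for w in itertools.product("ACGT", repeat=k)]

    def profile(seq):
        counts = {}
        for s in (seq, brute_revcomp(seq)):
            for i in range(len(s) - k + 1):
                w = s[i : i + k]
                counts[w] = counts.get(w, 0) + 1
        exp = brute_onf_expected(seq, k, order)
        n = sum(counts.values())
        return counts, exp, n

    ca, ea, na = profile(a)
    cb, eb, nb = profile(b)
    cross = norm_a = norm_b = 0.0
    for w in words:
        pa, pb = ea(w), eb(w)
        xa = ca.get(w, 0) - na * pa
        xb = cb.get(w, 0) - nb * pb
        if pa > 0:
            norm_a += xa * xa / (na * pa)
        if pb > 0:
            norm_b += xb * xb / (nb * pb)
        if pa > 0 and pb > 0:
            cross += xa * xb / (math.sqrt(na * pa) * math.sqrt(nb * pb))
    sim = cross / (math.sqrt(norm_a) * math.sqrt(norm_b))
    return (1.0 - sim) / 2.0


# ---------------------------------------------------------------------------
# Spacer matching
# ---------------------------------------------------------------------------


class TestSpacerMatching:
    def test_planted_exact_match_found_once(self):
        rng = np.random.default_rng(0)
        contig = random_seq(rng, 3000)
        spacer = contig[700:732]
        hits = sm.find_spacer_matches(spacer, contig)
        exact = [h for h in hits if h.mismatches == 0 and h.strand == "+"]
        assert len(exact) == 1 and exact[0].position == 701

    def test_reverse_complement_occurrence_reported_on_plus_coordinates(self):
        rng = np.random.default_rng(1)
        contig = random_seq(rng, 2000)
        spacer = sm.revcomp(contig[500:532])
        hits = sm.find_spacer_matches(spacer, contig)
        assert any(h.strand == "-" and h.position == 501 for h in hits)

    def test_two_substitutions_escape_the_one_mismatch_gate(self):
        rng = np.random.default_rng(2)
        contig = random_seq(rng, 2000)
        spacer = list(contig[100:132])
        spacer[3] = _COMP[spacer[3]]
        spacer[20] = _COMP[spacer[20]]
        hits = sm.find_spacer_matches("".join(spacer), contig, max_mm=1)
        assert all(h.position != 101 for h in hits)

    def test_spacer_longer_than_contig_gives_empty_result(self):
        assert sm.find_spacer_matches("ACGT" * 10, "ACGTACGT" * 3) == []

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError):
            sm.find_spacer_matches("ACGTACGTAC", "A" * 100)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force_scan_with_planted_near_matches(self, seed):
        rng = np.random.default_rng(100 + seed)
        contig = list(random_seq(rng, 1200))
        spacer = random_seq(rng, 30)
        # plant copies at 0/1/2 mismatches, some reverse-complemented
        for n_mm, pos in ((0, 50), (1, 300), (2, 600), (1, 900)):
            copy = list(spacer if pos != 900 else sm.revcomp(spacer))
            for p in rng.choice(30, size=n_mm, replace=False):
                copy[p] = _COMP[copy[p]]
            contig[pos : pos + 30] = copy
        contig = "".join(contig)
        got = sorted(
            (h.position, h.strand, h.mismatches)
            for h in sm.find_spacer_matches(spacer, contig, max_mm=1)
        )
        assert got == brute_spacer_scan(spacer, contig, 1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        spacer=st.text(alphabet="ACGT", min_size=20, max_size=40),
        contig=st.text(alphabet="ACGT", min_size=40, max_size=300),
        max_mm=st.integers(min_value=0, max_value=2),
    )
    def test_property_equivalent_to_brute_force(self, spacer, contig, max_mm):
        got = sorted(
            (h.position, h.strand, h.mismatches)
            for h in sm.find_spacer_matches(spacer, contig, max_mm)
        )
        assert got == brute_spacer_scan(spacer, contig, max_mm)


# ---------------------------------------------------------------------------
# E-values
# ---------------------------------------------------------------------------


class TestEvalue:
    def test_closed_form(self):
        expected = 0.46 * 1e4 * 1e6 * math.exp(-1.28 * 30)
        assert sm.evalue(30, 10**4, 10**6, 1.28, 0.46) == pytest.approx(expected, rel=1e-12)

    def test_monotone_in_score_and_linear_in_subject_length(self):
        e1 = sm.evalue(30, 1000, 10000)
        assert sm.evalue(40, 1000, 10000) < e1
        assert sm.evalue(30, 1000, 20000) == pytest.approx(2 * e1)
        assert sm.evalue(1e6, 1000, 10000) == pytest.approx(0.0, abs=1e-300)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            sm.evalue(30, 0, 100)
        with pytest.raises(ValueError):
            sm.evalue(30, 100, 100, lam=-1)


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------


class TestLocalAlign:
    def test_exact_substring_hit(self):
        rng = np.random.default_rng(3)
        subject = random_seq(rng, 5000)
        query = subject[1000:2000]
        hits = sm.local_align(query, subject)
        h = hits[0]
        assert h.identity == 1.0
        assert h.query_cov == pytest.approx(1.0)
        assert (h.s_start, h.s_end) == (1001, 2000)
        assert h.strand == "+"

    def test_reverse_complement_query_hits_minus_strand(self):
        rng = np.random.default_rng(4)
        subject = random_seq(rng, 4000)
        query = sm.revcomp(subject[500:1500])
        h = sm.local_align(query, subject)[0]
        assert h.strand == "-"
        assert h.identity == 1.0
        assert (h.s_start, h.s_end) == (501, 1500)

    def test_identity_matches_dp_oracle_on_diverged_insert(self):
        """Best-hit identity within +-0.02 of a full dynamic-programming
        alignment of the planted 25%-substituted region."""
        from Bio.Align import PairwiseAligner

        rng = np.random.default_rng(5)
        query = random_seq(rng, 10000)
        planted = list(query)
        for p in rng.choice(10000, size=2500, replace=False):
            planted[p] = "ACGT"[("ACGT".index(planted[p]) + 1 + int(rng.integers(3))) % 4]
        subject = random_seq(rng, 2000) + "".join(planted) + random_seq(rng, 2000)

        h = sm.local_align(query, subject)[0]

        aligner = PairwiseAligner(
            match_score=1, mismatch_score=-2, open_gap_score=-2.5, extend_gap_score=-1
        )
        aligner.mode = "global"
        aln = aligner.align(query, "".join(planted))[0]
        counts = aln.counts()
        oracle_identity = counts.identities / (
            counts.identities + counts.mismatches + counts.gaps
        )
        assert h.identity == pytest.approx(oracle_identity, abs=0.02)
        assert h.query_cov > 0.95

    def test_hits_are_deterministic_and_bounded(self):
        rng = np.random.default_rng(6)
        subject = random_seq(rng, 20000)
        query = subject[3000:8000] + random_seq(rng, 2000)
        h1 = sm.local_align(query, subject)
        h2 = sm.local_align(query, subject)
        assert h1 == h2
        for h in h1:
            assert 0 <= h.identity <= 1
            assert 0 <= h.query_cov <= 1
            assert h.q_start <= h.q_end and h.s_start <= h.s_end

    def test_empty_or_invalid_sequence_rejected(self):
        with pytest.raises(ValueError):
            sm.local_align("", "ACGT" * 100)
        with pytest.raises(ValueError):
            sm.local_align("ACGN" * 100, "ACGT" * 100)


def test_merged_query_coverage_unions_overlapping_intervals():
    mk = lambda a, b: sm.AlignmentHit(
        "q", "s", 1.0, b - a + 1, 0.0, 0.0, 1.0, a, b, a, b, "+"
    )
    cov = sm.merged_query_coverage([mk(1, 50), mk(40, 100), mk(201, 250)], 1000)
    assert cov == pytest.approx((100 + 50) / 1000)


# ---------------------------------------------------------------------------
# ONF profiles and d2*
# ---------------------------------------------------------------------------


class TestONF:
    def test_order0_expectation_is_product_of_mononucleotide_freqs(self):
        seq = "ACGT" * 100
        prof = sm.onf_profile(seq, k=2, order=0)
        # both-strand pooling keeps mononucleotide freqs at 1/4 each
        assert np.allclose(prof.expected_freqs, 1 / 16)

    def test_expected_freqs_sum_to_one(self):
        rng = np.random.default_rng(7)
        prof = sm.onf_profile(random_seq(rng, 1500), k=6, order=2)
        assert prof.expected_freqs.sum() == pytest.approx(1.0, abs=1e-9)
        assert prof.observed_counts.sum() == 2 * (1500 - 6 + 1)

    def test_order1_expectations_match_chain_product_oracle(self):
        rng = np.random.default_rng(8)
        seq = random_seq(rng, 1000)
        prof = sm.onf_profile(seq, k=6, order=1)
        oracle = brute_onf_expected(seq, 6, 1)
        for word in ("ACGTAC", "AAAAAA", "GTCAGT", "TTGCAA", "CACACA"):
            code = sum("ACGT".index(c) * 4 ** (5 - i) for i, c in enumerate(word))
            assert prof.expected_freqs[code] == pytest.approx(oracle(word), abs=1e-12)

    def test_k_not_greater_than_order_rejected(self):
        with pytest.raises(ValueError):
            sm.onf_profile("ACGT" * 50, k=2, order=2)


class TestD2Star:
    def test_self_dissimilarity_is_zero(self):
        rng = np.random.default_rng(9)
        prof = sm.onf_profile(random_seq(rng, 2000))
        assert sm.d2star(prof, prof) == pytest.approx(0.0, abs=1e-9)

    def test_symmetric_and_bounded_on_random_pairs(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            pa = sm.onf_profile(random_seq(rng, 800))
            pb = sm.onf_profile(random_seq(rng, 800))
            d_ab, d_ba = sm.d2star(pa, pb), sm.d2star(pb, pa)
            assert d_ab == d_ba
            assert 0.0 <= d_ab <= 1.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_direct_summation_oracle(self, seed):
        rng = np.random.default_rng(200 + seed)
        a, b = random_seq(rng, 2000), random_seq(rng, 2000)
        assert sm.d2star_sequences(a, b) == pytest.approx(
            brute_d2star(a, b), abs=1e-9
        )

    def test_mismatched_k_rejected(self):
        pa = sm.onf_profile("ACGT" * 100, k=6)
        pb = sm.onf_profile("ACGT" * 100, k=4)
        with pytest.raises(ValueError):
            sm.d2star(pa, pb)
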