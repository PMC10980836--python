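"""Sequence-comparison kernels for viral ecology pipelines.

Three families of primitives live here:

* a seed-and-extend **local nucleotide aligner** (megablast-like scoring,
  Karlin-Altschul e-values) used for vOTU ANI clustering, prophage/nucleotide
  host linkage and tRNA matching;
* a **fuzzy spacer matcher** reporting every full-length occurrence of a
  CRISPR spacer on either strand with at most a configurable number of
  substitutions (no indels);
* **oligonucleotide-frequency (ONF) profiles** and the d2* dissimilarity,
  an alignment-free compositional distance between a virus and a candidate
  host genome under a Markov null model of k-mer expectation.

All sequences are uppercase ACGT; ambiguity codes are unsupported.
Coordinates are 1-based inclusive; minus-strand hits report coordinates on
the plus strand of the subject.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import edlib
import numpy as np

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
VALID_BASES = frozenset("ACGT")


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _check_acgt(seq: str, name: str = "sequence") -> None:
    if not seq:
        raise ValueError(f"{name} is empty")
    if set(seq) - VALID_BASES:
        bad = sorted(set(seq) - VALID_BASES)
        raise ValueError(f"{name} contains non-ACGT characters: {bad}")


def encode(seq: str) -> np.ndarray:
    """Encode ACGT as uint8 codes 0..3."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.empty(arr.size, dtype=np.uint8)
    # A=65 C=67 G=71 T=84
    out[arr == 65] = 0
    out[arr == 67] = 1
    out[arr == 71] = 2
    out[arr == 84] = 3
    return out


# ---------------------------------------------------------------------------
# Local alignment
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignScoring:
    """Scoring system for the local aligner.

    Defaults are megablast-like (match +1, mismatch -2, affine gaps) with
    ungapped Karlin-Altschul constants used to convert raw scores to bit
    scores and e-values. The thresholds applied downstream are expressed on
    those derived scales, so the scoring system is configurable here.
    """

    match: float = 1.0
    mismatch: float = -2.0
    gap_open: float = -2.5
    gap_extend: float = -1.0
    lam: float = 1.28
    k_const: float = 0.46
    seed_k: int = 13
    band: int = 100
    chain_gap: int = 1000
    region_pad: int = 400
    min_raw_score: float = 20.0
    max_kmer_hits: int = 8  # mask over-represented subject words (repeats)
    min_group_seeds: int = 2  # chains smaller than this are noise

    def validate(self) -> None:
        if self.match <= 0 or self.mismatch >= 0:
            raise ValueError("match must be > 0 and mismatch < 0")
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")
        if self.lam <= 0 or self.k_const <= 0:
            raise ValueError("Karlin-Altschul parameters must be positive")
        if self.seed_k < 4:
            raise ValueError("seed_k too small")


DEFAULT_SCORING = AlignScoring()


@dataclass
class AlignmentHit:
    """One local alignment between a query and a subject.

    identity is matches / alignment columns (gap columns included);
    query_cov is the aligned query span as a fraction of full query length.
    Coordinates are 1-based inclusive on the plus strand of each sequence.
    """

    query_id: str
    subject_id: str
    identity: float
    aln_len: int
    query_cov: float
    bit_score: float
    evalue: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    raw_score: float = 0.0
    n_match: int = 0
    mismatches: int = 0
    gap_opens: int = 0

    def as_tabular(self) -> str:
        """Conventional 12-column tabular line (blast outfmt-6 order)."""
        return "\t".join(
            str(x)
            for x in (
                self.query_id,
                self.subject_id,
                f"{self.identity * 100:.2f}",
                self.aln_len,
                self.mismatches,
                self.gap_opens,
                self.q_start,
                self.q_end,
                self.s_start,
                self.s_end,
                f"{self.evalue:.2g}",
                f"{self.bit_score:.1f}",
            )
        )


def evalue(raw_score: float, m: int, n: int, lam: float = DEFAULT_SCORING.lam,
           k_const: float = DEFAULT_SCORING.k_const) -> float:
    """Karlin-Altschul expectation E = K * m * n * exp(-lambda * S)."""
    if m <= 0 or n <= 0:
        raise ValueError("sequence lengths must be positive")
    if lam <= 0 or k_const <= 0:
        raise ValueError("lambda and K must be positive")
    return k_const * m * n * math.exp(-lam * raw_score)


def bit_score(raw_score: float, lam: float = DEFAULT_SCORING.lam,
              k_const: float = DEFAULT_SCORING.k_const) -> float:
    """Normalized score in bits: (lambda*S - ln K) / ln 2."""
    return (lam * raw_score - math.log(k_const)) / math.log(2.0)


def _parse_cigar(cigar: str) -> list[tuple[int, str]]:
    ops = []
    n = 0
    for ch in cigar:
        if ch.isdigit():
            n = n * 10 + ord(ch) - 48
        else:
            ops.append((n, ch))
            n = 0
    return ops


def _score_runs(ops: Sequence[tuple[int, str]], sc: AlignScoring) -> list[float]:
    scores = []
    for n, op in ops:
        if op == "=":
            scores.append(n * sc.match)
        elif op == "X":
            scores.append(n * sc.mismatch)
        elif op in "ID":
            scores.append(sc.gap_open + (n - 1) * sc.gap_extend)
        else:  # pragma: no cover - edlib emits only =XID
            raise ValueError(f"unexpected cigar op {op!r}")
    return scores


def _best_subpath(ops: Sequence[tuple[int, str]], sc: AlignScoring):
    """Maximal-scoring contiguous run interval (Kadane at run granularity).

    Runs are homogeneous, so trimming inside a run is never better than
    keeping or dropping it whole at the path ends.
    """
    scores = _score_runs(ops, sc)
    best = (-math.inf, 0, 0)
    cur = 0.0
    start = 0
    for i, s in enumerate(scores):
        if cur <= 0:
            cur = s
            start = i
        else:
            cur += s
        if cur > best[0]:
            best = (cur, start, i + 1)
    return best  # (score, run_start, run_end_exclusive)


def _align_window(query: str, subject: str, sc: AlignScoring):
    """Edit-distance alignment of `query` into `subject` (infix mode), then
    trimmed to the maximal-scoring local sub-path under `sc`.

    Returns None if no positive-scoring sub-path exists, else a dict of
    0-based half-open coordinates and alignment statistics.
    """
    res = edlib.align(query, subject, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    s0, s1 = res["locations"][0]
    ops = _parse_cigar(res["cigar"])
    score, r0, r1 = _best_subpath(ops, sc)
    if score <= 0:
        return None
    # walk runs to locate trimmed interval and count columns
    q_off = 0
    s_off = 0
    q_beg = q_end = s_beg = s_end = 0
    n_match = n_mm = n_gapcols = n_gapopen = 0
    for i, (n, op) in enumerate(ops):
        if i == r0:
            q_beg, s_beg = q_off, s_off
        if op == "=":
            q_off += n
            s_off += n
            if r0 <= i < r1:
                n_match += n
        elif op == "X":
            q_off += n
            s_off += n
            if r0 <= i < r1:
                n_mm += n
        elif op == "I":  # insertion in query w.r.t. subject: consumes query
            q_off += n
            if r0 <= i < r1:
                n_gapcols += n
                n_gapopen += 1
        elif op == "D":  # deletion: consumes subject
            s_off += n
            if r0 <= i < r1:
                n_gapcols += n
                n_gapopen += 1
        if i == r1 - 1:
            q_end, s_end = q_off, s_off
    aln_len = n_match + n_mm + n_gapcols
    if aln_len == 0:
        return None
    return {
        "score": score,
        "q0": q_beg,
        "q1": q_end,
        "s0": s0 + s_beg,
        "s1": s0 + s_end,
        "n_match": n_match,
        "n_mismatch": n_mm,
        "n_gap_open": n_gapopen,
        "aln_len": aln_len,
    }


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        index.setdefault(seq[i : i + k], []).append(i)
    return index


def _seed_regions(query: str, subject: str, sc: AlignScoring):
    """Diagonal-banded seed chains, as candidate alignment windows.

    Exact seed_k-mer matches are grouped by diagonal (within `band`) and
    query position (gaps up to `chain_gap`); each group yields one window.
    """
    k = sc.seed_k
    if len(query) < 4 * k or len(subject) < 4 * k:
        # fall back to a single whole-sequence window for short inputs
        return [(0, len(query), 0, len(subject))]
    index = _kmer_positions(subject, k)
    # mask over-represented words: low-complexity/repeat protection
    index = {w: pos for w, pos in index.items() if len(pos) <= sc.max_kmer_hits}
    seeds = []  # (diag, qpos, spos)
    for q in range(len(query) - k + 1):
        for s in index.get(query[q : q + k], ()):
            seeds.append((s - q, q, s))
    if not seeds:
        return []
    seeds.sort()
    regions = []
    group: list[tuple[int, int, int]] = []

    def flush(g):
        if len(g) < sc.min_group_seeds:
            return
        qs = [x[1] for x in g]
        ss = [x[2] for x in g]
        pad = sc.region_pad
        qa, qb = max(0, min(qs) - pad), min(len(query), max(qs) + k + pad)
        sa, sb = max(0, min(ss) - pad), min(len(subject), max(ss) + k + pad)
        regions.append((qa, qb, sa, sb))

    for seed in seeds:
        if group and (
            seed[0] - group[-1][0] > sc.band
            or abs(seed[1] - max(x[1] for x in group)) > sc.chain_gap
        ):
            flush(group)
            group = []
        group.append(seed)
    flush(group)
    # merge overlapping windows
    regions.sort()
    merged = []
    for r in regions:
        if merged and r[0] <= merged[-1][1] and r[2] <= merged[-1][3]:
            last = merged[-1]
            merged[-1] = (
                last[0],
                max(last[1], r[1]),
                min(last[2], r[2]),
                max(last[3], r[3]),
            )
        else:
            merged.append(r)
    return merged


def _window_hit(query_full_len: int, qoffset: int, soffset: int, w: dict,
                strand: str, query_id: str, subject_id: str,
                m: int, n: int, sc: AlignScoring) -> AlignmentHit:
    q0 = qoffset + w["q0"]
    q1 = qoffset + w["q1"]  # half-open on the aligned strand
    if strand == "+":
        q_start, q_end = q0 + 1, q1
    else:
        # coordinates on the plus strand of the query
        q_start, q_end = query_full_len - q1 + 1, query_full_len - q0
    s_start = soffset + w["s0"] + 1
    s_end = soffset + w["s1"]
    ident = w["n_match"] / w["aln_len"]
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        identity=ident,
        aln_len=w["aln_len"],
        query_cov=(q1 - q0) / query_full_len,
        bit_score=bit_score(w["score"], sc.lam, sc.k_const),
        evalue=evalue(w["score"], m, n, sc.lam, sc.k_const),
        q_start=q_start,
        q_end=q_end,
        s_start=s_start,
        s_end=s_end,
        strand=strand,
        raw_score=w["score"],
        n_match=w["n_match"],
        mismatches=w["n_mismatch"],
        gap_opens=w["n_gap_open"],
    )


def _overlap_frac(a0, a1, b0, b1) -> float:
    inter = min(a1, b1) - max(a0, b0)
    if inter <= 0:
        return 0.0
    return inter / max(1, min(a1 - a0, b1 - b0))


def local_align(query: str, subject: str, scoring: AlignScoring | None = None,
                query_id: str = "query", subject_id: str = "subject") -> list[AlignmentHit]:
    """Seed-and-extend local alignment of `query` against both strands of
    `subject`.

    Returns maximal-scoring, non-overlapping local hits with raw score above
    ``scoring.min_raw_score``, sorted by raw score descending (ties broken
    leftmost by q_start then s_start).
    """
    sc = scoring or DEFAULT_SCORING
    sc.validate()
    _check_acgt(query, "query")
    _check_acgt(subject, "subject")
    m, n = len(query), len(subject)
    hits: list[AlignmentHit] = []
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        for qa, qb, sa, sb in _seed_regions(qseq, subject, sc):
            w = _align_window(qseq[qa:qb], subject[sa:sb], sc)
            if w is None or w["score"] < sc.min_raw_score:
                continue
            hits.append(_window_hit(m, qa, sa, w, strand, query_id, subject_id, m, n, sc))
    hits.sort(key=lambda h: (-h.raw_score, h.q_start, h.s_start))
    kept: list[AlignmentHit] = []
    for h in hits:
        redundant = any(
            k.strand == h.strand
            and _overlap_frac(h.q_start, h.q_end, k.q_start, k.q_end) > 0.5
            and _overlap_frac(h.s_start, h.s_end, k.s_start, k.s_end) > 0.5
            for k in kept
        )
        if not redundant:
            kept.append(h)
    return kept


def align_pair(query: str, subject: str, scoring: AlignScoring | None = None,
               query_id: str = "query", subject_id: str = "subject") -> AlignmentHit | None:
    """Best local hit aligning `query` into `subject` without seeding.

    Suited to short queries (tRNAs, spacers-with-context) where a single
    alignment window spanning both sequences is cheap; both strands tried.
    """
    sc = scoring or DEFAULT_SCORING
    sc.validate()
    _check_acgt(query, "query")
    _check_acgt(subject, "subject")
    m, n = len(query), len(subject)
    best: AlignmentHit | None = None
    for strand, qseq in (("+", query), ("-", revcomp(query))):
        w = _align_window(qseq, subject, sc)
        if w is None:
            continue
        h = _window_hit(m, 0, 0, w, strand, query_id, subject_id, m, n, sc)
        if best is None or h.raw_score > best.raw_score:
            best = h
    return best


def merged_query_coverage(hits: Iterable[AlignmentHit], query_len: int) -> float:
    """Fraction of the query covered by the union of hit query intervals."""
    ivals = sorted((h.q_start, h.q_end) for h in hits)
    covered = 0
    cur_start = cur_end = None
    for a, b in ivals:
        if cur_end is None or a > cur_end + 1:
            if cur_end is not None:
                covered += cur_end - cur_start + 1
            cur_start, cur_end = a, b
        else:
            cur_end = max(cur_end, b)
    if cur_end is not None:
        covered += cur_end - cur_start + 1
    return covered / query_len


# ---------------------------------------------------------------------------
# CRISPR spacer matching
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpacerMatch:
    """Full-length spacer occurrence with at most `mismatches` substitutions.

    position is the 1-based start of the match on the plus strand of the
    contig regardless of strand.
    """

    spacer_id: str
    contig_id: str
    position: int
    strand: str
    mismatches: int


def find_spacer_matches(spacer: str, contig: str, max_mm: int = 1,
                        spacer_id: str = "spacer", contig_id: str = "contig",
                        min_spacer_len: int = 20) -> list[SpacerMatch]:
    """Every full-length, indel-free occurrence of `spacer` on either strand
    of `contig` with at most `max_mm` substitutions.

    A spacer longer than the contig yields an empty result.
    """
    _check_acgt(spacer, "spacer")
    _check_acgt(contig, "contig")
    if len(spacer) < min_spacer_len:
        raise ValueError(f"spacer shorter than {min_spacer_len} bp")
    L = len(spacer)
    if L > len(contig):
        return []
    carr = encode(contig)
    n_win = len(contig) - L + 1
    out: list[SpacerMatch] = []
    for strand, sp in (("+", spacer), ("-", revcomp(spacer))):
        sarr = encode(sp)
        mm = np.zeros(n_win, dtype=np.int32)
        for j in range(L):
            mm += carr[j : j + n_win] != sarr[j]
            # early exit impossible vectorised; L is small
        for pos in np.nonzero(mm <= max_mm)[0]:
            out.append(
                SpacerMatch(spacer_id, contig_id, int(pos) + 1, strand, int(mm[pos]))
            )
    out.sort(key=lambda s: (s.position, s.strand))
    return out


# ---------------------------------------------------------------------------
# ONF profiles and d2*
# ---------------------------------------------------------------------------


def _kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Integer code of every k-word (first base most significant)."""
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    for j in range(k):
        out += codes[j : j + n].astype(np.int64) * 4 ** (k - 1 - j)
    return out


def _count_words(seq: str, k: int) -> np.ndarray:
    codes = encode(seq)
    return np.bincount(_kmer_codes(codes, k), minlength=4**k).astype(np.float64)


@dataclass
class ONFProfile:
    """Observed k-word counts and Markov-null expected frequencies.

    Counts pool the sequence and its reverse complement (both-strand
    convention); expected frequencies come from an order-`order` Markov
    chain estimated from the same pooled sequence and sum to 1.
    """

    k: int
    order: int
    observed_counts: np.ndarray
    expected_freqs: np.ndarray
    seq_len: int

    @property
    def n_words(self) -> float:
        return float(self.observed_counts.sum())


def onf_profile(sequence: str, k: int = 6, order: int = 2) -> ONFProfile:
    """ONF profile of a sequence: pooled-strand k-word counts plus expected
    k-word frequencies under the order-`order` Markov null estimated from
    the same pooled sequence."""
    _check_acgt(sequence)
    if k <= order:
        raise ValueError("k must exceed the Markov null order")
    if len(sequence) < k:
        raise ValueError("sequence shorter than k")
    if len(sequence) < 4**order * 10:
        import warnings

        warnings.warn(
            f"sequence of {len(sequence)} bp is short for an order-{order} "
            "Markov null; expected frequencies will be noisy"
        )
    rc = revcomp(sequence)
    observed = _count_words(sequence, k) + _count_words(rc, k)

    if order == 0:
        mono = _count_words(sequence, 1) + _count_words(rc, 1)
        p1 = mono / mono.sum()
        expected = np.ones(4**k)
        for j in range(k):
            idx = (np.arange(4**k) // 4 ** (k - 1 - j)) % 4
            expected *= p1[idx]
    else:
        ctx_counts = _count_words(sequence, order) + _count_words(rc, order)
        trans_counts = _count_words(sequence, order + 1) + _count_words(rc, order + 1)
        trans = trans_counts.reshape(4**order, 4)
        row_sums = trans.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            trans_p = np.where(row_sums > 0, trans / row_sums, 0.0)
        p_ctx = ctx_counts / ctx_counts.sum()
        words = np.arange(4**k)
        # initial context = first `order` bases of the word
        expected = p_ctx[words // 4 ** (k - order)]
        for j in range(k - order):
            ctx = (words // 4 ** (k - order - j)) % 4**order
            nxt = (words // 4 ** (k - order - j - 1)) % 4
            expected *= trans_p[ctx, nxt]
    return ONFProfile(k, order, observed, expected, len(sequence))


def d2star(a: ONFProfile, b: ONFProfile) -> float:
    """d2* dissimilarity in [0, 1] between two ONF profiles.

    Counts are centered by their Markov-null expectations
    (X~_w = X_w - N p_w), standardised by sqrt(N p_w), and compared by a
    cosine-type similarity; the dissimilarity is (1 - similarity) / 2.
    Words with zero expected frequency in a profile are excluded from that
    profile's terms.
    """
    if a.k != b.k or a.order != b.order:
        raise ValueError("profiles differ in k or Markov order")
    na, nb = a.n_words, b.n_words
    ea = na * a.expected_freqs
    eb = nb * b.expected_freqs
    xa = a.observed_counts - ea
    xb = b.observed_counts - eb
    mask_a = ea > 0
    mask_b = eb > 0
    both = mask_a & mask_b
    denom = np.sqrt(ea[both]) * np.sqrt(eb[both])
    cross = float(np.sum(xa[both] * xb[both] / denom))
    norm_a = math.sqrt(float(np.sum(xa[mask_a] ** 2 / ea[mask_a])))
    norm_b = math.sqrt(float(np.sum(xb[mask_b] ** 2 / eb[mask_b])))
    if norm_a == 0 or norm_b == 0:
        return 0.5  # no compositional deviation to compare
    sim = cross / (norm_a * norm_b)
    sim = min(1.0, max(-1.0, sim))
    return (1.0 - sim) / 2.0


def d2star_sequences(a: str, b: str, k: int = 6, order: int = 2) -> float:
    """Convenience wrapper: d2* between two raw sequences."""
    return d2star(onf_profile(a, k, order), onf_profile(b, k, order))
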