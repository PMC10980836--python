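"""Four-channel in-silico virus-host prediction and consensus assignment.

Evidence channels, from most to least robust:

1. **CRISPR** — virus and a host genome bin both match the same spacer,
   each over the spacer's full length with at most one mismatch.
2. **tRNA** — a viral tRNA aligns to a host tRNA at >=90% identity over
   >=90% of the viral query length.
3. **nucleotide homology** — merged local hits from the vOTU representative
   (>=10 kb) to one host bin at e-value <= 1e-3, >=70% identity, >70% query
   coverage and >=50 bit-score (prophage-style signal).
4. **ONF** — alignment-free compositional similarity, d2* <= 0.2.

A consensus ("most probable") host per vOTU is chosen by: most distinct
supporting methods first; then best robustness rank (crispr > {trna,
nucleotide} > onf); among ONF-only candidates, lowest d2*. Ties that rest
on tRNA evidence for several hosts are returned UNRESOLVED.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import seqmatch
from .seqmatch import AlignScoring

UNRESOLVED = "UNRESOLVED"

#: robustness rank per method (lower = more robust); trna and nucleotide tie.
METHOD_RANK = {"crispr": 0, "trna": 1, "nucleotide": 1, "onf": 2}


@dataclass(frozen=True)
class LinkEvidence:
    """One piece of virus-host evidence.

    score is method-native: mismatches (crispr), identity (trna), bit score
    (nucleotide), d2* (onf). detail records the matching elements.
    """

    votu_id: str
    host_id: str
    method: str
    score: float
    detail: str = ""


@dataclass
class HostAssignment:
    """Consensus host for one vOTU with an audit trail of applied rules."""

    votu_id: str
    host_id: str
    supporting_methods: frozenset[str]
    rule_trace: list[str]
    n_candidate_hosts: int

    @property
    def resolved(self) -> bool:
        return self.host_id != UNRESOLVED


# ---------------------------------------------------------------------------
# Evidence collectors
# ---------------------------------------------------------------------------


def collect_crispr(
    spacers: Mapping[str, str],
    viral_contigs: Mapping[str, str],
    host_contigs_by_bin: Mapping[str, Mapping[str, str]],
    max_mm: int = 1,
) -> list[LinkEvidence]:
    """CRISPR spacer linkage: a vOTU and a host bin are linked when the same
    spacer matches both (full-length, <= max_mm mismatches each, either
    strand). One evidence record per (vOTU, bin) pair; score is the smaller
    of the two match mismatch-counts, minimized over shared spacers."""
    virus_hits: dict[str, list[tuple[str, int]]] = defaultdict(list)
    host_hits: dict[str, list[tuple[str, int]]] = defaultdict(list)
    for sp_id, sp in spacers.items():
        for v_id, v_seq in viral_contigs.items():
            for m in seqmatch.find_spacer_matches(sp, v_seq, max_mm, sp_id, v_id):
                virus_hits[sp_id].append((v_id, m.mismatches))
        for bin_id, contigs in host_contigs_by_bin.items():
            for c_id, c_seq in contigs.items():
                for m in seqmatch.find_spacer_matches(sp, c_seq, max_mm, sp_id, c_id):
                    host_hits[sp_id].append((bin_id, m.mismatches))
    best: dict[tuple[str, str], tuple[int, str]] = {}
    for sp_id in spacers:
        for v_id, v_mm in virus_hits.get(sp_id, ()):
            for bin_id, h_mm in host_hits.get(sp_id, ()):
                mm = max(v_mm, h_mm)
                key = (v_id, bin_id)
                if key not in best or mm < best[key][0]:
                    best[key] = (mm, f"spacer {sp_id} (virus {v_mm} mm, host {h_mm} mm)")
    return [
        LinkEvidence(v, h, "crispr", float(mm), detail)
        for (v, h), (mm, detail) in sorted(best.items())
    ]


def collect_trna(
    viral_trnas: Mapping[str, tuple[str, str]],
    host_trnas: Mapping[str, tuple[str, str]],
    min_identity: float = 0.90,
    min_query_frac: float = 0.90,
    scoring: AlignScoring | None = None,
) -> list[LinkEvidence]:
    """tRNA homology linkage.

    Both inputs map trna_id -> (owner entity id, sequence); owners are vOTU
    ids on the viral side and host-bin ids on the host side. A pair links
    when the viral tRNA aligns to a host tRNA at >= min_identity over
    >= min_query_frac of the viral query length. Score is identity.
    """
    best: dict[tuple[str, str], tuple[float, str]] = {}
    for vt_id, (v_id, v_seq) in viral_trnas.items():
        for ht_id, (h_id, h_seq) in host_trnas.items():
            hit = seqmatch.align_pair(v_seq, h_seq, scoring, vt_id, ht_id)
            if hit is None:
                continue
            span = (hit.q_end - hit.q_start + 1) / len(v_seq)
            if hit.identity >= min_identity and span >= min_query_frac:
                key = (v_id, h_id)
                if key not in best or hit.identity > best[key][0]:
                    best[key] = (hit.identity, f"{vt_id} ~ {ht_id}")
    return [
        LinkEvidence(v, h, "trna", ident, detail)
        for (v, h), (ident, detail) in sorted(best.items())
    ]


def collect_nucleotide(
    votu_seqs: Mapping[str, str],
    host_contigs_by_bin: Mapping[str, Mapping[str, str]],
    max_evalue: float = 1e-3,
    min_identity: float = 0.70,
    min_query_cov: float = 0.70,
    min_query_len: int = 10000,
    min_bit: float = 50.0,
    scoring: AlignScoring | None = None,
) -> list[LinkEvidence]:
    """Nucleotide-homology (prophage-style) linkage.

    Hits from a vOTU representative to all contigs of a host bin are
    filtered individually (e-value, identity, bit score) and their query
    intervals merged; the bin links when merged coverage exceeds
    min_query_cov (strict >). Queries below min_query_len are skipped.
    Score is the best hit bit score.
    """
    out = []
    for v_id, v_seq in votu_seqs.items():
        if len(v_seq) < min_query_len:
            continue
        for bin_id, contigs in host_contigs_by_bin.items():
            good = []
            for c_id, c_seq in contigs.items():
                for h in seqmatch.local_align(v_seq, c_seq, scoring, v_id, c_id):
                    if (
                        h.evalue <= max_evalue
                        and h.identity >= min_identity
                        and h.bit_score >= min_bit
                    ):
                        good.append(h)
            if not good:
                continue
            cov = seqmatch.merged_query_coverage(good, len(v_seq))
            if cov > min_query_cov:
                best = max(good, key=lambda h: h.bit_score)
                out.append(
                    LinkEvidence(
                        v_id,
                        bin_id,
                        "nucleotide",
                        best.bit_score,
                        f"merged query coverage {cov:.2f}; best hit {best.subject_id}"
                        f" id {best.identity:.2f}",
                    )
                )
    return out


def collect_onf(
    votu_seqs: Mapping[str, str],
    host_genomes: Mapping[str, str | Sequence[str]],
    max_d2star: float = 0.2,
    k: int = 6,
    order: int = 2,
) -> list[LinkEvidence]:
    """ONF compositional linkage: every (vOTU, host) pair with d2* <= 0.2
    (inclusive). Host genomes may be one sequence or a list of contigs,
    which are concatenated for profiling. Score is d2*."""
    host_profiles = {}
    for h_id, seqs in host_genomes.items():
        seq = seqs if isinstance(seqs, str) else "".join(seqs)
        host_profiles[h_id] = seqmatch.onf_profile(seq, k, order)
    out = []
    for v_id, v_seq in votu_seqs.items():
        vp = seqmatch.onf_profile(v_seq, k, order)
        for h_id, hp in host_profiles.items():
            d = seqmatch.d2star(vp, hp)
            if d <= max_d2star:
                out.append(LinkEvidence(v_id, h_id, "onf", d, f"d2*={d:.4f}"))
    return out


# ---------------------------------------------------------------------------
# Consensus assignment
# ---------------------------------------------------------------------------


def assign_most_probable_host(evidence: Iterable[LinkEvidence]) -> list[HostAssignment]:
    """Ranked consensus: one most-probable host per vOTU.

    Candidates are ranked by (i) number of distinct supporting methods,
    then (ii) best robustness rank among them. Remaining ties: ONF-only
    ties go to the lowest d2*; ties resting on tRNA support for several
    hosts are UNRESOLVED; a tRNA-vs-nucleotide tie is broken by the higher
    bit score when nucleotide evidence is present, else UNRESOLVED.
    The result is a pure function of the evidence multiset.
    """
    by_votu: dict[str, dict[str, list[LinkEvidence]]] = defaultdict(lambda: defaultdict(list))
    for ev in evidence:
        if ev.method not in METHOD_RANK:
            raise ValueError(f"unknown evidence method {ev.method!r}")
        by_votu[ev.votu_id][ev.host_id].append(ev)

    out: list[HostAssignment] = []
    for votu_id in sorted(by_votu):
        hosts = by_votu[votu_id]
        trace: list[str] = []

        def sort_key(h: str):
            methods = {e.method for e in hosts[h]}
            return (-len(methods), min(METHOD_RANK[m] for m in methods), h)

        ranked = sorted(hosts, key=sort_key)
        top_methods = {e.method for e in hosts[ranked[0]]}
        tied = [
            h
            for h in ranked
            if len({e.method for e in hosts[h]}) == len(top_methods)
            and min(METHOD_RANK[m] for m in {e.method for e in hosts[h]})
            == min(METHOD_RANK[m] for m in top_methods)
        ]
        trace.append(
            f"{len(hosts)} candidate hosts; top support {sorted(top_methods)} "
            f"({len(tied)} tied)"
        )
        if len(tied) == 1:
            winner = tied[0]
            trace.append("unique best-supported host")
        else:
            tied_methods = {m for h in tied for e in hosts[h] for m in [e.method]}
            if tied_methods == {"onf"}:
                best = min(
                    tied, key=lambda h: min(e.score for e in hosts[h] if e.method == "onf")
                )
                scores = sorted(
                    min(e.score for e in hosts[h] if e.method == "onf") for h in tied
                )
                if len(scores) > 1 and math.isclose(scores[0], scores[1]):
                    winner = UNRESOLVED
                    trace.append("ONF-only tie with equal d2*; unresolved")
                else:
                    winner = best
                    trace.append(f"ONF-only tie broken by lowest d2* ({scores[0]:.4f})")
            elif sum(1 for h in tied if any(e.method == "trna" for e in hosts[h])) > 1:
                winner = UNRESOLVED
                trace.append("multiple hosts tied on tRNA evidence; unresolved")
            elif any(any(e.method == "nucleotide" for e in hosts[h]) for h in tied):
                winner = max(
                    tied,
                    key=lambda h: max(
                        (e.score for e in hosts[h] if e.method == "nucleotide"),
                        default=-math.inf,
                    ),
                )
                trace.append("tie broken by highest nucleotide bit score")
            else:
                winner = UNRESOLVED
                trace.append("tie not resolvable by stated rules; unresolved")

        methods = (
            frozenset(e.method for e in hosts[winner]) if winner != UNRESOLVED else frozenset()
        )
        out.append(
            HostAssignment(
                votu_id=votu_id,
                host_id=winner,
                supporting_methods=methods,
                rule_trace=trace,
                n_candidate_hosts=len(hosts),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Host-range summary
# ---------------------------------------------------------------------------

RANGE_CLASSES = (
    "single-MAG specialist",
    "single-phylum",
    "multi-phylum same-domain",
    "cross-domain",
    "UNKNOWN",
)


def summarize_host_range(
    evidence: Iterable[LinkEvidence],
    host_taxonomy: Mapping[str, tuple[str, str]],
) -> dict[str, str]:
    """Classify each vOTU's host range from the full (pre-consensus)
    evidence set. host_taxonomy maps bin id -> (domain, phylum). A vOTU
    whose hosts include a bin missing from the taxonomy is UNKNOWN."""
    import warnings

    hosts_by_votu: dict[str, set[str]] = defaultdict(set)
    for ev in evidence:
        hosts_by_votu[ev.votu_id].add(ev.host_id)
    out: dict[str, str] = {}
    for votu_id, hosts in sorted(hosts_by_votu.items()):
        missing = [h for h in hosts if h not in host_taxonomy]
        if missing:
            warnings.warn(f"{votu_id}: hosts missing from taxonomy: {missing}")
            out[votu_id] = "UNKNOWN"
            continue
        if len(hosts) == 1:
            out[votu_id] = "single-MAG specialist"
            continue
        domains = {host_taxonomy[h][0] for h in hosts}
        phyla = {host_taxonomy[h] for h in hosts}
        if len(domains) > 1:
            out[votu_id] = "cross-domain"
        elif len(phyla) > 1:
            out[votu_id] = "multi-phylum same-domain"
        else:
            out[votu_id] = "single-phylum"
    return out
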