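"""Viral-contig filtering and species-level clustering into vOTUs.

The pipeline stage mirrors common virome practice: candidate viral contigs
(called upstream by several viral-identification tools whose scores are
consumed as a table) are screened by length and per-caller score gates,
exactly deduplicated (reverse-complement aware), greedily clustered at
>=95% average nucleotide identity over >=85% of the shorter sequence, and
finally checked for host contamination from the gene annotations of each
cluster representative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from . import seqmatch
from .seqmatch import AlignScoring, revcomp


@dataclass
class GeneAnnotation:
    """One gene call on a contig; 1-based inclusive coordinates.

    category is the upstream caller's verdict (viral / host / unknown);
    auxiliary_score and amg_flags carry AMG-caller metadata when present.
    """

    gene_id: str
    start: int
    end: int
    strand: str = "+"
    category: str = "unknown"
    function_label: str = ""
    auxiliary_score: int | None = None
    amg_flags: frozenset[str] = frozenset()
    caller: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"gene {self.gene_id}: start > end")
        if self.category not in ("viral", "host", "unknown"):
            raise ValueError(f"gene {self.gene_id}: bad category {self.category!r}")


@dataclass
class Contig:
    """A nucleotide sequence with caller scores and per-gene annotations."""

    id: str
    sequence: str
    sample_id: str = ""
    caller_scores: dict[str, float] = field(default_factory=dict)
    genes: list[GeneAnnotation] = field(default_factory=list)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class VOTU:
    """A cluster of viral contigs with its representative and filter trail."""

    representative_id: str
    member_ids: list[str]
    rep_length: int
    verdicts: list[tuple[str, bool, str]] = field(default_factory=list)

    @property
    def retained(self) -> bool:
        return all(ok for _, ok, _ in self.verdicts)


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

#: per-caller retention rules; callers are identified by the score-map key.
SCREEN_CALLERS = ("virsorter", "vibrant", "deepvirfinder")


def screen_contigs(
    contigs: Iterable[Contig],
    min_len: int = 5000,
    score_min: float = 0.9,
    p_max: float = 0.05,
) -> tuple[list[Contig], list[tuple[str, bool, str]]]:
    """Length + per-caller score screen for candidate viral contigs.

    A contig is retained when its length is >= min_len and at least one
    caller rule fires: score > score_min for the VirSorter2-like caller;
    any call at all for the VIBRANT-like caller; score > score_min AND
    p < p_max for the DeepVirFinder-like caller. Returns the retained
    contigs plus a per-contig provenance log of (id, retained, reason).
    """
    retained: list[Contig] = []
    log: list[tuple[str, bool, str]] = []
    for c in contigs:
        if not c.caller_scores:
            log.append((c.id, False, "no caller scores"))
            continue
        if c.length < min_len:
            log.append((c.id, False, f"length {c.length} < {min_len}"))
            continue
        fired = []
        s = c.caller_scores
        if s.get("virsorter", -1.0) > score_min:
            fired.append("virsorter score")
        if "vibrant" in s:
            fired.append("vibrant call")
        if s.get("deepvirfinder", -1.0) > score_min and s.get("deepvirfinder_p", 1.0) < p_max:
            fired.append("deepvirfinder score+p")
        if fired:
            retained.append(c)
            log.append((c.id, True, "; ".join(fired)))
        else:
            log.append((c.id, False, "no caller rule fired"))
    return retained, log


# ---------------------------------------------------------------------------
# Exact dedup
# ---------------------------------------------------------------------------


def dedupe_exact(contigs: Sequence[Contig], collapse_rc: bool = True) -> list[Contig]:
    """Collapse byte-identical contigs (and, by default, exact
    reverse-complement duplicates) keeping the lexicographically smallest id."""
    best: dict[str, Contig] = {}
    order: list[str] = []
    for c in contigs:
        key = min(c.sequence, revcomp(c.sequence)) if collapse_rc else c.sequence
        cur = best.get(key)
        if cur is None:
            best[key] = c
            order.append(key)
        elif c.id < cur.id:
            best[key] = c
    return [best[k] for k in order]


# ---------------------------------------------------------------------------
# ANI and clustering
# ---------------------------------------------------------------------------


def pairwise_ani(a: Contig, b: Contig, scoring: AlignScoring | None = None) -> tuple[float, float]:
    """(ANI, coverage-of-shorter) from merged local-alignment blocks.

    ANI is the alignment-length-weighted mean identity over all retained
    local hits; coverage is the fraction of the shorter sequence covered by
    the union of its hit intervals. Returns (0, 0) when nothing aligns.
    """
    if a.length <= b.length:
        query, subject = a, b
    else:
        query, subject = b, a
    hits = seqmatch.local_align(
        query.sequence, subject.sequence, scoring, query_id=query.id, subject_id=subject.id
    )
    if not hits:
        return 0.0, 0.0
    total = sum(h.aln_len for h in hits)
    ani = sum(h.identity * h.aln_len for h in hits) / total
    cov = seqmatch.merged_query_coverage(hits, query.length)
    return ani, min(1.0, cov)


def cluster_votus(
    contigs: Sequence[Contig],
    ani_min: float = 0.95,
    cov_min: float = 0.85,
    rep_min_len: int = 10000,
    scoring: AlignScoring | None = None,
) -> list[VOTU]:
    """Greedy centroid clustering into vOTUs.

    Contigs are sorted by length descending (ties broken by id); each joins
    the first existing representative it matches at >= ani_min identity over
    >= cov_min of the shorter sequence, otherwise it founds a new cluster.
    The longest member is the representative. Clusters whose representative
    is shorter than rep_min_len carry a failing verdict (not silently
    dropped); use ``[v for v in out if v.retained]`` for the retained set.
    """
    ordered = sorted(contigs, key=lambda c: (-c.length, c.id))
    reps: list[Contig] = []
    members: dict[str, list[str]] = {}
    for c in ordered:
        placed = False
        for rep in reps:
            ani, cov = pairwise_ani(c, rep, scoring)
            if ani >= ani_min and cov >= cov_min:
                members[rep.id].append(c.id)
                placed = True
                break
        if not placed:
            reps.append(c)
            members[c.id] = [c.id]
    out = []
    for rep in reps:
        ok = rep.length >= rep_min_len
        detail = f"representative {rep.length} bp (min {rep_min_len})"
        out.append(
            VOTU(
                representative_id=rep.id,
                member_ids=members[rep.id],
                rep_length=rep.length,
                verdicts=[("rep_length", ok, detail)],
            )
        )
    return out


# ---------------------------------------------------------------------------
# Host-contamination filter
# ---------------------------------------------------------------------------


def host_contamination_filter(
    votu: VOTU,
    rep_genes: Sequence[GeneAnnotation],
    host_bp_max_frac: float = 0.30,
    host_viral_ratio_max: float = 10.0,
) -> tuple[bool, str]:
    """Flag vOTUs that look like mis-called host sequence.

    FAILS (returns (False, reason)) when any of: no viral genes at all;
    summed host-gene span exceeds 30% of the representative length; or the
    host:viral gene-count ratio exceeds 10:1 (strict >). The verdict is also
    appended to the vOTU's audit trail.
    """
    n_viral = sum(1 for g in rep_genes if g.category == "viral")
    n_host = sum(1 for g in rep_genes if g.category == "host")
    host_bp = sum(g.end - g.start + 1 for g in rep_genes if g.category == "host")
    reasons = []
    if n_viral == 0:
        reasons.append("viral gene count = 0")
    if host_bp / votu.rep_length > host_bp_max_frac:
        reasons.append(
            f"host genes span {host_bp / votu.rep_length:.0%} of representative (> {host_bp_max_frac:.0%})"
        )
    if n_viral > 0 and n_host / n_viral > host_viral_ratio_max:
        reasons.append(f"host:viral gene ratio {n_host}:{n_viral} > {host_viral_ratio_max}:1")
    passed = not reasons
    votu.verdicts.append(
        ("host_contamination", passed, "; ".join(reasons) if reasons else "clean")
    )
    return passed, "; ".join(reasons) if reasons else "clean"
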