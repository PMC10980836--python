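"""Auxiliary-metabolic-gene (AMG) confidence classification.

Candidate AMGs come from two upstream annotation callers: a DRAM-v-like
caller ("callerA") that emits an auxiliary score and single-letter flags
per gene, and a VIBRANT-like caller ("callerB") that emits bare AMG calls.
The rule engine applied here:

* callerA metabolic filter — auxiliary_score <= 3, flag 'M' present, and
  none of the contamination/structural flags T, F, V, A, P or B;
* genomic-context check — the candidate must be preceded AND followed on
  its contig by genes with viral annotations (not necessarily adjacent);
* cross-matching — genes passing the filter that both callers predict are
  "high" confidence, callerA-only genes are "low"; callerB-only calls are
  recorded but left unclassified;
* host-homology — where the vOTU has an assigned host with protein
  sequences, the AMG protein is locally aligned (BLOSUM62) against the
  host proteome and classed identical (100% identity over >=50% of the
  query), homologous (>30% identity over >=50%), or divergent_or_none.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Align import PairwiseAligner, substitution_matrices

from .votu import GeneAnnotation

#: flags that disqualify a callerA AMG call (transposon, flank, viral-like,
#: attachment, provirus boundary, and B-flagged categories).
EXCLUDED_FLAGS = frozenset("TFVAPB")
REQUIRED_FLAG = "M"

CONFIDENCE_VALUES = ("high", "low", "rejected", "unclassified")
HOMOLOGY_CLASSES = ("identical", "homologous", "divergent_or_none", "no_host")


@dataclass
class AMGCall:
    """Classified AMG candidate with the rule that decided its fate."""

    gene_id: str
    votu_id: str
    caller_set: frozenset[str]
    auxiliary_score: int | None = None
    amg_flags: frozenset[str] = frozenset()
    flanking_ok: bool = False
    confidence: str = "rejected"
    rule_fired: str = ""
    host_homology: str = "no_host"


def filter_amg(
    auxiliary_score: int | None,
    amg_flags: Iterable[str],
    on_transposon_scaffold: bool = False,
    near_scaffold_end: bool = False,
) -> tuple[bool, str]:
    """CallerA metabolic filter.

    PASS iff auxiliary_score <= 3 AND 'M' in flags AND no excluded flag
    (T/F/V/A/P/B). Transposon-scaffold and scaffold-end exclusions are
    consumed as upstream booleans and applied as reject rules.
    """
    flags = frozenset(amg_flags)
    if on_transposon_scaffold:
        return False, "gene on transposon-bearing scaffold"
    if near_scaffold_end:
        return False, "gene near scaffold end"
    if auxiliary_score is None:
        return False, "auxiliary_score missing"
    if auxiliary_score > 3:
        return False, f"auxiliary_score {auxiliary_score} > 3"
    if REQUIRED_FLAG not in flags:
        return False, "metabolic flag M absent"
    bad = flags & EXCLUDED_FLAGS
    if bad:
        return False, f"excluded flag(s) {''.join(sorted(bad))}"
    return True, "auxiliary_score <= 3, flag M, no excluded flags"


def flanking_check(
    gene_id: str,
    contig_genes: Sequence[GeneAnnotation],
    require_adjacent: bool = False,
) -> bool:
    """True iff a viral-annotated gene lies strictly before AND strictly
    after the candidate on the same contig (ordered by start coordinate).
    With require_adjacent=True the immediate neighbours must be viral."""
    ordered = sorted(contig_genes, key=lambda g: (g.start, g.gene_id))
    idx = next((i for i, g in enumerate(ordered) if g.gene_id == gene_id), None)
    if idx is None:
        raise ValueError(f"gene {gene_id} not found on contig")
    before = ordered[:idx]
    after = ordered[idx + 1 :]
    if require_adjacent:
        return bool(before) and bool(after) and before[-1].category == "viral" and after[0].category == "viral"
    return any(g.category == "viral" for g in before) and any(
        g.category == "viral" for g in after
    )


def classify_amg(
    gene_id: str,
    votu_id: str,
    caller_set: Iterable[str],
    auxiliary_score: int | None,
    amg_flags: Iterable[str],
    flanking_ok: bool,
    on_transposon_scaffold: bool = False,
    near_scaffold_end: bool = False,
) -> AMGCall:
    """Full per-gene classification (filter, flanking, then cross-match).

    callerB-only calls are recorded with confidence "unclassified": the
    metabolic filter operates on callerA metadata, so they can be neither
    confirmed nor rejected here.
    """
    callers = frozenset(caller_set)
    call = AMGCall(
        gene_id=gene_id,
        votu_id=votu_id,
        caller_set=callers,
        auxiliary_score=auxiliary_score,
        amg_flags=frozenset(amg_flags),
        flanking_ok=flanking_ok,
    )
    if "callerA" not in callers:
        call.confidence = "unclassified"
        call.rule_fired = "callerB-only call; recorded, not classified"
        return call
    ok, rule = filter_amg(
        auxiliary_score, amg_flags, on_transposon_scaffold, near_scaffold_end
    )
    if not ok:
        call.confidence = "rejected"
        call.rule_fired = rule
        return call
    if not flanking_ok:
        call.confidence = "rejected"
        call.rule_fired = "not flanked by viral genes"
        return call
    if "callerB" in callers:
        call.confidence = "high"
        call.rule_fired = "passed filter; predicted by both callers"
    else:
        call.confidence = "low"
        call.rule_fired = "passed filter; callerA only"
    return call


def cross_match(calls: Iterable[AMGCall]) -> dict[str, str]:
    """Confidence per gene id from an already-classified call set."""
    return {c.gene_id: c.confidence for c in calls}


# ---------------------------------------------------------------------------
# Host homology
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"


def _protein_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11
    aligner.extend_gap_score = -1
    return aligner


def host_homology_class(
    amg_protein: str,
    host_proteins: Mapping[str, str] | None,
    identity_min: float = 0.30,
    cov_min: float = 0.50,
) -> str:
    """Relatedness of an AMG protein to its assigned host's proteome.

    identical: a host protein matches at 100% identity over >=50% of the
    viral query; homologous: >30% identity over >=50%; otherwise
    divergent_or_none. no_host when no host assignment/proteome exists.
    Identity is counted over aligned columns of the best local alignment;
    coverage is the aligned query span as a fraction of query length.
    """
    if not amg_protein:
        raise ValueError("empty AMG protein sequence")
    if not host_proteins:
        return "no_host"
    aligner = _protein_aligner()
    best_class = "divergent_or_none"
    for h_seq in host_proteins.values():
        if not h_seq:
            raise ValueError("empty host protein sequence")
        try:
            aln = aligner.align(amg_protein, h_seq)[0]
        except IndexError:
            continue
        counts = aln.counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        if cols == 0:
            continue
        identity = counts.identities / cols
        q_span = aln.aligned[0][-1][1] - aln.aligned[0][0][0]
        cov = q_span / len(amg_protein)
        if cov >= cov_min:
            if identity >= 1.0 - 1e-9:
                return "identical"
            if identity > identity_min:
                best_class = "homologous"
    return best_class
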