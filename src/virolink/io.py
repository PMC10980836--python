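"""Readers and writers for the pipeline's plain-text interchange files."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .votu import Contig, GeneAnnotation


def write_fasta(path: str | Path, sequences: Mapping[str, str]) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gene_annotations(path: str | Path, contigs: Iterable[Contig]) -> None:
    rows = []
    for c in contigs:
        for g in c.genes:
            rows.append({
                "contig_id": c.id,
                "gene_id": g.gene_id,
                "start": g.start,
                "end": g.end,
                "strand": g.strand,
                "category": g.category,
                "function_label": g.function_label,
                "auxiliary_score": "" if g.auxiliary_score is None else g.auxiliary_score,
                "amg_flags": "".join(sorted(g.amg_flags)),
                "caller": g.caller,
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_annotations(path: str | Path) -> dict[str, list[GeneAnnotation]]:
    """gene_annotations.tsv -> genes grouped by contig id."""
    df = pd.read_csv(path, sep="\t", dtype={"amg_flags": str}, keep_default_na=False)
    out: dict[str, list[GeneAnnotation]] = {}
    for rec in df.itertuples():
        score = rec.auxiliary_score
        score = None if score in ("", None) else int(float(score))
        out.setdefault(rec.contig_id, []).append(
            GeneAnnotation(
                gene_id=rec.gene_id,
                start=int(rec.start),
                end=int(rec.end),
                strand=rec.strand,
                category=rec.category,
                function_label=rec.function_label,
                auxiliary_score=score,
                amg_flags=frozenset(rec.amg_flags or ""),
                caller=rec.caller,
            )
        )
    return out


def read_trna_tables(trna_tsv: str | Path, trna_fasta: str | Path,
                     viral_ids: set[str]) -> tuple[dict, dict]:
    """(viral_trnas, host_trnas), each trna_id -> (owner id, sequence)."""
    coords = pd.read_csv(trna_tsv, sep="\t")
    seqs = read_fasta(trna_fasta)
    viral, host = {}, {}
    for rec in coords.itertuples():
        target = viral if rec.entity_id in viral_ids else host
        target[rec.trna_id] = (rec.entity_id, seqs[rec.trna_id])
    return viral, host


def write_links(path: str | Path, evidence) -> None:
    pd.DataFrame(
        [{"votu_id": e.votu_id, "host_id": e.host_id, "method": e.method,
          "score": e.score, "detail": e.detail} for e in evidence]
    ).to_csv(path, sep="\t", index=False)


def write_assignments(path: str | Path, assignments) -> None:
    pd.DataFrame(
        [{"votu_id": a.votu_id, "host_id": a.host_id,
          "supporting_methods": ",".join(sorted(a.supporting_methods)),
          "n_candidate_hosts": a.n_candidate_hosts,
          "rule_trace": " | ".join(a.rule_trace)} for a in assignments]
    ).to_csv(path, sep="\t", index=False)


def write_votus(path: str | Path, votus) -> None:
    pd.DataFrame(
        [{"representative_id": v.representative_id,
          "members": ",".join(v.member_ids),
          "n_members": len(v.member_ids),
          "rep_length": v.rep_length,
          "retained": v.retained,
          "verdicts": "; ".join(f"{n}:{'pass' if ok else 'FAIL'}({d})"
                                 for n, ok, d in v.verdicts)} for v in votus]
    ).to_csv(path, sep="\t", index=False)
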