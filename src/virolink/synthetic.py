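"""Synthetic groundwater-like community with machine-readable ground truth.

The generator emulates the study design the pipeline targets — a set of
prokaryotic genome bins (hosts), viral contigs, CRISPR spacers, tRNAs,
per-sample read-mapping summaries for 16 metagenomes, per-gene transcript
counts for 6 metatranscriptomes, and an environmental parameter table —
entirely in silico, so every downstream stage can be tested against
planted truth without any sequencing data.

Compositional structure comes from per-lineage Markov chains: each host
lineage has its own fixed-order transition matrix, "host-derived" viruses
are emitted from their designated host's chain (creating an ONF linkage
signal), and "unrelated" viruses from an independent chain. Virus-host
linkage signals are planted explicitly:

* **crispr** — a repeat-spacer-repeat array inserted into the host, one
  spacer copied from a viral protospacer with a configured number of
  substitutions (plus optional 2-mismatch decoy spacers that must *not*
  link under the <=1-mismatch matcher);
* **trna** — a ~75 bp tRNA-like segment inserted into both genomes at a
  configured identity;
* **prophage** — a contiguous viral region copied into the host at a
  configured identity and fraction of the virus length.

Per-sample abundances are linearly coupled to environmental covariates
(truncated-Gaussian coverage, negative draws set to zero), with paired
host/virus entities sharing the same coupling. All randomness flows
through a single seeded generator: identical configs give byte-identical
outputs. Sequences are uppercase ACGT only; ambiguity codes unsupported.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .seqmatch import revcomp
from .votu import Contig, GeneAnnotation

_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"
TRNA_LEN = 75


@dataclass(frozen=True)
class PlantedLink:
    """One planted virus-host signal (indices into the virus/host lists)."""

    virus: int
    host: int
    channel: str  # crispr | trna | prophage
    mismatches: int = 0  # crispr: substitutions between spacer and protospacer
    identity: float = 1.0  # trna / prophage: fraction of preserved bases
    fraction: float = 0.8  # prophage: fraction of virus length copied

    def validate(self, n_viruses: int, n_hosts: int) -> None:
        if self.channel not in ("crispr", "trna", "prophage"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if not (0 <= self.virus < n_viruses):
            raise ValueError(f"virus index {self.virus} out of range")
        if not (0 <= self.host < n_hosts):
            raise ValueError(f"host index {self.host} out of range")
        if not (0.0 <= self.identity <= 1.0):
            raise ValueError("identity must be in [0, 1]")
        if not (0.0 < self.fraction <= 1.0):
            raise ValueError("fraction must be in (0, 1]")
        if self.mismatches < 0:
            raise ValueError("mismatches must be >= 0")


@dataclass(frozen=True)
class Coupling:
    """Linear coverage-covariate coupling for one entity."""

    entity: str
    covariate: str
    slope: float
    intercept: float = 1.0
    noise_sd: float = 0.15


@dataclass(frozen=True)
class PlantedAMG:
    """One planted AMG-candidate gene with its expected classification."""

    virus: int
    gene_index: int
    auxiliary_score: int
    flags: str
    callers: str  # "A", "B" or "AB"
    transposon: bool = False
    expected_confidence: str = "high"
    homology: str = "divergent_or_none"  # planted protein relationship to host


def _default_links() -> list[PlantedLink]:
    crispr_mm = [0, 0, 0, 0, 1, 1, 0, 1]
    prophage_id = [0.75, 0.80, 0.85, 0.90, 0.78]
    links = [
        PlantedLink(i, i, "crispr", mismatches=mm) for i, mm in enumerate(crispr_mm)
    ]
    links += [
        PlantedLink(8 + j, 8 + j, "prophage", identity=ident, fraction=0.8)
        for j, ident in enumerate(prophage_id)
    ]
    links += [PlantedLink(13 + j, 13 + j, "trna", identity=1.0) for j in range(4)]
    return links


def _default_amgs() -> list[PlantedAMG]:
    return [
        PlantedAMG(0, 3, 2, "M", "AB", expected_confidence="high", homology="identical"),
        PlantedAMG(1, 3, 3, "M", "A", expected_confidence="low", homology="homologous"),
        PlantedAMG(2, 3, 2, "MF", "AB", expected_confidence="rejected"),
        PlantedAMG(3, 3, 4, "M", "AB", expected_confidence="rejected"),
        PlantedAMG(4, 3, 1, "M", "B", expected_confidence="unclassified"),
        PlantedAMG(5, 0, 2, "M", "AB", expected_confidence="rejected"),  # first gene
        PlantedAMG(6, 3, 2, "M", "AB", transposon=True, expected_confidence="rejected"),
        PlantedAMG(7, 3, 1, "MT", "A", expected_confidence="rejected"),
    ]


DEFAULT_ENV_PARAMS = (
    "DO", "DOC", "nitrate", "iron", "sulfate", "ammonium", "pH", "temperature",
)

# plausible groundwater ranges, mg/l except pH and temperature (deg C)
_ENV_RANGES = {
    "DO": (0.2, 9.0),
    "DOC": (0.3, 3.0),
    "nitrate": (0.05, 6.0),
    "iron": (0.01, 2.5),
    "sulfate": (1.0, 30.0),
    "ammonium": (0.01, 1.0),
    "pH": (6.0, 8.0),
    "temperature": (11.0, 16.0),
}


@dataclass
class SimConfig:
    """Configuration of the synthetic community.

    Defaults mirror the study layout the pipeline models: 16 metagenome
    samples, 6 metatranscriptomes, 20 host bins, 30 viruses with a core of
    planted crispr/prophage/trna links, and fully lineage-specific
    order-2 Markov composition (divergence 1.0).
    """

    seed: int
    n_hosts: int = 20
    n_viruses: int = 30
    n_samples: int = 16
    n_expression_samples: int = 6
    host_genome_len: int = 50_000
    virus_len_range: tuple[int, int] = (12_000, 15_000)
    markov_order: int = 2
    lineage_divergence: float = 1.0  # 0 = all lineages share one chain
    dirichlet_alpha: float = 1.0  # uniform over transition simplexes
    spacer_len: int = 32
    repeat_len: int = 28
    spacers_per_array: int = 5
    n_host_derived: int = 25  # remaining viruses come from an unrelated chain
    planted_links: list[PlantedLink] | None = None
    n_decoy_spacers: int = 3
    decoy_mismatches: int = 2
    planted_amgs: list[PlantedAMG] | None = None
    env_params: tuple[str, ...] = DEFAULT_ENV_PARAMS
    coupling: list[Coupling] | None = None
    n_coupled_pairs: int = 5
    coupling_noise_sd: float = 0.15
    library_size: int = 2_000_000
    expression_library_size: int = 1_000_000
    gene_len: int = 900
    gene_spacing: int = 100

    def validate(self) -> None:
        for name in ("n_hosts", "n_viruses", "n_samples", "n_expression_samples",
                     "host_genome_len", "spacer_len", "library_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.virus_len_range[0] < 1_000:
            raise ValueError("virus_len_range minimum must be >= 1000 bp")
        if self.virus_len_range[0] < 10_000:
            warnings.warn("virus_len_range minimum below 10 kb: such viruses "
                          "will be dropped by vOTU retention (noted in truth)")
        if self.virus_len_range[0] > self.virus_len_range[1]:
            raise ValueError("virus_len_range must be (min, max)")
        if not (0.0 <= self.lineage_divergence <= 1.0):
            raise ValueError("lineage_divergence must be in [0, 1]")
        if self.markov_order < 0 or self.markov_order > 4:
            raise ValueError("markov_order must be in 0..4")
        if self.n_host_derived > self.n_viruses:
            raise ValueError("n_host_derived exceeds n_viruses")
        for link in self.links():
            link.validate(self.n_viruses, self.n_hosts)

    def links(self) -> list[PlantedLink]:
        if self.planted_links is not None:
            return self.planted_links
        return [
            l for l in _default_links()
            if l.virus < self.n_viruses and l.host < self.n_hosts
        ]

    def amgs(self) -> list[PlantedAMG]:
        if self.planted_amgs is not None:
            return self.planted_amgs
        return [a for a in _default_amgs() if a.virus < self.n_viruses]


@dataclass
class Community:
    """In-memory synthetic community plus its ground truth."""

    config: SimConfig
    hosts: dict[str, str]
    host_taxonomy: dict[str, tuple[str, str]]
    viruses: dict[str, str]
    virus_contigs: list[Contig]
    spacers: dict[str, str]
    viral_trnas: dict[str, tuple[str, str]]
    host_trnas: dict[str, tuple[str, str]]
    trna_coords: pd.DataFrame
    amg_calls: pd.DataFrame
    amg_proteins: dict[str, str]
    host_proteins: dict[str, dict[str, str]]
    mapped_lengths: pd.DataFrame
    read_counts: pd.DataFrame
    env: pd.DataFrame
    truth: dict

    @property
    def host_contigs_by_bin(self) -> dict[str, dict[str, str]]:
        return {h: {f"{h}_c1": seq} for h, seq in self.hosts.items()}

    @property
    def entity_lengths(self) -> dict[str, int]:
        out = {h: len(s) for h, s in self.hosts.items()}
        out.update({v: len(s) for v, s in self.viruses.items()})
        return out

    @property
    def library_sizes(self) -> dict[str, float]:
        return {s: float(self.config.library_size) for s in self.env.index}


# ---------------------------------------------------------------------------
# Markov emission
# ---------------------------------------------------------------------------


def _random_transition(rng: np.random.Generator, order: int, alpha: float) -> np.ndarray:
    return rng.dirichlet([alpha] * 4, size=4**order)


def _mix(base: np.ndarray, own: np.ndarray, divergence: float) -> np.ndarray:
    return (1.0 - divergence) * base + divergence * own


def _emit(rng: np.random.Generator, trans: np.ndarray, order: int, length: int) -> str:
    """Emit `length` bases from a fixed-order Markov chain."""
    if order == 0:
        probs = trans.reshape(-1)[:4]
        return "".join(rng.choice(list(_BASES), size=length, p=probs / probs.sum()))
    cum = np.cumsum(trans, axis=1)
    cum_list = [(float(row[0]), float(row[1]), float(row[2])) for row in cum]
    out = bytearray()
    start = rng.integers(0, 4, size=order)
    ctx = 0
    for b in start:
        out.append(b)
        ctx = ctx * 4 + int(b)
    mod = 4 ** (order - 1)
    us = rng.random(length)
    for i in range(order, length):
        c = cum_list[ctx]
        u = us[i]
        b = int(u > c[0]) + int(u > c[1]) + int(u > c[2])
        out.append(b)
        ctx = (ctx % mod) * 4 + b
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[np.frombuffer(bytes(out[:length]), dtype=np.uint8)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute bases at rate (1 - identity); no indels."""
    arr = list(seq)
    n_sub = int(round((1.0 - identity) * len(arr)))
    if n_sub == 0:
        return seq
    pos = rng.choice(len(arr), size=n_sub, replace=False)
    for p in pos:
        arr[p] = _BASES[(_BASES.index(arr[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def _substitute_k(rng: np.random.Generator, seq: str, k: int) -> str:
    """Exactly k substitutions at distinct positions."""
    arr = list(seq)
    for p in rng.choice(len(arr), size=k, replace=False):
        arr[p] = _BASES[(_BASES.index(arr[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(arr)


def _insert(seq: str, payload: str, pos: int) -> str:
    return seq[:pos] + payload + seq[pos:]


def _rand_protein(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_AA), size=length))


def _mutate_protein(rng: np.random.Generator, seq: str, identity: float) -> str:
    arr = list(seq)
    n_sub = int(round((1.0 - identity) * len(arr)))
    for p in rng.choice(len(arr), size=n_sub, replace=False):
        cur = arr[p]
        choices = [a for a in _AA if a != cur]
        arr[p] = choices[int(rng.integers(len(choices)))]
    return "".join(arr)


# ---------------------------------------------------------------------------
# Generation stages
# ---------------------------------------------------------------------------


def generate_hosts(config: SimConfig, rng: np.random.Generator):
    """Per-lineage Markov genomes plus lineage labels and a toy taxonomy.

    Each host is its own lineage; the lineage transition matrix is a
    divergence-weighted mix of a shared base chain and a lineage-specific
    Dirichlet draw, so inter-lineage hexamer profiles separate as
    divergence grows.
    """
    config.validate()
    order = config.markov_order
    base = _random_transition(rng, order, 1.0)
    phyla = ["Pseudomonadota", "Patescibacteria", "Nitrospirota", "Omnitrophota",
             "Nanoarchaeota", "Thermoproteota"]
    domains = {"Nanoarchaeota": "Archaea", "Thermoproteota": "Archaea"}
    hosts: dict[str, str] = {}
    taxonomy: dict[str, tuple[str, str]] = {}
    chains: dict[str, np.ndarray] = {}
    for i in range(config.n_hosts):
        hid = f"host_{i:03d}"
        own = _random_transition(rng, order, config.dirichlet_alpha)
        chain = _mix(base, own, config.lineage_divergence)
        chains[hid] = chain
        hosts[hid] = _emit(rng, chain, order, config.host_genome_len)
        phylum = phyla[i % len(phyla)]
        taxonomy[hid] = (domains.get(phylum, "Bacteria"), phylum)
    return hosts, taxonomy, chains, base


def generate_viruses(config: SimConfig, rng: np.random.Generator,
                     chains: dict[str, np.ndarray], links: Sequence[PlantedLink]):
    """Viral contigs: host-derived viruses share their source host's chain,
    the rest come from an independent chain. Returns (sequences,
    source-host map, warnings)."""
    order = config.markov_order
    unrelated = _random_transition(rng, order, config.dirichlet_alpha)
    host_ids = sorted(chains)
    link_host = {l.virus: host_ids[l.host] for l in links}
    sources: dict[str, str | None] = {}
    seqs: dict[str, str] = {}
    notes: list[str] = []
    for i in range(config.n_viruses):
        vid = f"vir_{i:03d}"
        length = int(rng.integers(config.virus_len_range[0], config.virus_len_range[1] + 1))
        if length < 10_000:
            notes.append(f"{vid}: requested length {length} < 10 kb; "
                         "will be dropped by vOTU retention")
        if i < config.n_host_derived:
            src = link_host.get(i, host_ids[i % len(host_ids)])
            seqs[vid] = _emit(rng, chains[src], order, length)
            sources[vid] = src
        else:
            seqs[vid] = _emit(rng, unrelated, order, length)
            sources[vid] = None
    return seqs, sources, notes


def _plant_all_links(config: SimConfig, rng: np.random.Generator,
                     hosts: dict[str, str], viruses: dict[str, str],
                     links: Sequence[PlantedLink]):
    """Apply every planted link, mutating host/virus sequences.

    Returns (spacers, viral_trnas, host_trnas, trna_rows, truth_links).
    Insertion points are drawn away from sequence ends; planting order is
    fixed by the link list so outputs stay deterministic.
    """
    host_ids = sorted(hosts)
    virus_ids = sorted(viruses)
    spacers: dict[str, str] = {}
    viral_trnas: dict[str, tuple[str, str]] = {}
    host_trnas: dict[str, tuple[str, str]] = {}
    trna_rows: list[dict] = []
    truth_links: list[dict] = []
    repeat = "".join(rng.choice(list(_BASES), size=config.repeat_len))

    def random_spacer() -> str:
        return "".join(rng.choice(list(_BASES), size=config.spacer_len))

    def build_array(special: str) -> tuple[str, list[str]]:
        spacer_list = [random_spacer() for _ in range(config.spacers_per_array - 1)]
        slot = int(rng.integers(config.spacers_per_array))
        spacer_list.insert(slot, special)
        arr = repeat + repeat.join(spacer_list) + repeat
        return arr, spacer_list

    n_sp = 0
    for link in links:
        vid = virus_ids[link.virus]
        hid = host_ids[link.host]
        if link.channel == "crispr":
            vseq = viruses[vid]
            start = int(rng.integers(500, len(vseq) - 500 - config.spacer_len))
            protospacer = vseq[start : start + config.spacer_len]
            spacer = (
                _substitute_k(rng, protospacer, link.mismatches)
                if link.mismatches
                else protospacer
            )
            array, all_spacers = build_array(spacer)
            pos = int(rng.integers(500, len(hosts[hid]) - 500))
            hosts[hid] = _insert(hosts[hid], array, pos)
            for s in all_spacers:
                spacers[f"spacer_{n_sp:03d}"] = s
                n_sp += 1
            truth_links.append(
                {"virus": vid, "host": hid, "channel": "crispr",
                 "mismatches": link.mismatches, "protospacer_start": start + 1}
            )
        elif link.channel == "trna":
            t = "".join(rng.choice(list(_BASES), size=TRNA_LEN))
            host_copy = _mutate(rng, t, link.identity)
            vpos = int(rng.integers(500, len(viruses[vid]) - 500))
            hpos = int(rng.integers(500, len(hosts[hid]) - 500))
            viruses[vid] = _insert(viruses[vid], t, vpos)
            hosts[hid] = _insert(hosts[hid], host_copy, hpos)
            vt_id = f"trna_v_{vid}"
            ht_id = f"trna_h_{hid}"
            viral_trnas[vt_id] = (vid, t)
            host_trnas[ht_id] = (hid, host_copy)
            trna_rows.append({"trna_id": vt_id, "entity_id": vid,
                              "start": vpos + 1, "end": vpos + TRNA_LEN, "strand": "+"})
            trna_rows.append({"trna_id": ht_id, "entity_id": hid,
                              "start": hpos + 1, "end": hpos + TRNA_LEN, "strand": "+"})
            truth_links.append({"virus": vid, "host": hid, "channel": "trna",
                                "identity": link.identity})
        elif link.channel == "prophage":
            vseq = viruses[vid]
            seg_len = int(round(link.fraction * len(vseq)))
            start = int(rng.integers(0, len(vseq) - seg_len + 1))
            segment = _mutate(rng, vseq[start : start + seg_len], link.identity)
            pos = int(rng.integers(500, len(hosts[hid]) - 500))
            hosts[hid] = _insert(hosts[hid], segment, pos)
            truth_links.append({"virus": vid, "host": hid, "channel": "prophage",
                                "identity": link.identity, "fraction": link.fraction,
                                "virus_start": start + 1})
    # decoy spacers: protospacer copies with extra mismatches, archived in a
    # host array but beyond the <=1-mismatch matcher's reach on the virus
    decoys = []
    for d in range(config.n_decoy_spacers):
        vid = virus_ids[int(rng.integers(len(virus_ids)))]
        hid = host_ids[(int(rng.integers(len(host_ids))))]
        vseq = viruses[vid]
        start = int(rng.integers(500, len(vseq) - 500 - config.spacer_len))
        decoy = _substitute_k(
            rng, vseq[start : start + config.spacer_len], config.decoy_mismatches
        )
        array, all_spacers = build_array(decoy)
        pos = int(rng.integers(500, len(hosts[hid]) - 500))
        hosts[hid] = _insert(hosts[hid], array, pos)
        decoy_ids = []
        for s in all_spacers:
            sp_id = f"spacer_{n_sp:03d}"
            spacers[sp_id] = s
            if s == decoy:
                decoy_ids.append(sp_id)
            n_sp += 1
        decoys.append({"virus": vid, "host": hid, "spacer_ids": decoy_ids,
                       "mismatches": config.decoy_mismatches})
    return spacers, viral_trnas, host_trnas, trna_rows, truth_links, decoys


def _build_genes(config: SimConfig, rng: np.random.Generator,
                 viruses: dict[str, str], amgs: Sequence[PlantedAMG]):
    """Tile gene annotations along each virus and plant AMG candidates."""
    virus_ids = sorted(viruses)
    amg_by_virus: dict[str, list[PlantedAMG]] = {}
    for a in amgs:
        amg_by_virus.setdefault(virus_ids[a.virus], []).append(a)
    contigs: list[Contig] = []
    amg_rows: list[dict] = []
    truth_amgs: list[dict] = []
    for vid in virus_ids:
        seq = viruses[vid]
        genes: list[GeneAnnotation] = []
        step = config.gene_len + config.gene_spacing
        n_genes = max(1, (len(seq) - config.gene_spacing) // step)
        planted = {a.gene_index: a for a in amg_by_virus.get(vid, [])}
        for g in range(n_genes):
            start = g * step + 1
            end = min(start + config.gene_len - 1, len(seq))
            gene_id = f"{vid}_g{g:03d}"
            a = planted.get(g)
            if a is not None:
                genes.append(GeneAnnotation(
                    gene_id, start, end, "+", "unknown", "metabolic candidate",
                    auxiliary_score=a.auxiliary_score,
                    amg_flags=frozenset(a.flags), caller="dramv",
                ))
                amg_rows.append({
                    "gene_id": gene_id, "votu_id": vid,
                    "auxiliary_score": a.auxiliary_score, "amg_flags": a.flags,
                    "callers": a.callers, "transposon": a.transposon,
                })
                truth_amgs.append({
                    "gene_id": gene_id, "votu_id": vid,
                    "expected_confidence": a.expected_confidence,
                    "expected_homology": a.homology,
                })
            else:
                category = "unknown" if g % 7 == 6 else "viral"
                genes.append(GeneAnnotation(
                    gene_id, start, end, "+", category,
                    "hypothetical" if category == "unknown" else "viral structural",
                ))
        contigs.append(Contig(
            id=vid, sequence=seq, sample_id=f"gwj{1 + int(rng.integers(config.n_samples)):02d}",
            caller_scores={"virsorter": 0.95, "vibrant": 1.0,
                           "deepvirfinder": 0.95, "deepvirfinder_p": 0.01},
            genes=genes,
        ))
    return contigs, amg_rows, truth_amgs


def _build_proteins(config: SimConfig, rng: np.random.Generator,
                    truth_amgs: list[dict], links: Sequence[PlantedLink],
                    n_hosts: int):
    """Host proteomes plus AMG proteins with planted homology classes."""
    host_ids = [f"host_{i:03d}" for i in range(n_hosts)]
    host_proteins = {
        h: {f"{h}_p{j:02d}": _rand_protein(rng, 200) for j in range(12)}
        for h in host_ids
    }
    virus_host = {f"vir_{l.virus:03d}": host_ids[l.host] for l in links}
    amg_proteins: dict[str, str] = {}
    for rec in truth_amgs:
        vid = rec["votu_id"]
        host = virus_host.get(vid)
        if rec["expected_homology"] == "identical" and host:
            src = sorted(host_proteins[host])[0]
            amg_proteins[rec["gene_id"]] = host_proteins[host][src]
        elif rec["expected_homology"] == "homologous" and host:
            src = sorted(host_proteins[host])[1]
            amg_proteins[rec["gene_id"]] = _mutate_protein(
                rng, host_proteins[host][src], 0.65
            )
        else:
            amg_proteins[rec["gene_id"]] = _rand_protein(rng, 200)
    return amg_proteins, host_proteins


def simulate_tables(config: SimConfig, rng: np.random.Generator,
                    entity_lengths: dict[str, int],
                    couplings: Sequence[Coupling],
                    gene_lengths: dict[str, int]):
    """Environment table, per-sample mapped read lengths, and per-gene
    transcript counts.

    Coupled entities follow coverage = intercept + slope * covariate +
    Gaussian noise truncated at zero; the rest get entity-specific baseline
    coverage with environment-independent noise. Planted singleton genes
    carry exactly one read in one sample.
    """
    samples = [f"gwj{i + 1:02d}" for i in range(config.n_samples)]
    env = pd.DataFrame(
        {p: rng.uniform(*_ENV_RANGES.get(p, (0.0, 1.0)), size=config.n_samples)
         for p in config.env_params},
        index=pd.Index(samples, name="sample_id"),
    )
    coupled = {c.entity: c for c in couplings}
    rows = []
    for entity, length in sorted(entity_lengths.items()):
        c = coupled.get(entity)
        if c is not None:
            z = env[c.covariate].to_numpy()
            z = (z - z.mean()) / (z.std() or 1.0)
            cov = c.intercept + c.slope * z + rng.normal(0.0, c.noise_sd, config.n_samples)
        else:
            base = rng.uniform(0.4, 2.5)
            cov = base + rng.normal(0.0, 0.3, config.n_samples)
        cov = np.clip(cov, 0.0, None)
        for s, value in zip(samples, cov):
            rows.append({"entity_id": entity, "sample_id": s,
                         "mapped_bp": int(round(value * length))})
    mapped = pd.DataFrame(rows)

    expr_samples = samples[: config.n_expression_samples]
    gene_ids = sorted(gene_lengths)
    lam = rng.gamma(2.0, 10.0, size=len(gene_ids))
    count_rows = []
    singleton_truth = []
    for gi, gene in enumerate(gene_ids):
        counts = rng.poisson(lam[gi], size=len(expr_samples))
        counts[counts == 1] = 2  # reserve singletons for explicit planting
        if gi % 37 == 5:  # planted singleton: must normalize to TPM 0
            counts[gi % len(expr_samples)] = 1
            singleton_truth.append({"gene_id": gene,
                                    "sample_id": expr_samples[gi % len(expr_samples)]})
        for s, n in zip(expr_samples, counts):
            count_rows.append({"gene_id": gene, "sample_id": s, "read_count": int(n)})
    read_counts = pd.DataFrame(count_rows)
    return env, mapped, read_counts, singleton_truth


def default_couplings(config: SimConfig, links: Sequence[PlantedLink]) -> list[Coupling]:
    """Couple the first n_coupled_pairs planted virus-host pairs to cycling
    covariates; both pair members share slope sign and covariate."""
    covs = ["DO", "iron", "nitrate"]
    out = []
    for i, link in enumerate(links[: config.n_coupled_pairs]):
        cov = covs[i % len(covs)]
        slope = 1.2 if i % 2 == 0 else -1.0
        out.append(Coupling(f"vir_{link.virus:03d}", cov, slope,
                            intercept=2.0, noise_sd=config.coupling_noise_sd))
        out.append(Coupling(f"host_{link.host:03d}", cov, slope * 0.8,
                            intercept=2.5, noise_sd=config.coupling_noise_sd))
    return out


def simulate_community(config: SimConfig) -> Community:
    """Run every generation stage under one seeded generator."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    links = config.links()
    hosts, taxonomy, chains, _base = generate_hosts(config, rng)
    viruses, sources, notes = generate_viruses(config, rng, chains, links)
    spacers, vtrnas, htrnas, trna_rows, truth_links, decoys = _plant_all_links(
        config, rng, hosts, viruses, links
    )
    contigs, amg_rows, truth_amgs = _build_genes(config, rng, viruses, config.amgs())
    amg_proteins, host_proteins = _build_proteins(
        config, rng, truth_amgs, links, config.n_hosts
    )
    couplings = config.coupling if config.coupling is not None else default_couplings(config, links)
    entity_lengths = {h: len(s) for h, s in hosts.items()}
    entity_lengths.update({v: len(s) for v, s in viruses.items()})
    gene_lengths = {g.gene_id: g.end - g.start + 1 for c in contigs for g in c.genes}
    env, mapped, read_counts, singletons = simulate_tables(
        config, rng, entity_lengths, couplings, gene_lengths
    )

    presence = {}
    for rec in mapped.itertuples():
        frac = rec.mapped_bp / entity_lengths[rec.entity_id]
        presence.setdefault(rec.entity_id, {})[rec.sample_id] = bool(frac > 0.10)

    truth = {
        "true_links": truth_links,
        "source_host": sources,
        "decoy_spacers": decoys,
        "planted_amg_labels": truth_amgs,
        "planted_singletons": singletons,
        "coupling": [asdict(c) for c in couplings],
        "true_presence": presence,
        "warnings": notes,
        "host_taxonomy": {h: list(t) for h, t in taxonomy.items()},
    }
    for note in notes:
        warnings.warn(note)
    return Community(
        config=config, hosts=hosts, host_taxonomy=taxonomy, viruses=viruses,
        virus_contigs=contigs, spacers=spacers, viral_trnas=vtrnas,
        host_trnas=htrnas,
        trna_coords=pd.DataFrame(
            trna_rows, columns=["trna_id", "entity_id", "start", "end", "strand"]
        ),
        amg_calls=pd.DataFrame(amg_rows), amg_proteins=amg_proteins,
        host_proteins=host_proteins,
        mapped_lengths=mapped, read_counts=read_counts, env=env, truth=truth,
    )


# ---------------------------------------------------------------------------
# Clustering fixture
# ---------------------------------------------------------------------------


def generate_clustering_set(
    seed: int,
    n_species: int = 10,
    n_variants: int = 3,
    n_singletons: int = 5,
    n_short: int = 2,
    length_range: tuple[int, int] = (10_500, 16_000),
    variant_identity: float = 0.98,
) -> tuple[list[Contig], dict]:
    """Planted-species set for exercising vOTU clustering.

    Each species is one representative-length sequence plus near-identical
    full-overlap variants (substitutions at 1 - variant_identity, light end
    truncation); singletons are unrelated sequences; `n_short` extra
    contigs are below 10 kb so their clusters fail representative-length
    retention. Truth maps contig id -> planted species.
    """
    rng = np.random.default_rng(seed)
    contigs: list[Contig] = []
    species_of: dict[str, str] = {}
    for s in range(n_species):
        length = int(rng.integers(*length_range))
        rep = "".join(rng.choice(list(_BASES), size=length))
        sid = f"sp{s:02d}"
        contigs.append(Contig(f"{sid}_v0", rep))
        species_of[f"{sid}_v0"] = sid
        for v in range(1, n_variants):
            trim = int(rng.integers(0, int(0.04 * length)))
            var = _mutate(rng, rep[: length - trim], variant_identity)
            contigs.append(Contig(f"{sid}_v{v}", var))
            species_of[f"{sid}_v{v}"] = sid
    for j in range(n_singletons):
        length = int(rng.integers(*length_range))
        cid = f"single{j:02d}"
        contigs.append(Contig(cid, "".join(rng.choice(list(_BASES), size=length))))
        species_of[cid] = cid
    short_ids = []
    for j in range(n_short):
        length = int(rng.integers(6_000, 9_500))
        cid = f"short{j:02d}"
        contigs.append(Contig(cid, "".join(rng.choice(list(_BASES), size=length))))
        short_ids.append(cid)
    truth = {"species_of": species_of, "short_ids": short_ids,
             "n_retained_expected": n_species + n_singletons}
    return contigs, truth


# ---------------------------------------------------------------------------
# File output
# ---------------------------------------------------------------------------


def write_community(community: Community, outdir: str | Path) -> Path:
    """Write the community as the pipeline's plain-text input files."""
    from . import io as vio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    vio.write_fasta(outdir / "hosts.fasta", community.hosts)
    vio.write_fasta(outdir / "viruses.fasta", community.viruses)
    vio.write_fasta(outdir / "spacers.fasta", community.spacers)
    trna_seqs = {tid: seq for tid, (_, seq) in community.viral_trnas.items()}
    trna_seqs.update({tid: seq for tid, (_, seq) in community.host_trnas.items()})
    vio.write_fasta(outdir / "trnas.fasta", trna_seqs)
    community.trna_coords.to_csv(outdir / "trnas.tsv", sep="\t", index=False)
    vio.write_gene_annotations(outdir / "gene_annotations.tsv", community.virus_contigs)
    community.amg_calls.to_csv(outdir / "amg_calls.tsv", sep="\t", index=False)
    community.mapped_lengths.to_csv(outdir / "mapped_lengths.tsv", sep="\t", index=False)
    community.read_counts.to_csv(outdir / "read_counts.tsv", sep="\t", index=False)
    community.env.to_csv(outdir / "environment.tsv", sep="\t")
    vio.write_fasta(outdir / "amg_proteins.fasta", community.amg_proteins)
    host_prot = {pid: seq for prots in community.host_proteins.values()
                 for pid, seq in prots.items()}
    vio.write_fasta(outdir / "host_proteins.fasta", host_prot)
    with open(outdir / "truth.json", "w") as fh:
        json.dump(community.truth, fh, indent=1, sort_keys=True)
    return outdir
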