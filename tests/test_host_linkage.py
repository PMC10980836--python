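"""Evidence collection and consensus host-assignment tests."""

import random

import numpy as np
import pytest

from virolink import host_linkage as hl
from virolink.host_linkage import LinkEvidence, UNRESOLVED
from conftest import random_seq


# ---------------------------------------------------------------------------
# Channel gates on constructed micro-cases
# ---------------------------------------------------------------------------


class TestCrisprChannel:
    def test_shared_spacer_links_and_multi_bin_spacer_emits_both(self):
        rng = np.random.default_rng(0)
        spacer = random_seq(rng, 32)
        virus = random_seq(rng, 500) + spacer + random_seq(rng, 500)
        hostA = random_seq(rng, 400) + spacer + random_seq(rng, 400)
        hostB = random_seq(rng, 400) + spacer + random_seq(rng, 400)
        ev = hl.collect_crispr(
            {"sp1": spacer},
            {"v1": virus},
            {"binA": {"a1": hostA}, "binB": {"b1": hostB}},
        )
        assert {(e.votu_id, e.host_id) for e in ev} == {("v1", "binA"), ("v1", "binB")}

    def test_one_mismatch_each_side_still_links(self):
        rng = np.random.default_rng(1)
        spacer = random_seq(rng, 32)
        mutate = lambda s, p: s[:p] + ("A" if s[p] != "A" else "C") + s[p + 1 :]
        virus = random_seq(rng, 300) + mutate(spacer, 5) + random_seq(rng, 300)
        host = random_seq(rng, 300) + mutate(spacer, 20) + random_seq(rng, 300)
        ev = hl.collect_crispr({"sp": spacer}, {"v": virus}, {"h": {"c": host}})
        assert len(ev) == 1 and ev[0].score == 1.0


class TestTrnaChannel:
    def make(self, rng, identity=1.0, query_frac=1.0):
        t = random_seq(rng, 75)
        host_t = list(t[: int(75 * query_frac)])
        n_sub = int(round((1 - identity) * len(host_t)))
        for p in rng.choice(len(host_t), size=n_sub, replace=False):
            host_t[p] = "ACGT"[("ACGT".index(host_t[p]) + 2) % 4]
        return t, "".join(host_t)

    def test_identical_trna_links(self):
        rng = np.random.default_rng(2)
        t, ht = self.make(rng)
        ev = hl.collect_trna({"vt": ("v1", t)}, {"ht": ("h1", ht)})
        assert [(e.votu_id, e.host_id) for e in ev] == [("v1", "h1")]
        assert ev[0].score == pytest.approx(1.0)

    def test_85_percent_identity_fails_gate(self):
        rng = np.random.default_rng(3)
        t, ht = self.make(rng, identity=0.85)
        assert hl.collect_trna({"vt": ("v1", t)}, {"ht": ("h1", ht)}) == []

    def test_high_identity_over_short_span_fails_coverage(self):
        rng = np.random.default_rng(4)
        t, ht = self.make(rng, identity=0.97, query_frac=0.6)
        assert hl.collect_trna({"vt": ("v1", t)}, {"ht": ("h1", ht)}) == []


class TestNucleotideChannel:
    def planted(self, rng, vlen=12000, identity=0.8, fraction=0.8):
        virus = random_seq(rng, vlen)
        seg = list(virus[: int(fraction * vlen)])
        n_sub = int(round((1 - identity) * len(seg)))
        for p in rng.choice(len(seg), size=n_sub, replace=False):
            seg[p] = "ACGT"[("ACGT".index(seg[p]) + 1 + int(rng.integers(3))) % 4]
        host = random_seq(rng, 3000) + "".join(seg) + random_seq(rng, 3000)
        return virus, host

    def test_planted_prophage_links(self):
        rng = np.random.default_rng(5)
        virus, host = self.planted(rng, identity=0.75, fraction=0.8)
        ev = hl.collect_nucleotide({"v": virus}, {"h": {"c": host}})
        assert [(e.votu_id, e.host_id) for e in ev] == [("v", "h")]
        assert ev[0].score >= 50.0  # bit-score gate holds for the planted signal

    def test_low_coverage_fails_gate(self):
        rng = np.random.default_rng(6)
        virus, host = self.planted(rng, identity=0.9, fraction=0.4)
        assert hl.collect_nucleotide({"v": virus}, {"h": {"c": host}}) == []

    def test_short_query_channel_not_applicable(self):
        rng = np.random.default_rng(7)
        virus, host = self.planted(rng, vlen=8000, identity=0.95, fraction=0.9)
        assert hl.collect_nucleotide({"v": virus}, {"h": {"c": host}}) == []


class TestONFChannel:
    def test_gate_is_inclusive_at_the_threshold(self):
        from virolink import seqmatch

        rng = np.random.default_rng(8)
        a, b = random_seq(rng, 3000), random_seq(rng, 3000)
        d = seqmatch.d2star_sequences(a, b)
        at = hl.collect_onf({"v": a}, {"h": b}, max_d2star=d)
        below = hl.collect_onf({"v": a}, {"h": b}, max_d2star=d - 1e-9)
        assert len(at) == 1 and at[0].score == pytest.approx(d)
        assert below == []


# ---------------------------------------------------------------------------
# Channel recovery on the default community
# ---------------------------------------------------------------------------


class TestCommunityRecovery:
    def test_crispr_channel_perfect_precision_and_recall(self, evidence, truth_links):
        found = {(e.votu_id, e.host_id) for e in evidence["crispr"]}
        assert found == truth_links["crispr"]

    def test_trna_channel_perfect_precision_and_recall(self, evidence, truth_links):
        found = {(e.votu_id, e.host_id) for e in evidence["trna"]}
        assert found == truth_links["trna"]

    def test_nucleotide_channel_perfect_precision_and_recall(self, evidence, truth_links):
        found = {(e.votu_id, e.host_id) for e in evidence["nucleotide"]}
        assert found == truth_links["prophage"]

    def test_decoy_spacers_never_link_their_virus(self, community, evidence):
        crispr_pairs = {(e.votu_id, e.host_id) for e in evidence["crispr"]}
        for decoy in community.truth["decoy_spacers"]:
            assert (decoy["virus"], decoy["host"]) not in crispr_pairs

    def test_onf_favours_source_host(self, community, evidence):
        """Host-derived viruses sit compositionally closer to their source
        host than to at least 80% of the other hosts."""
        from virolink import seqmatch

        src = {v: s for v, s in community.truth["source_host"].items() if s}
        profiles = {
            h: seqmatch.onf_profile(s) for h, s in community.hosts.items()
        }
        ok = 0
        for v, true_host in src.items():
            vp = seqmatch.onf_profile(community.viruses[v])
            ds = {h: seqmatch.d2star(vp, hp) for h, hp in profiles.items()}
            rank = sum(1 for h, d in ds.items() if d < ds[true_host])
            if rank <= 0.2 * (len(ds) - 1):
                ok += 1
        assert ok / len(src) >= 0.8


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------


class TestConsensus:
    def test_most_methods_wins(self):
        ev = [
            LinkEvidence("v", "hostA", "crispr", 0),
            LinkEvidence("v", "hostA", "onf", 0.15),
            LinkEvidence("v", "hostB", "onf", 0.05),
        ]
        (a,) = hl.assign_most_probable_host(ev)
        assert a.host_id == "hostA"
        assert a.supporting_methods == {"crispr", "onf"}

    def test_onf_only_tie_broken_by_lowest_score(self):
        ev = [
            LinkEvidence("v", "hostA", "onf", 0.15),
            LinkEvidence("v", "hostB", "onf", 0.10),
        ]
        (a,) = hl.assign_most_probable_host(ev)
        assert a.host_id == "hostB"

    def test_multi_host_trna_tie_is_unresolved(self):
        ev = [
            LinkEvidence("v", "hostA", "trna", 1.0),
            LinkEvidence("v", "hostB", "trna", 1.0),
        ]
        (a,) = hl.assign_most_probable_host(ev)
        assert a.host_id == UNRESOLVED

    def test_trna_vs_nucleotide_tie_broken_by_bit_score(self):
        ev = [
            LinkEvidence("v", "hostA", "trna", 1.0),
            LinkEvidence("v", "hostB", "nucleotide", 800.0),
        ]
        (a,) = hl.assign_most_probable_host(ev)
        assert a.host_id == "hostB"
        assert any("bit score" in t for t in a.rule_trace)

    def test_crispr_outranks_equal_count_combinations(self):
        ev = [
            LinkEvidence("v", "hostA", "crispr", 0),
            LinkEvidence("v", "hostA", "onf", 0.19),
            LinkEvidence("v", "hostB", "trna", 1.0),
            LinkEvidence("v", "hostB", "onf", 0.02),
        ]
        (a,) = hl.assign_most_probable_host(ev)
        assert a.host_id == "hostA"

    def test_consensus_invariant_under_evidence_permutation(self, evidence):
        pooled = sum(evidence.values(), [])
        baseline = {
            a.votu_id: a.host_id for a in hl.assign_most_probable_host(pooled)
        }
        shuffled = pooled[:]
        random.Random(42).shuffle(shuffled)
        assert {
            a.votu_id: a.host_id for a in hl.assign_most_probable_host(shuffled)
        } == baseline

    def test_community_consensus_recovers_all_planted_hosts(self, community, evidence):
        pooled = sum(evidence.values(), [])
        amap = {a.votu_id: a.host_id for a in hl.assign_most_probable_host(pooled)}
        for rec in community.truth["true_links"]:
            assert amap[rec["virus"]] == rec["host"]

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            hl.assign_most_probable_host([LinkEvidence("v", "h", "psychic", 1.0)])


class TestHostRange:
    TAX = {
        "h1": ("Bacteria", "Pseudomonadota"),
        "h2": ("Bacteria", "Pseudomonadota"),
        "h3": ("Bacteria", "Patescibacteria"),
        "h4": ("Archaea", "Nanoarchaeota"),
    }

    def r(self, votu, host):
        return LinkEvidence(votu, host, "onf", 0.1)

    def test_classes(self):
        ev = [
            self.r("v1", "h1"),
            self.r("v2", "h1"), self.r("v2", "h2"),
            self.r("v3", "h1"), self.r("v3", "h3"),
            self.r("v4", "h1"), self.r("v4", "h4"),
        ]
        out = hl.summarize_host_range(ev, self.TAX)
        assert out == {
            "v1": "single-MAG specialist",
            "v2": "single-phylum",
            "v3": "multi-phylum same-domain",
            "v4": "cross-domain",
        }

    def test_missing_taxonomy_warns_unknown(self):
        with pytest.warns(UserWarning):
            out = hl.summarize_host_range(
                [self.r("v", "h1"), self.r("v", "mystery")], self.TAX
            )
        assert out["v"] == "UNKNOWN"
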