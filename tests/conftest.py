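"""Shared fixtures: one default synthetic community, simulated once."""

import numpy as np
import pytest

from virolink import host_linkage, synthetic

COMMUNITY_SEED = 1


@pytest.fixture(scope="session")
def community():
    """Default synthetic community (20 hosts, 30 viruses, 16 samples)."""
    cfg = synthetic.SimConfig(seed=COMMUNITY_SEED)
    return synthetic.simulate_community(cfg)


@pytest.fixture(scope="session")
def evidence(community):
    """All four evidence channels collected on the default community."""
    com = community
    return {
        "crispr": host_linkage.collect_crispr(
            com.spacers, com.viruses, com.host_contigs_by_bin
        ),
        "trna": host_linkage.collect_trna(com.viral_trnas, com.host_trnas),
        "nucleotide": host_linkage.collect_nucleotide(
            com.viruses, com.host_contigs_by_bin
        ),
        "onf": host_linkage.collect_onf(com.viruses, dict(com.hosts)),
    }


@pytest.fixture(scope="session")
def truth_links(community):
    by_channel = {"crispr": set(), "prophage": set(), "trna": set()}
    for rec in community.truth["true_links"]:
        by_channel[rec["channel"]].add((rec["virus"], rec["host"]))
    return by_channel


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))
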