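"""Shared fixtures: small hand-built alignments and simulated datasets."""

from __future__ import annotations

import numpy as np
import pytest

from specdelim.seqio import Alignment, GroupingScheme


def make_alignment(pairs, locus="locus"):
    """Alignment from a list of (id, sequence) pairs."""
    ids, seqs = zip(*pairs)
    return Alignment(locus, tuple(ids), tuple(seqs))


@pytest.fixture
def tiny_alignment():
    return make_alignment(
        [
            ("s1", "ACGTACGT"),
            ("s2", "ACGTACGA"),
            ("s3", "ACGTACGT"),
            ("s4", "TCGTACGA"),
        ]
    )


@pytest.fixture
def two_group_scheme():
    """Two groups x two populations x two specimens, fixed differences
    between groups, identical within."""
    aln = make_alignment(
        [
            ("a1", "AAAAAAAAAA"),
            ("a2", "AAAAAAAAAA"),
            ("b1", "AAAAAAAAAA"),
            ("b2", "AAAAAAAAAA"),
            ("c1", "GGGGGAAAAA"),
            ("c2", "GGGGGAAAAA"),
            ("d1", "GGGGGAAAAA"),
            ("d2", "GGGGGAAAAA"),
        ]
    )
    scheme = GroupingScheme(
        "fixed",
        {
            "a1": ("X", "pa"),
            "a2": ("X", "pa"),
            "b1": ("X", "pb"),
            "b2": ("X", "pb"),
            "c1": ("Y", "pc"),
            "c2": ("Y", "pc"),
            "d1": ("Y", "pd"),
            "d2": ("Y", "pd"),
        },
    )
    return aln, scheme


def random_alignment(rng, n=5, L=200, locus="rand"):
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, L)]) for _ in range(n)]
    return make_alignment([(f"s{i}", s) for i, s in enumerate(seqs)], locus)


def random_structured_instance(rng, n_groups=3, pops_per_group=2, L=60):
    """Random nested instance: unequal sample sizes, random sequences."""
    bases = np.array(list("ACGT"))
    mapping = {}
    pairs = []
    for gi in range(n_groups):
        for pi in range(pops_per_group):
            n = int(rng.integers(2, 6))
            for ii in range(n):
                sid = f"g{gi}p{pi}i{ii}"
                mapping[sid] = (f"G{gi}", f"g{gi}p{pi}")
                pairs.append((sid, "".join(bases[rng.integers(0, 4, L)])))
    return make_alignment(pairs), GroupingScheme("rand", mapping)
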