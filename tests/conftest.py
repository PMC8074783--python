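"""Shared fixtures and tiny generators used across the suite."""

from __future__ import annotations

import dendropy
import numpy as np
import pytest

from haplomorph.io import HaplotypeAlignment, HaplotypeRecord, SupportTree


def make_alignment(seqs: dict[str, str]) -> HaplotypeAlignment:
    """Alignment from {haplotype_id: sequence}; individual ids follow the
    trailing-lowercase-letter convention."""
    from haplomorph.io import split_haplotype_id

    return HaplotypeAlignment(
        [
            HaplotypeRecord(hid, split_haplotype_id(hid)[0], seq)
            for hid, seq in seqs.items()
        ]
    )


def yule_tree(n: int, rng: np.random.Generator) -> SupportTree:
    """Ultrametric pure-Yule tree with ``n`` tips (random joins at Yule
    heights); the null world for the GMYC calibration."""
    taxa = dendropy.TaxonNamespace()
    nodes = []
    for i in range(n):
        nd = dendropy.Node(taxon=taxa.new_taxon(label=f"t{i}"))
        nd.height = 0.0
        nodes.append(nd)
    t = 0.0
    splits = []
    for k in range(1, n):
        t += rng.exponential(1.0 / k)
        splits.append(t)
    present = t + rng.exponential(1.0 / n)
    for h in sorted(present - s for s in splits):
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = dendropy.Node()
        parent.height = h
        a, b = nodes[i], nodes[j]
        parent.add_child(a)
        parent.add_child(b)
        a.edge.length = h - a.height
        b.edge.length = h - b.height
        nodes = [x for k2, x in enumerate(nodes) if k2 not in (i, j)]
        nodes.append(parent)
    nodes[0].edge.length = 0.0
    return SupportTree(tree=dendropy.Tree(taxon_namespace=taxa, seed_node=nodes[0]))


def random_dna(n: int, length: int, rng: np.random.Generator) -> list[str]:
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
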