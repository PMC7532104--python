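"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's sparse-matrix code paths:
path counting is done by exhaustive loop enumeration over adjacency
dictionaries, AUC by comparing every positive–negative score pair, and
average-linkage clustering by a naive agglomerator that recomputes
inter-cluster means at every step.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from repcool.composition import compose_all
from repcool.features import encode_pairs
from repcool.networks import NetworkRole, TypedNetwork
from repcool.synthetic import SyntheticConfig, generate


# ------------------------------------------------------------- oracles


def brute_force_path_counts(drgn, dign, middle=None):
    """Count drug→gene[→gene]→disease paths by exhaustive enumeration."""
    drug_genes: dict[str, set[str]] = {}
    for d, g in drgn.edges:
        drug_genes.setdefault(d, set()).add(g)
    gene_diseases: dict[str, set[str]] = {}
    for s, g in dign.edges:
        gene_diseases.setdefault(g, set()).add(s)
    neighbors: dict[str, set[str]] = {}
    if middle is not None:
        for a, b in middle.edges:
            neighbors.setdefault(a, set()).add(b)
            neighbors.setdefault(b, set()).add(a)

    counts: dict[tuple[str, str], int] = {}
    for d, genes in drug_genes.items():
        for g1 in genes:
            if middle is None:
                for s in gene_diseases.get(g1, ()):
                    counts[(d, s)] = counts.get((d, s), 0) + 1
            else:
                for g2 in neighbors.get(g1, ()):
                    for s in gene_diseases.get(g2, ()):
                        counts[(d, s)] = counts.get((d, s), 0) + 1
    return counts


def brute_force_auc(scores, labels) -> float:
    """P(positive outscores negative), ties counted half."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


def brute_force_average_linkage(D: np.ndarray):
    """Naive agglomeration returning sorted merge heights.

    At every step merges the closest cluster pair under average linkage,
    recomputing all inter-cluster mean distances from the original
    matrix.
    """
    clusters: list[list[int]] = [[i] for i in range(D.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            dist = float(
                np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            )
            if best is None or dist < best[0]:
                best = (dist, a, b)
        dist, a, b = best
        heights.append(dist)
        merged = clusters[a] + clusters[b]
        clusters = [
            c for k, c in enumerate(clusters) if k not in (a, b)
        ] + [merged]
    return sorted(heights)


def random_primaries(rng, n_drugs, n_genes, n_diseases, density):
    """One random six-network instance (ER backgrounds, shared genes)."""
    drugs = [f"d{i}" for i in range(n_drugs)]
    genes = [f"g{i}" for i in range(n_genes)]
    diseases = [f"s{i}" for i in range(n_diseases)]

    def bip(role, name, left, right):
        edges = {
            (l, r)
            for l in left
            for r in right
            if rng.random() < density
        }
        return TypedNetwork.from_edges(role, name, edges)

    def gg(role, name):
        edges = {
            (genes[i], genes[j])
            for i in range(n_genes)
            for j in range(i + 1, n_genes)
            if rng.random() < density
        }
        return TypedNetwork.from_edges(role, name, edges)

    drgn = bip(NetworkRole.DRGN, "drgn", drugs, genes)
    digns = [
        bip(NetworkRole.DIGN, f"dign{k}", diseases, genes) for k in range(3)
    ]
    ppin = gg(NetworkRole.PPIN, "ppin")
    gcn = gg(NetworkRole.GCN, "gcn")
    return drgn, digns, ppin, gcn


# ------------------------------------------------------------ fixtures


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic study conditions (seed 42)."""
    return generate(SyntheticConfig())


@pytest.fixture(scope="session")
def default_composed(default_bundle):
    return compose_all(default_bundle.recipes())


@pytest.fixture(scope="session")
def default_matrix(default_bundle, default_composed):
    return encode_pairs(default_bundle.truth, default_composed)


@pytest.fixture
def tiny_drgn():
    return TypedNetwork.from_edges(
        NetworkRole.DRGN, "drgn", [("d1", "g1"), ("d1", "g2"), ("d2", "g3")]
    )


@pytest.fixture
def tiny_dign():
    return TypedNetwork.from_edges(
        NetworkRole.DIGN, "dign", [("s1", "g2"), ("s1", "g3"), ("s2", "g1")]
    )
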