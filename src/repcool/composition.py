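"""Compose primary networks into weighted drug–disease networks.

A composition recipe chains a drug–gene network with a disease–gene
network, optionally bridged by one gene–gene network (PPI or
co-expression):

    drug → gene → disease                 (length-2 chain)
    drug → gene → gene → disease          (length-3 chain)

The weight of a composed drug–disease edge is the number of distinct
connecting paths. For a length-2 chain that is the number of shared genes;
for a length-3 chain it is the number of ordered gene pairs (g1, g2) with
g1 ≠ g2 such that the drug hits g1, the middle network links g1 and g2
(in either direction), and the disease is associated with g2. A self-hop
g1 = g2 is excluded: it would merely duplicate the direct composition,
and the direct and bridged networks are meant as distinct evidence
channels.

With three disease–gene networks and two gene–gene bridges, the default
is nine composed networks: three direct, three PPI-bridged, three
co-expression-bridged.

Weights are computed as products of binary sparse adjacency matrices
(the middle matrix symmetrized with a zeroed diagonal), which is exactly
path counting.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.sparse as sp

from .networks import (
    NetworkFormatError,
    NetworkRole,
    TypedNetwork,
    ValidationError,
    _iter_records,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CompositionRecipe:
    """An ordered chain of primary networks composing to drug→disease.

    The first network must be a DRGN, the last a DIGN, and an optional
    single middle network must be a PPIN or GCN.
    """

    recipe_id: str
    chain: tuple[TypedNetwork, ...]

    def __post_init__(self) -> None:
        if len(self.chain) not in (2, 3):
            raise ValidationError(
                f"recipe {self.recipe_id!r}: chain length must be 2 or 3, "
                f"got {len(self.chain)}"
            )
        first, last = self.chain[0], self.chain[-1]
        if first.role != NetworkRole.DRGN:
            raise ValidationError(
                f"recipe {self.recipe_id!r}: chain must start with a DRGN, "
                f"got {first.role.value}"
            )
        if last.role != NetworkRole.DIGN:
            raise ValidationError(
                f"recipe {self.recipe_id!r}: chain must end with a DIGN, "
                f"got {last.role.value}"
            )
        if len(self.chain) == 3 and self.chain[1].role not in (
            NetworkRole.PPIN,
            NetworkRole.GCN,
        ):
            raise ValidationError(
                f"recipe {self.recipe_id!r}: middle network must be PPIN "
                f"or GCN, got {self.chain[1].role.value}"
            )

    @property
    def length(self) -> int:
        return len(self.chain)

    def describe(self) -> str:
        return " o ".join(n.name for n in self.chain)


@dataclass(frozen=True)
class ComposedNetwork:
    """Weighted drug–disease edges; weight = number of distinct paths.

    Zero-weight pairs are absent: the edge map stores only pairs with at
    least one connecting path.
    """

    recipe_id: str
    weights: dict[tuple[str, str], int]

    @property
    def drugs(self) -> frozenset[str]:
        return frozenset(d for d, _ in self.weights)

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(s for _, s in self.weights)

    def weight(self, drug: str, disease: str) -> int:
        return self.weights.get((drug, disease), 0)

    def __len__(self) -> int:
        return len(self.weights)


def default_recipes(
    drgn: TypedNetwork,
    digns: Sequence[TypedNetwork],
    ppin: TypedNetwork,
    gcn: TypedNetwork,
) -> list[CompositionRecipe]:
    """Build the nine standard recipes from the six primary networks.

    Fixed order: Net1–Net3 are the direct compositions DRGN∘DIGN_i (one
    per disease–gene network), Net4–Net6 bridge through the PPI network,
    Net7–Net9 through the co-expression network.
    """
    if drgn.role != NetworkRole.DRGN:
        raise ValidationError(f"expected a DRGN, got {drgn.role.value}")
    if len(digns) != 3 or any(n.role != NetworkRole.DIGN for n in digns):
        raise ValidationError(
            f"expected exactly 3 DIGNs, got "
            f"{[n.role.value for n in digns]}"
        )
    if ppin.role != NetworkRole.PPIN:
        raise ValidationError(f"expected a PPIN, got {ppin.role.value}")
    if gcn.role != NetworkRole.GCN:
        raise ValidationError(f"expected a GCN, got {gcn.role.value}")

    recipes: list[CompositionRecipe] = []
    for i, dign in enumerate(digns, start=1):
        recipes.append(CompositionRecipe(f"Net{i}", (drgn, dign)))
    for i, dign in enumerate(digns, start=4):
        recipes.append(CompositionRecipe(f"Net{i}", (drgn, ppin, dign)))
    for i, dign in enumerate(digns, start=7):
        recipes.append(CompositionRecipe(f"Net{i}", (drgn, gcn, dign)))
    return recipes


def _index(nodes: Iterable[str]) -> dict[str, int]:
    return {n: i for i, n in enumerate(sorted(set(nodes)))}


def compose(recipe: CompositionRecipe) -> ComposedNetwork:
    """Compose one recipe into a weighted drug–disease network.

    Weights are entries of A_dg · [A_gg] · A_gd over binary adjacency
    matrices, the gene–gene matrix symmetrized with its diagonal forced
    to zero — i.e. exact counts of distinct drug→gene[→gene]→disease
    paths with distinct middle genes.
    """
    drgn = recipe.chain[0]
    dign = recipe.chain[-1]
    middle = recipe.chain[1] if recipe.length == 3 else None

    gene_ids: set[str] = set(drgn.right_nodes) | set(dign.right_nodes)
    if middle is not None:
        gene_ids |= set(middle.left_nodes) | set(middle.right_nodes)
    drugs = _index(drgn.left_nodes)
    genes = _index(gene_ids)
    diseases = _index(dign.left_nodes)
    if not drugs or not diseases or not genes:
        return ComposedNetwork(recipe.recipe_id, {})

    def bipartite(net: TypedNetwork, rows: dict, cols: dict) -> sp.csr_matrix:
        r = [rows[a] for a, _ in net.edges]
        c = [cols[b] for _, b in net.edges]
        return sp.csr_matrix(
            (np.ones(len(r), dtype=np.int64), (r, c)),
            shape=(len(rows), len(cols)),
        )

    A = bipartite(drgn, drugs, genes)                 # drugs × genes
    B = bipartite(dign, diseases, genes).T.tocsr()    # genes × diseases

    if middle is None:
        W = A @ B
    else:
        r = [genes[a] for a, _ in middle.edges]
        c = [genes[b] for _, b in middle.edges]
        ones = np.ones(len(r), dtype=np.int64)
        M = sp.csr_matrix(
            (ones, (r, c)), shape=(len(genes), len(genes))
        )
        M = M + M.T  # canonical storage has each undirected edge once
        M.setdiag(0)
        M.eliminate_zeros()
        W = A @ M @ B

    W = sp.coo_matrix(W)
    drug_names = sorted(drugs)
    disease_names = sorted(diseases)
    weights = {
        (drug_names[i], disease_names[j]): int(v)
        for i, j, v in zip(W.row, W.col, W.data)
        if v > 0
    }
    return ComposedNetwork(recipe.recipe_id, weights)


def compose_all(recipes: Sequence[CompositionRecipe]) -> list[ComposedNetwork]:
    """Compose every recipe, logging a per-network summary."""
    if not recipes:
        raise ValidationError("no recipes supplied")
    out = []
    for recipe in recipes:
        net = compose(recipe)
        logger.info(
            "%s (%s): %d drugs, %d diseases, %d drug-disease associations",
            recipe.recipe_id, recipe.describe(),
            len(net.drugs), len(net.diseases), len(net),
        )
        out.append(net)
    return out


def load_composed(path: str | Path, recipe_id: str | None = None,
                  header: bool = True) -> ComposedNetwork:
    """Read a composed network written by ``networks.write_network``."""
    path = Path(path)
    weights: dict[tuple[str, str], int] = {}
    for lineno, fields in _iter_records(path, header):
        if len(fields) < 3 or not fields[0] or not fields[1]:
            raise NetworkFormatError(
                f"{path}: line {lineno}: expected "
                f"drug<TAB>disease<TAB>weight"
            )
        try:
            w = int(fields[2])
        except ValueError as exc:
            raise NetworkFormatError(
                f"{path}: line {lineno}: non-integer weight {fields[2]!r}"
            ) from exc
        if w < 1:
            raise ValidationError(
                f"{path}: line {lineno}: weight must be >= 1, got {w}"
            )
        weights[(fields[0], fields[1])] = w
    return ComposedNetwork(
        recipe_id if recipe_id is not None else path.stem, weights
    )
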