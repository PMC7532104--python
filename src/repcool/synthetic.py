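"""Synthetic six-network bundles with planted drug–disease associations.

The generator emulates the statistical structure the repositioning method
relies on: truly associated drug–disease pairs accumulate more connecting
gene paths than random pairs. Each of the six primary networks gets an
independent Erdős–Rényi background at a configurable density; on top of
that, every planted pair is wired to a set of signal genes — directly
(drug–g in DRGN plus disease–g in each disease–gene network with
probability 0.8, so the three DIGN channels are correlated but not
identical, mimicking overlapping curation) or through a bridge
(drug–g1, g1–g2 in PPIN or GCN, g2–disease) for a configurable fraction
of the signal.

Generation is fully seed-reproducible, and every planted pair is
guaranteed at least one connecting path in at least one composed network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .composition import default_recipes
from .networks import (
    Label,
    LabeledPairSet,
    NetworkRole,
    TypedNetwork,
    ValidationError,
    write_labeled_pairs,
    write_network,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic bundle.

    ``background_density`` applies per network role (one Bernoulli rate
    per potential edge); ``shared_genes_per_planted`` is the effect size:
    how many signal genes tie each planted pair together;
    ``bridge_fraction`` routes that portion of the signal through a
    gene–gene hop (PPIN or GCN, coin flip) instead of a directly shared
    gene; ``dign_signal_prob`` is the chance each disease–gene network
    independently records a signal gene's disease link.
    """

    n_drugs: int = 50
    n_diseases: int = 30
    n_genes: int = 200
    background_density: dict[str, float] = field(
        default_factory=lambda: {
            "DRGN": 0.01, "DIGN": 0.01, "PPIN": 0.01, "GCN": 0.01,
        }
    )
    n_planted: int = 40
    shared_genes_per_planted: int = 4
    bridge_fraction: float = 0.3
    dign_signal_prob: float = 0.8
    seed: int = 42

    def validate(self) -> None:
        if min(self.n_drugs, self.n_diseases, self.n_genes) < 1:
            raise ValidationError("node counts must be positive")
        if not 0 <= self.n_planted <= self.n_drugs * self.n_diseases:
            raise ValidationError(
                f"n_planted={self.n_planted} exceeds the "
                f"{self.n_drugs}x{self.n_diseases} pair grid"
            )
        if self.n_planted > 0 and not (
            1 <= self.shared_genes_per_planted <= self.n_genes
        ):
            raise ValidationError(
                "shared_genes_per_planted must be in [1, n_genes]"
            )
        if not 0 <= self.bridge_fraction <= 1:
            raise ValidationError("bridge_fraction must be in [0, 1]")
        if not 0 <= self.dign_signal_prob <= 1:
            raise ValidationError("dign_signal_prob must be in [0, 1]")
        for role, p in self.background_density.items():
            if not 0 <= p <= 1:
                raise ValidationError(
                    f"background density for {role} must be in [0, 1]"
                )


@dataclass(frozen=True)
class SyntheticBundle:
    drgn: TypedNetwork
    digns: tuple[TypedNetwork, TypedNetwork, TypedNetwork]
    ppin: TypedNetwork
    gcn: TypedNetwork
    truth: LabeledPairSet
    config: SyntheticConfig

    @property
    def networks(self) -> tuple[TypedNetwork, ...]:
        return (self.drgn, *self.digns, self.ppin, self.gcn)

    def recipes(self):
        return default_recipes(
            self.drgn, list(self.digns), self.ppin, self.gcn
        )

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for net in self.networks:
            write_network(net, out_dir / f"{net.name}.tsv")
        write_labeled_pairs(self.truth, out_dir / "truth_pairs.tsv")


def _bipartite_background(
    rng: np.random.Generator,
    left: list[str],
    right: list[str],
    density: float,
) -> set[tuple[str, str]]:
    mask = rng.random((len(left), len(right))) < density
    rows, cols = np.nonzero(mask)
    return {(left[i], right[j]) for i, j in zip(rows, cols)}


def _genepair_background(
    rng: np.random.Generator, genes: list[str], density: float
) -> set[tuple[str, str]]:
    n = len(genes)
    iu, ju = np.triu_indices(n, k=1)
    mask = rng.random(len(iu)) < density
    return {
        (genes[i], genes[j]) for i, j in zip(iu[mask], ju[mask])
    }


def generate(config: SyntheticConfig | None = None) -> SyntheticBundle:
    """Draw one synthetic bundle under the configured conditions.

    The planted pairs are the positive truth set; an equal number of
    never-planted pairs is sampled as the negative truth set. If the
    probabilistic signal injection leaves a planted pair without any
    connecting path (possible when every DIGN coin flip fails), one
    direct disease–gene edge is added to a randomly chosen DIGN so the
    guarantee of at least one path holds.
    """
    config = config if config is not None else SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    drugs = [f"d{i:03d}" for i in range(config.n_drugs)]
    diseases = [f"s{i:03d}" for i in range(config.n_diseases)]
    genes = [f"g{i:03d}" for i in range(config.n_genes)]
    dens = config.background_density

    drgn_edges = _bipartite_background(
        rng, drugs, genes, dens.get("DRGN", 0.0)
    )
    dign_edges = [
        _bipartite_background(rng, diseases, genes, dens.get("DIGN", 0.0))
        for _ in range(3)
    ]
    ppin_edges = _genepair_background(rng, genes, dens.get("PPIN", 0.0))
    gcn_edges = _genepair_background(rng, genes, dens.get("GCN", 0.0))

    # plant associations on distinct pairs
    grid = config.n_drugs * config.n_diseases
    planted_idx = rng.choice(grid, size=config.n_planted, replace=False)
    planted = [
        (drugs[i // config.n_diseases], diseases[i % config.n_diseases])
        for i in sorted(planted_idx)
    ]
    planted_set = set(planted)

    # direct-channel DIGN edges per planted pair, used for the path
    # guarantee below
    for drug, disease in planted:
        signal_genes = rng.choice(
            config.n_genes, size=config.shared_genes_per_planted,
            replace=False,
        )
        has_path = False
        for gi in signal_genes:
            g1 = genes[gi]
            drgn_edges.add((drug, g1))
            if rng.random() < config.bridge_fraction:
                # bridged signal: d-g1, g1-g2 (PPIN or GCN), g2-s
                g2i = int(rng.integers(config.n_genes - 1))
                if g2i >= gi:
                    g2i += 1  # distinct second gene
                g2 = genes[g2i]
                edge = (g1, g2) if g1 <= g2 else (g2, g1)
                (ppin_edges if rng.random() < 0.5 else gcn_edges).add(edge)
                target = g2
            else:
                target = g1
            for edges in dign_edges:
                if rng.random() < config.dign_signal_prob:
                    edges.add((disease, target))
                    has_path = True
        if not has_path:
            g1 = genes[signal_genes[0]]
            dign_edges[int(rng.integers(3))].add((disease, g1))

    # negatives: never-planted pairs, one per planted pair
    candidates = sorted(
        (d, s)
        for d in drugs
        for s in diseases
        if (d, s) not in planted_set
    )
    n_neg = min(config.n_planted, len(candidates))
    neg_idx = rng.choice(len(candidates), size=n_neg, replace=False)
    truth = LabeledPairSet.from_pairs(
        [(d, s, Label.POSITIVE) for d, s in planted]
        + [
            (candidates[i][0], candidates[i][1], Label.NEGATIVE)
            for i in sorted(neg_idx)
        ]
    )

    bundle = SyntheticBundle(
        drgn=TypedNetwork.from_edges(NetworkRole.DRGN, "drgn", drgn_edges),
        digns=tuple(
            TypedNetwork.from_edges(NetworkRole.DIGN, f"dign{i + 1}", e)
            for i, e in enumerate(dign_edges)
        ),
        ppin=TypedNetwork.from_edges(NetworkRole.PPIN, "ppin", ppin_edges),
        gcn=TypedNetwork.from_edges(NetworkRole.GCN, "gcn", gcn_edges),
        truth=truth,
        config=config,
    )
    logger.info(
        "synthetic bundle: %d drugs, %d diseases, %d genes, %d planted "
        "pairs; edge counts %s",
        config.n_drugs, config.n_diseases, config.n_genes, config.n_planted,
        {n.name: len(n) for n in bundle.networks},
    )
    return bundle


def with_seed(config: SyntheticConfig, seed: int) -> SyntheticConfig:
    """Same study conditions under a different random seed."""
    return replace(config, seed=seed)
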