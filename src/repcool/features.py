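"""Encode drug–disease pairs as vectors of composed-network weights.

Each pair becomes one row; column *j* holds the pair's path-count weight
in the *j*-th composed network (nine columns under the default recipes),
with 0 where the pair is absent. Absence of evidence is zero evidence,
not a missing value. Features stay raw integer counts — no scaling or
log transform is applied by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .composition import ComposedNetwork
from .networks import Label, LabeledPairSet, ValidationError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FeatureMatrix:
    """Pairs × composed-network weights, with optional binary labels."""

    pairs: tuple[tuple[str, str], ...]
    X: np.ndarray  # (n_pairs, n_networks) non-negative integers
    labels: tuple[Label, ...] | None = None
    column_names: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(set(self.pairs)):
            raise ValidationError("duplicate drug-disease pairs in rows")
        if self.X.shape[0] != len(self.pairs):
            raise ValidationError("feature matrix / pair list length mismatch")
        if self.labels is not None and len(self.labels) != len(self.pairs):
            raise ValidationError("labels not aligned with rows")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def y(self) -> np.ndarray:
        """Binary target vector (1 = positive); requires full labeling."""
        if self.labels is None:
            raise ValidationError("feature matrix has no labels")
        if any(l == Label.UNLABELED for l in self.labels):
            raise ValidationError("feature matrix has unlabeled rows")
        return np.array(
            [1 if l == Label.POSITIVE else 0 for l in self.labels],
            dtype=np.int64,
        )

    def __len__(self) -> int:
        return len(self.pairs)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        cols = self.column_names or tuple(
            f"w{j + 1}" for j in range(self.n_features)
        )
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("drug_id\tdisease_id\t" + "\t".join(cols))
            fh.write("\tlabel\n" if self.labels is not None else "\n")
            for i, (drug, disease) in enumerate(self.pairs):
                row = "\t".join(str(int(v)) for v in self.X[i])
                fh.write(f"{drug}\t{disease}\t{row}")
                if self.labels is not None:
                    fh.write(f"\t{self.labels[i].value}")
                fh.write("\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureMatrix":
        path = Path(path)
        with open(path, "r", encoding="utf-8") as fh:
            lines = [
                l.rstrip("\n") for l in fh
                if l.strip() and not l.startswith("#")
            ]
        header = lines[0].split("\t")
        labeled = header[-1] == "label"
        cols = tuple(header[2 : len(header) - 1 if labeled else len(header)])
        pairs, rows, labels = [], [], []
        for line in lines[1:]:
            fields = line.split("\t")
            pairs.append((fields[0], fields[1]))
            end = len(fields) - 1 if labeled else len(fields)
            rows.append([int(v) for v in fields[2:end]])
            if labeled:
                labels.append(Label(fields[-1]))
        X = (
            np.array(rows, dtype=np.int64)
            if rows else np.zeros((0, len(cols)), dtype=np.int64)
        )
        return cls(
            pairs=tuple(pairs),
            X=X,
            labels=tuple(labels) if labeled else None,
            column_names=cols,
        )


def encode_pairs(
    pairs: LabeledPairSet,
    networks: Sequence[ComposedNetwork],
) -> FeatureMatrix:
    """Encode each unique pair as its weight vector across the networks.

    Column order follows network order; a pair absent from a network gets
    weight 0 there, and a pair absent from every network is retained as a
    zero vector (it still carries the information "no path evidence").
    """
    if not networks:
        raise ValidationError("no composed networks supplied")
    if not len(pairs):
        raise ValidationError("no pairs supplied")
    keys = [(d, s) for d, s, _ in pairs.pairs]
    labels = tuple(l for _, _, l in pairs.pairs)
    X = np.zeros((len(keys), len(networks)), dtype=np.int64)
    for j, net in enumerate(networks):
        for i, key in enumerate(keys):
            X[i, j] = net.weights.get(key, 0)
    has_labels = any(l != Label.UNLABELED for l in labels)
    return FeatureMatrix(
        pairs=tuple(keys),
        X=X,
        labels=labels if has_labels else None,
        column_names=tuple(n.recipe_id for n in networks),
    )


def sample_negatives(
    positives: LabeledPairSet,
    drugs: set[str] | frozenset[str],
    diseases: set[str] | frozenset[str],
    ratio: float = 1.0,
    seed: int = 0,
) -> LabeledPairSet:
    """Augment positives with uniformly sampled negative pairs.

    Negatives are drawn without replacement from the complement of the
    positive set over ``drugs × diseases``, ``ceil(ratio × n_positives)``
    of them, reproducibly under ``seed``. This treats non-associations as
    missing completely at random — the standard, least-assuming choice
    when a benchmark provides positives only.
    """
    if ratio <= 0:
        raise ValidationError(f"ratio must be positive, got {ratio}")
    pos = positives.positives
    n_needed = int(np.ceil(ratio * len(pos)))
    candidates = sorted(
        (d, s)
        for d in drugs
        for s in diseases
        if (d, s) not in pos
    )
    if len(candidates) < n_needed:
        raise ValidationError(
            f"cannot sample {n_needed} negatives: only {len(candidates)} "
            f"candidate non-positive pairs available "
            f"(shortfall {n_needed - len(candidates)})"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_needed, replace=False)
    negatives = LabeledPairSet.from_pairs(
        (candidates[i][0], candidates[i][1], Label.NEGATIVE)
        for i in sorted(idx)
    )
    logger.info(
        "sampled %d negatives for %d positives (ratio %.2f, seed %d)",
        n_needed, len(pos), ratio, seed,
    )
    return positives + negatives
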