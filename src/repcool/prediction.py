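"""Rank unlabeled drug–disease pairs as repositioning candidates.

The classifier (by default the most sensitive one from an evaluation
round, mirroring the use of random forest for final prediction) is fit on
all labeled data and candidates are ranked by positive-class probability.
The candidate universe for a query disease is restricted to drugs with at
least one nonzero composed weight for that disease — all-zero vectors are
uninformative and would only pad the output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .classification import EvaluationReport, positive_scores
from .composition import ComposedNetwork
from .features import FeatureMatrix, encode_pairs
from .networks import Label, LabeledPairSet, ValidationError
from sklearn.base import clone

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CandidateRanking:
    """Ordered candidate list: scores non-increasing, ranks 1..n."""

    entries: tuple[tuple[str, str, float, int], ...]
    classifier_name: str
    seed: int

    def __len__(self) -> int:
        return len(self.entries)

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("rank\tdrug_id\tdisease_id\tscore\n")
            for drug, disease, score, rank in self.entries:
                fh.write(f"{rank}\t{drug}\t{disease}\t{score:.6f}\n")

    def rank_of(self, drug: str, disease: str) -> int | None:
        for d, s, _, rank in self.entries:
            if (d, s) == (drug, disease):
                return rank
        return None


def rank_candidates(
    train: FeatureMatrix,
    candidates: FeatureMatrix,
    classifier,
    top_k: int | None = None,
    seed: int = 0,
) -> CandidateRanking:
    """Fit on all labeled rows, score candidates, sort descending.

    Ties are broken by (drug_id, disease_id) lexicographic order so the
    ranking is deterministic. Candidates appearing among training
    positives are rejected.
    """
    if candidates.n_features != train.n_features:
        raise ValidationError(
            f"column mismatch: train has {train.n_features} features, "
            f"candidates have {candidates.n_features}"
        )
    train_positive = {
        pair
        for pair, label in zip(train.pairs, train.labels or ())
        if label == Label.POSITIVE
    }
    overlap = train_positive & set(candidates.pairs)
    if overlap:
        raise ValidationError(
            f"candidates overlap training positives: {sorted(overlap)[:5]}"
        )
    name = getattr(classifier, "__class__", type(classifier)).__name__
    if len(candidates) == 0:
        return CandidateRanking((), name, seed)

    model = clone(classifier)
    model.fit(np.asarray(train.X, dtype=float), train.y())
    scores = positive_scores(model, np.asarray(candidates.X, dtype=float))
    order = sorted(
        range(len(candidates)),
        key=lambda i: (-scores[i], candidates.pairs[i]),
    )
    if top_k is not None:
        order = order[:top_k]
    entries = tuple(
        (
            candidates.pairs[i][0],
            candidates.pairs[i][1],
            float(scores[i]),
            rank,
        )
        for rank, i in enumerate(order, start=1)
    )
    return CandidateRanking(entries, name, seed)


def candidates_for_disease(
    disease_id: str,
    networks: Sequence[ComposedNetwork],
    known_positives: LabeledPairSet,
) -> FeatureMatrix:
    """Build the unlabeled candidate matrix for one query disease.

    One row per drug that has nonzero weight with the disease in at least
    one composed network, excluding drugs already positively associated
    with it. Row vectors are exactly what ``encode_pairs`` produces for
    the same pairs.
    """
    linked_drugs: set[str] = set()
    seen_disease = False
    for net in networks:
        for (d, s), _ in net.weights.items():
            if s == disease_id:
                seen_disease = True
                linked_drugs.add(d)
    if not seen_disease:
        raise ValidationError(
            f"disease {disease_id!r} absent from all composed networks"
        )
    excluded = {
        d for d, s in known_positives.positives if s == disease_id
    }
    drugs = sorted(linked_drugs - excluded)
    if not drugs:
        raise ValidationError(
            f"no candidate drugs remain for disease {disease_id!r}"
        )
    pairs = LabeledPairSet.from_pairs(
        (d, disease_id, Label.UNLABELED) for d in drugs
    )
    return encode_pairs(pairs, networks)


def select_classifier_name(
    reports: dict[str, EvaluationReport]
) -> str:
    """Pick the most sensitive (highest-recall) classifier for prediction.

    NaN recalls are skipped; ties break by AUC then name.
    """
    best = None
    for name, report in sorted(reports.items()):
        if math.isnan(report.recall):
            continue
        key = (report.recall, report.auc)
        if best is None or key > best[0]:
            best = (key, name)
    if best is None:
        raise ValidationError("no classifier with defined recall")
    logger.info("selected %s for prediction (recall %.4f)", best[1], best[0][0])
    return best[1]
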