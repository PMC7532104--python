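"""Structural similarity of drugs from a numeric descriptor table.

Given a drugs × descriptors matrix (e.g. Dragon-style structural
features, computed externally), this module produces the pairwise
Euclidean distance matrix on z-scored features, the Pearson correlation
matrix of descriptor rows, and an agglomerative-clustering dendrogram
exportable to Newick. Correlations are reported in [−1, 1]; multiply by
100 for the percentage-style display sometimes used in the literature.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .networks import ValidationError

logger = logging.getLogger(__name__)

LINKAGE_METHODS = ("average", "complete", "single")


@dataclass(frozen=True)
class DescriptorTable:
    drug_ids: tuple[str, ...]
    descriptors: np.ndarray  # drugs × features, float, no missing values
    feature_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if len(self.drug_ids) != len(set(self.drug_ids)):
            raise ValidationError("duplicate drug identifiers")
        if len(self.drug_ids) < 2 or self.descriptors.shape[1] < 2:
            raise ValidationError(
                "descriptor table needs >=2 drugs and >=2 features"
            )
        if self.descriptors.shape[0] != len(self.drug_ids):
            raise ValidationError("descriptor rows do not match drug_ids")
        if np.isnan(self.descriptors).any():
            raise ValidationError("missing values after load")

    @classmethod
    def from_file(cls, path: str | Path, sep: str | None = None
                  ) -> "DescriptorTable":
        """Load a headered TSV/CSV: first column drug_id, rest numeric.

        Columns that are entirely missing, then rows with any remaining
        missing value, are dropped with a logged count.
        """
        path = Path(path)
        if sep is None:
            sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep, index_col=0, comment="#")
        n_cols = df.shape[1]
        df = df.dropna(axis=1, how="all")
        n_rows = df.shape[0]
        df = df.dropna(axis=0, how="any")
        dropped_cols = n_cols - df.shape[1]
        dropped_rows = n_rows - df.shape[0]
        if dropped_cols or dropped_rows:
            logger.warning(
                "dropped %d all-missing columns and %d incomplete rows "
                "from %s", dropped_cols, dropped_rows, path,
            )
        return cls(
            drug_ids=tuple(str(i) for i in df.index),
            descriptors=df.to_numpy(dtype=float),
            feature_names=tuple(str(c) for c in df.columns),
        )


def similarity_matrices(
    table: DescriptorTable,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance and Pearson-correlation matrices between drugs.

    Distance is Euclidean between feature-standardized (z-scored
    per-column) descriptor rows, so no single large-scale descriptor
    dominates; correlation is the Pearson coefficient between raw
    descriptor rows. A drug whose descriptor row is constant has no
    defined correlation and is rejected by name.
    """
    X = table.descriptors
    row_sd = X.std(axis=1)
    constant = [
        table.drug_ids[i] for i in np.nonzero(row_sd == 0)[0]
    ]
    if constant:
        raise ValidationError(
            f"constant descriptor row(s), correlation undefined: "
            f"{constant}"
        )
    col_sd = X.std(axis=0, ddof=0)
    safe_sd = np.where(col_sd == 0, 1.0, col_sd)  # constant column -> 0 z
    Z = (X - X.mean(axis=0)) / safe_sd
    D = squareform(pdist(Z, metric="euclidean"))
    C = np.corrcoef(X)
    np.fill_diagonal(C, 1.0)
    ids = list(table.drug_ids)
    return (
        pd.DataFrame(D, index=ids, columns=ids),
        pd.DataFrame(C, index=ids, columns=ids),
    )


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative clustering tree over drugs.

    Wraps a scipy linkage matrix; merge heights are non-decreasing
    root-ward for the supported linkage methods.
    """

    linkage_matrix: np.ndarray
    leaf_names: tuple[str, ...]
    method: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_names)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def to_newick(self) -> str:
        """Newick string with branch lengths.

        A node's branch length is its parent's merge height minus its own
        (leaves have height 0), so root-to-leaf path lengths equal the
        root merge height.
        """
        tree = sch.to_tree(self.linkage_matrix)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaf_names[node.id]}:{length:.10g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        return render(tree, tree.dist) + ";"


def cluster_dendrogram(
    distance_matrix: pd.DataFrame | np.ndarray,
    linkage: str = "average",
    leaf_names: Sequence[str] | None = None,
) -> Dendrogram:
    """Agglomerative clustering from a full symmetric distance matrix."""
    if linkage not in LINKAGE_METHODS:
        raise ValidationError(
            f"linkage must be one of {LINKAGE_METHODS}, got {linkage!r}"
        )
    if isinstance(distance_matrix, pd.DataFrame):
        if leaf_names is None:
            leaf_names = [str(i) for i in distance_matrix.index]
        D = distance_matrix.to_numpy(dtype=float)
    else:
        D = np.asarray(distance_matrix, dtype=float)
        if leaf_names is None:
            leaf_names = [f"leaf{i}" for i in range(D.shape[0])]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValidationError("distance matrix must be square")
    if (D < 0).any():
        raise ValidationError("distance matrix has negative entries")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValidationError("distance matrix is not symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValidationError("distance matrix diagonal must be zero")
    if len(leaf_names) != D.shape[0]:
        raise ValidationError("leaf_names do not match matrix size")
    Z = sch.linkage(squareform(D, checks=False), method=linkage)
    return Dendrogram(
        linkage_matrix=Z,
        leaf_names=tuple(str(n) for n in leaf_names),
        method=linkage,
    )


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, sep="\t", float_format="%.10g")
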